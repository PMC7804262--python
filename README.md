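# enamelmetrics

Quantitative measurement of **linear enamel hypoplasia (LEH)** defects and
**perikymata** (near-weekly enamel growth increments) from high-resolution 3D
tooth-surface topographies, as produced by confocal profilometry of teeth or
epoxy replicas.

Hypoplastic defects record early-life physiological stress, but their depth
also reflects species- and tooth-specific enamel growth: faster-extending
enamel produces shallower perikymata *and* shallower defects. This package
implements a measurement chain that (i) measures defect and perikyma depths
directly on raw, un-leveled elevation models using a fixed occlusal-shoulder
convention, (ii) normalizes defect depth by perikymata depth into an **LEH
severity ratio** that compares stress severity across taxa with different
growth rates, and (iii) quantifies how plane/sphere "form-removal" leveling
biases depth measurements (it makes defects read shallower and perikymata
read deeper). It is aimed at dental anthropologists and bioarchaeologists.

## What it computes

For a transect profile *z(d)* drawn occlusal-to-cervical across a feature:

- **Defect depth** = z(occlusal shoulder) − z(deepest groove minimum), in µm.
- **Perikyma depth** = z(occlusal-side ridge) − z(groove floor), in µm.
- Extrema are found with an amplitude-threshold peak finder: all strict local
  extrema, pruned smallest-amplitude-first until every adjacent
  maximum–minimum pair spans ≥ the minimum amplitude (defaults: 5 µm for
  defects, 0.2 µm for perikymata; both adjustable, as shallow features
  require).
- **LEH severity ratio** = defect depth ÷ median perikymata depth of the same
  tooth; where a tooth's perikymata are unmeasurable, the median for that
  species and tooth type is the fallback reference.
- **Group statistics**: Pearson correlation of log tooth medians, and linear
  mixed models `log(depth) ~ group + (1 | specimen)` fitted by REML with
  containment denominator degrees of freedom, plus Tukey- or Holm-adjusted
  pairwise contrasts.

The pipeline: XYZ `.dat` point clouds → Delaunay-interpolated digital
elevation model (DEM, default 0.64 µm/pixel) → optional vertical flip and
median/MAD spike cleaning → bilinear transect profiles → depth measurements
(defects in triplicate) → severity ratios and group models. A synthetic
crown-surface generator (curved crown, quasi-periodic asymmetric perikymata,
Gaussian furrow defects, instrument noise/spikes/dropouts) provides known
ground truth for every stage.

## Worked example

```python
import numpy as np
from enamelmetrics import (
    DefectSpec, PerikymataSpec, SyntheticSurfaceSpec, generate_surface,
    interpolate_dem, extract_profile, measure_defect_depth,
    measure_perikymata_depths, aggregate_feature, replicate_transects, Transect,
)
from enamelmetrics.synthetic import defect_transect

# a curved crown strip with one 26.4 µm furrow defect and 1.57 µm perikymata
spec = SyntheticSurfaceSpec(
    extent=(100.0, 700.0), pixel_pitch=1.0, crown_radius=5000.0,
    apex_position=250.0,
    perikymata=PerikymataSpec(mean_spacing=45.0, depth_mean=1.57, depth_sd=0.2),
    defects=[DefectSpec(center=500.0, width=120.0, depth=26.4)],
    noise_sd=0.05, dropout_rate=0.015, seed=0,
)
cloud, _, truth = generate_surface(spec)
dem = interpolate_dem(cloud, pixel_pitch=1.0)

# triplicate defect measurement on three parallel transects, 25 µm apart
base = defect_transect(spec, spec.defects[0])
reps = replicate_transects(base, n=3, lateral_offset=25.0, dem=dem)
ms = [measure_defect_depth(extract_profile(dem, t), min_amplitude=5.0,
                           replicate_index=i) for i, t in enumerate(reps)]
agg = aggregate_feature(ms)
print(f"defect depth: {agg.mean_depth:.1f} um (n={agg.n} replicates, "
      f"range {agg.spread:.2f} um)")
print(f"ground truth: {truth.defects[0]['surface_depth_um']:.1f} um")

# perikymata on a level area near the curvature apex
pk_tr = Transect(start=(50.0, 160.0), end=(50.0, 360.0))
pk = measure_perikymata_depths(extract_profile(dem, pk_tr), n_target=4,
                               min_amplitude=0.2)
print("perikymata depths (um):", [round(m.depth, 2) for m in pk])
print(f"LEH severity ratio: {agg.mean_depth / np.median([m.depth for m in pk]):.1f}")
```

prints

```
defect depth: 32.7 um (n=3 replicates, range 0.16 um)
ground truth: 32.6 um
perikymata depths (um): [1.68, 1.37, 2.04, 2.33]
LEH severity ratio: 17.6
```

The triplicate mean matches the analytic ground truth to 0.1 µm. The
measured depth exceeds the 26.4 µm furrow amplitude because on a curved,
un-leveled crown the occlusal shoulder sits up-slope of the floor — exactly
the geometry the measurement convention defines (and the reason the package
measures raw rather than leveled surfaces, with short transects). The
severity ratio (17.6) falls in the range published for anterior teeth.

A command line mirrors the library: `enamelmetrics simulate | build-dem |
level | measure | summarize | stats` (see `enamelmetrics --help`), with every
effective parameter echoed to a run-manifest JSON.

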