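"""Shared fixtures: small synthetic fields reused across test modules."""

import numpy as np
import pytest

from enamelmetrics import (
    DefectSpec,
    PerikymataSpec,
    SyntheticSurfaceSpec,
    generate_surface,
)


@pytest.fixture(scope="session")
def curved_defect_field():
    """Curved crown (R=5000 µm) with one 40 µm furrow cervical of the apex.

    Geometry mirrors a defect-centered scan strip: the curvature apex sits
    occlusal of the defect so the occlusal shoulder reads against the
    down-slope, and a perikymata zone on the occlusal flank stays usable.
    """
    spec = SyntheticSurfaceSpec(
        extent=(100.0, 1500.0),
        pixel_pitch=2.0,
        crown_radius=5000.0,
        apex_position=600.0,
        perikymata=PerikymataSpec(
            mean_spacing=45.0, spacing_gradient=0.1, depth_mean=1.5, depth_sd=0.15
        ),
        defects=[DefectSpec(center=900.0, width=200.0, depth=40.0)],
        noise_sd=0.0,
        spike_rate=0.0,
        dropout_rate=0.0,
        seed=5,
    )
    cloud, dem, truth = generate_surface(spec)
    return spec, cloud, dem, truth


@pytest.fixture(scope="session")
def flat_defect_field():
    """Flat field with one 30 µm furrow, no noise — simplest ground truth."""
    spec = SyntheticSurfaceSpec(
        extent=(80.0, 600.0),
        pixel_pitch=1.0,
        crown_radius=np.inf,
        perikymata=PerikymataSpec(
            mean_spacing=45.0, spacing_gradient=0.1, depth_mean=1.5, depth_sd=0.15
        ),
        defects=[DefectSpec(center=300.0, width=120.0, depth=30.0)],
        noise_sd=0.0,
        spike_rate=0.0,
        dropout_rate=0.0,
        seed=7,
    )
    cloud, dem, truth = generate_surface(spec)
    return spec, cloud, dem, truth
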