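"""Published reference depths for Neanderthal and H. sapiens anterior teeth.

Median and range of perikymata depth, linear-enamel-hypoplasia (LEH) defect
depth and LEH severity ratio (defect depth / perikymata depth), by taxon and
tooth type, as published for a sample of 35 anterior teeth (280 perikymata,
71 defects).  Tooth types: lower/upper canine (LC/UC), lower/upper central
incisor (LI1/UI1), lower/upper lateral incisor (LI2/UI2).  All depths in µm.

These tables serve as worked-example inputs and as realistic parameter
regimes for the synthetic-surface generator; they are not outputs of this
package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_depth_table", "TOOTH_TYPES", "TOOTH_CLASS"]

TOOTH_TYPES = ("LC", "LI1", "LI2", "UC", "UI1", "UI2")

TOOTH_CLASS = {
    "LC": "canine",
    "UC": "canine",
    "LI1": "incisor",
    "LI2": "incisor",
    "UI1": "incisor",
    "UI2": "incisor",
}

# (taxon, tooth_type): n_pk, pk median, pk range, n_defects, defect median,
# defect range, severity median, severity range.  A None range means n = 1.
_TABLE = [
    ("Neanderthal", "LC", 10, 1.57, (1.17, 3.09), 5, 26.4, (19.6, 46.2), 16.8, (12.5, 29.4)),
    ("Neanderthal", "LI1", 10, 0.83, (0.71, 1.18), 3, 15.2, (9.8, 27.5), 18.3, (11.8, 33.1)),
    ("Neanderthal", "LI2", 10, 0.84, (0.46, 1.78), 2, 19.0, (10.7, 27.3), 22.6, (12.7, 32.5)),
    ("Neanderthal", "UC", 50, 1.04, (0.42, 3.05), 13, 24.1, (13.3, 45.7), 27.1, (9.9, 49.2)),
    ("Neanderthal", "UI1", 20, 1.28, (0.49, 3.05), 5, 13.4, (9.5, 22.7), 13.4, (8.7, 15.6)),
    ("Neanderthal", "UI2", 30, 0.81, (0.53, 1.43), 8, 17.2, (10.1, 31.3), 20.7, (13.8, 35.6)),
    ("H. sapiens", "LC", 40, 4.32, (1.28, 11.29), 11, 47.5, (32.8, 101.7), 16.1, (5.7, 40.0)),
    ("H. sapiens", "LI1", 30, 2.42, (0.96, 7.95), 8, 38.4, (20.6, 48.4), 19.7, (4.2, 46.5)),
    ("H. sapiens", "LI2", 30, 2.52, (0.83, 8.17), 6, 36.7, (20.9, 50.5), 19.6, (5.6, 52.3)),
    ("H. sapiens", "UC", 20, 4.18, (1.68, 8.47), 3, 41.7, (32.7, 79.1), 7.8, (6.1, 28.3)),
    ("H. sapiens", "UI1", 20, 1.79, (1.14, 3.09), 6, 28.4, (18.7, 52.4), 16.3, (9.4, 30.5)),
    ("H. sapiens", "UI2", 10, 2.04, (1.55, 3.42), 1, 29.6, None, 14.5, None),
]


def published_depth_table() -> pd.DataFrame:
    """Reference depth medians/ranges as a tidy DataFrame."""
    rows = []
    for (taxon, tt, n_pk, pk_med, pk_rng, n_def, def_med, def_rng, sev_med, sev_rng) in _TABLE:
        rows.append(
            {
                "taxon": taxon,
                "tooth_type": tt,
                "tooth_class": TOOTH_CLASS[tt],
                "n_perikymata": n_pk,
                "pk_median_um": pk_med,
                "pk_min_um": pk_rng[0] if pk_rng else None,
                "pk_max_um": pk_rng[1] if pk_rng else None,
                "n_defects": n_def,
                "defect_median_um": def_med,
                "defect_min_um": def_rng[0] if def_rng else None,
                "defect_max_um": def_rng[1] if def_rng else None,
                "severity_median": sev_med,
                "severity_min": sev_rng[0] if sev_rng else None,
                "severity_max": sev_rng[1] if sev_rng else None,
            }
        )
    return pd.DataFrame(rows)
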