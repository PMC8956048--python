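"""Published reference data bundled for validation and worked examples.

Small tables transcribed from the originating NIR study of *Poria
cocos*: the validation-set comparison of reference and NIR-predicted
cultivation regions, the glucose standard curve of the phenol-sulfuric
polysaccharide assay, and the HPLC calibration lines for the five
triterpene acids.
"""

from __future__ import annotations

import pandas as pd

from .chemistry import StandardCurve

# (sample, reference region, NIR-predicted region) for the 27
# Kennard-Stone validation samples of the regional-origin study.
_REGION_VALIDATION = [
    ("S16", "YN", "YN"), ("S19", "YN", "YN"), ("S22", "YN", "YN"),
    ("S25", "YN", "YN"), ("S35", "YN", "YN"), ("S50", "YN", "YN"),
    ("S57", "DBM", "DBM"), ("S64", "DBM", "DBM"), ("S65", "DBM", "DBM"),
    ("S67", "DBM", "DBM"), ("S68", "DBM", "DBM"), ("S69", "DBM", "DBM"),
    ("S73", "DBM", "DBM"), ("S76", "DBM", "DBM"), ("S80", "DBM", "DBM"),
    ("S83", "XQ", "XQ"), ("S88", "XQ", "XQ"), ("S92", "XQ", "DBM"),
    ("S93", "DBM", "DBM"), ("S101", "DBM", "DBM"), ("S102", "DBM", "DBM"),
    ("S109", "DBM", "DBM"), ("S112", "DBM", "DBM"), ("S121", "YN", "YN"),
    ("S128", "DBM", "DBM"), ("S133", "YN", "YN"), ("S136", "XQ", "DBM"),
]


def reference_region_validation() -> pd.DataFrame:
    """The published 27-sample validation comparison (reference vs NIR)."""
    return pd.DataFrame(_REGION_VALIDATION,
                        columns=["sample_id", "reference", "predicted"])


def glucose_standard_curve() -> StandardCurve:
    """Published phenol-sulfuric D-glucose curve: Y = 84.978 X + 0.0571."""
    return StandardCurve(slope=84.978, intercept=0.0571, r2=0.9924)


def hplc_calibration_table() -> pd.DataFrame:
    """Published HPLC calibration lines for the five triterpene acids.

    Slope/intercept map concentration in mg/mL to peak area; LOD/LOQ are
    in ug/mL.
    """
    rows = [
        ("dtua", 16985351.48000, 4404.85745, 0.996, 0.81, 40.60, 0.209, 0.696),
        ("paa", 14178282.95000, -1464.46374, 0.998, 0.40, 20.00, 0.186, 0.619),
        ("pac", 16709116.59000, -399.56329, 0.999, 0.41, 20.40, 0.166, 0.554),
        ("dpa", 15817965.09000, 518.67483, 0.998, 0.79, 39.60, 0.236, 0.788),
        ("dtra", 18347795.59000, 9040.36403, 0.994, 1.21, 60.40, 0.157, 0.525),
    ]
    return pd.DataFrame(rows, columns=["compound", "slope", "intercept", "r2",
                                       "range_low", "range_high", "lod", "loq"])
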