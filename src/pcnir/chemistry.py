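"""Wet-lab reference arithmetic behind the quality parameters.

Covers the gravimetric extract-content formula, ordinary least-squares
standard curves (phenol-sulfuric polysaccharide assay, HPLC triterpene
calibration), curve inversion with dilution, ICH-convention detection
limits, and per-region summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .spectra import REGIONS


@dataclass
class ExtractGravimetry:
    """One gravimetric extract determination.

    ``S`` sample mass (g); ``W0`` evaporating-dish mass (g); ``W1`` dish
    plus residue after drying (g); ``aliquot_factor`` corrects for the
    measured aliquot (2 when 25 of 50 mL is evaporated).
    """

    S: float
    W0: float
    W1: float
    aliquot_factor: float = 2.0

    def __post_init__(self):
        if self.S <= 0:
            raise ValidationError(f"sample mass must be positive, got {self.S}")
        if self.W1 < self.W0:
            raise ValidationError("dish+residue mass below empty dish mass")
        if self.aliquot_factor <= 0:
            raise ValidationError("aliquot factor must be positive")


def extract_content(g: ExtractGravimetry) -> float:
    """Extract content (%): (W1 - W0) * aliquot_factor / S * 100."""
    return (g.W1 - g.W0) * g.aliquot_factor / g.S * 100.0


@dataclass
class StandardCurve:
    """A linear calibration: response = slope * concentration + intercept."""

    slope: float
    intercept: float
    r2: float
    residual_sd: Optional[float] = None
    lod: Optional[float] = None
    loq: Optional[float] = None

    def __post_init__(self):
        if self.r2 > 1.0 + 1e-12:
            raise ValidationError("r2 cannot exceed 1")
        if self.lod is not None and self.loq is not None and self.lod >= self.loq:
            raise ValidationError("LOD must be below LOQ")


def fit_standard_curve(concentrations: Sequence[float],
                       responses: Sequence[float]) -> StandardCurve:
    """OLS line through calibration points; r2 is the squared Pearson r.

    The residual standard deviation uses the n-2 denominator and feeds
    :func:`lod_loq`.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size != resp.size:
        raise ValidationError("concentration and response lengths differ")
    if conc.size < 3:
        raise ValidationError("need at least 3 calibration points")
    if np.ptp(conc) == 0:
        raise ValidationError("degenerate design: all concentrations equal")
    fit = stats.linregress(conc, resp)
    resid = resp - (fit.slope * conc + fit.intercept)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / (conc.size - 2)))
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r2=float(fit.rvalue ** 2), residual_sd=residual_sd)


def concentration_from_response(curve: StandardCurve, response: float,
                                dilution_factor: float = 1.0) -> float:
    """Invert the calibration line: ((response - intercept)/slope) * dilution."""
    if curve.slope == 0:
        raise ValidationError("zero slope: calibration cannot be inverted")
    return (response - curve.intercept) / curve.slope * dilution_factor


def lod_loq(curve: StandardCurve) -> tuple[float, float]:
    """Detection and quantification limits, ICH convention.

    LOD = 3.3 * residual_sd / slope, LOQ = 10 * residual_sd / slope.
    """
    if curve.residual_sd is None:
        raise ValidationError("curve has no residual_sd; refit from raw points")
    if curve.slope <= 0:
        raise ValidationError("LOD/LOQ require a positive slope")
    lod = 3.3 * curve.residual_sd / curve.slope
    loq = 10.0 * curve.residual_sd / curve.slope
    return lod, loq


def region_summary(values: Sequence[float], regions: Sequence[str],
                   ndigits: int = 2) -> pd.DataFrame:
    """Per-region n/min/max/mean/sd table, rounded for display.

    Samples with missing values are dropped per region; a region left
    empty is omitted.  The sample (n-1) SD is reported as missing for
    single-sample regions.
    """
    values = np.asarray(values, dtype=float)
    regions = np.asarray(regions)
    if values.size != regions.size:
        raise ValidationError("values and regions lengths differ")
    rows = []
    seen = [r for r in REGIONS if r in set(regions.tolist())]
    seen += [r for r in pd.unique(regions) if r not in REGIONS]
    for region in seen:
        v = values[(regions == region) & np.isfinite(values)]
        if v.size == 0:
            continue
        sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
        rows.append({"region": region, "n": int(v.size),
                     "min": round(float(v.min()), ndigits),
                     "max": round(float(v.max()), ndigits),
                     "mean": round(float(v.mean()), ndigits),
                     "sd": round(sd, ndigits) if np.isfinite(sd) else np.nan})
    return pd.DataFrame(rows, columns=["region", "n", "min", "max", "mean", "sd"])
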