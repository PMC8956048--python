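"""Spectral pretreatment operators and their named compositions.

Seven named pretreatments are supported: ``Raw``, ``MSC``, ``SNV``,
``Smooth``, ``Smooth+SNV``, ``Smooth+MSC`` and ``SG-1D``.  ``Smooth`` is
Savitzky-Golay smoothing (deriv=0); ``SG-1D`` is the Savitzky-Golay first
derivative scaled by the wavenumber step, so its units are absorbance per
cm^-1.  Composed names smooth first, then scatter-correct.

MSC learns a reference spectrum (the column-wise mean of the data it is
fitted on); :func:`apply_pretreatment` returns that state so validation
data can be corrected against the calibration reference instead of its
own mean — the only data-dependent state in the family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .errors import ValidationError
from .spectra import SpectraMatrix

PRETREATMENTS = ("Raw", "MSC", "SNV", "Smooth", "Smooth+SNV", "Smooth+MSC", "SG-1D")
_CANONICAL = {name.lower(): name for name in PRETREATMENTS}


@dataclass(frozen=True)
class PretreatmentSpec:
    """A named pretreatment with Savitzky-Golay window settings.

    ``window`` (odd, points) and ``polyorder`` apply to the Smooth and
    SG-1D family; defaults are the common chemometrics choice of an
    11-point quadratic filter.
    """

    name: str = "Raw"
    window: int = 11
    polyorder: int = 2

    def __post_init__(self):
        canonical = _CANONICAL.get(str(self.name).lower())
        if canonical is None:
            raise ValidationError(
                f"unknown pretreatment {self.name!r}; valid names: {list(PRETREATMENTS)}"
            )
        object.__setattr__(self, "name", canonical)
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError(f"window must be odd and >= 3, got {self.window}")
        if not (1 <= self.polyorder < self.window):
            raise ValidationError(
                f"polyorder must satisfy 1 <= polyorder < window, got {self.polyorder}"
            )


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: centre and scale each spectrum to sd 1.

    Uses the sample (n-1) standard deviation; every output row has mean 0
    and sd 1, which removes per-sample multiplicative scatter and offset.
    """
    x = spectra.absorbance
    if x.shape[1] < 2:
        raise ValidationError("SNV needs at least 2 points per spectrum")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        bad = [spectra.sample_ids[i] for i in zero]
        raise ValidationError(f"constant spectra (zero sd) for samples {bad}")
    return spectra.with_absorbance((x - mean) / sd)


def msc(spectra: SpectraMatrix,
        reference: Optional[np.ndarray] = None) -> tuple[SpectraMatrix, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed x = a + b*reference by OLS and replaced
    by (x - a)/b.  With ``reference`` omitted the column-wise mean of the
    input is used and returned for reuse on later (validation) data.
    """
    x = spectra.absorbance
    if reference is None:
        if x.shape[0] < 2:
            raise ValidationError("MSC needs >= 2 samples to form a mean reference")
        reference = x.mean(axis=0)
    reference = np.asarray(reference, dtype=float).ravel()
    if reference.size != x.shape[1]:
        raise ValidationError(
            f"reference length {reference.size} != {x.shape[1]} wavenumbers"
        )
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValidationError("constant MSC reference spectrum")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    tiny = np.abs(b) < 1e-12
    if tiny.any():
        bad = [spectra.sample_ids[i] for i in np.flatnonzero(tiny)]
        raise ValidationError(f"zero MSC slope for samples {bad}")
    a = x.mean(axis=1) - b * reference.mean()
    corrected = (x - a[:, None]) / b[:, None]
    return spectra.with_absorbance(corrected), reference


def savitzky_golay(spectra: SpectraMatrix, window: int = 11, polyorder: int = 2,
                   deriv: int = 0) -> SpectraMatrix:
    """Savitzky-Golay smoothing (deriv=0) or first derivative (deriv=1).

    The derivative is scaled by the uniform wavenumber step so units are
    absorbance per cm^-1; edges are handled by a one-sided polynomial fit
    so the output shape equals the input shape.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError(f"window must be odd and >= 3, got {window}")
    if window > spectra.n_wavenumbers:
        raise ValidationError(
            f"window {window} exceeds {spectra.n_wavenumbers} wavenumbers"
        )
    if not (1 <= polyorder < window):
        raise ValidationError("polyorder must satisfy 1 <= polyorder < window")
    if deriv not in (0, 1):
        raise ValidationError("deriv must be 0 (smooth) or 1 (first derivative)")
    steps = np.diff(spectra.wavenumbers)
    delta = steps.mean()
    if deriv == 1 and np.max(np.abs(steps - delta)) > 1e-6 * abs(delta):
        raise ValidationError(
            "derivative scaling undefined on a non-uniform wavenumber axis"
        )
    out = savgol_filter(spectra.absorbance, window_length=window,
                        polyorder=polyorder, deriv=deriv, delta=delta,
                        axis=1, mode="interp")
    return spectra.with_absorbance(out)


def apply_pretreatment(spectra: SpectraMatrix, spec: PretreatmentSpec,
                       fitted_state: Optional[dict] = None
                       ) -> tuple[SpectraMatrix, Optional[dict]]:
    """Apply a named pretreatment, learning or reusing data-dependent state.

    Returns ``(treated, fitted_state)``.  For the MSC family the state
    holds the reference spectrum learned from the data this was fitted
    on; pass it back to correct validation spectra against the
    calibration reference.  Stateless pretreatments return ``None``.
    """
    name = spec.name
    if name == "Raw":
        return spectra.copy(), None
    if name in ("Smooth", "Smooth+SNV", "Smooth+MSC"):
        smoothed = savitzky_golay(spectra, spec.window, spec.polyorder, deriv=0)
        if name == "Smooth":
            return smoothed, None
        if name == "Smooth+SNV":
            return snv(smoothed), None
        spectra = smoothed
        name = "MSC"
    if name == "SNV":
        return snv(spectra), None
    if name == "MSC":
        reference = None if fitted_state is None else fitted_state.get("msc_reference")
        corrected, reference = msc(spectra, reference)
        return corrected, {"msc_reference": reference}
    if name == "SG-1D":
        return savitzky_golay(spectra, spec.window, spec.polyorder, deriv=1), None
    raise ValidationError(  # pragma: no cover - spec validation precludes this
        f"unknown pretreatment {name!r}; valid names: {list(PRETREATMENTS)}"
    )
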