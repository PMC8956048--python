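"""Single-response partial least squares regression (NIPALS PLS1).

The calibration workflow follows standard NIR practice: mean-centre X and
y, extract latent variables by the NIPALS sequence (weight along the
covariance of X with y, score, deflate), collapse the latent regression
into a single coefficient vector, pick the factor count by 10-fold
cross-validation with a parsimony margin, and report RMSEC / RMSEP /
R2cal / R2pre plus the mean relative error over validation samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import PretreatmentSpec, apply_pretreatment
from .sampling import SplitResult
from .spectra import SpectraMatrix


@dataclass
class PLSRModel:
    """Fitted PLS1 state sufficient for bit-reproducible prediction."""

    n_factors: int
    x_weights: np.ndarray     # (p, a)
    x_loadings: np.ndarray    # (p, a)
    y_loadings: np.ndarray    # (a,)
    x_mean: np.ndarray        # (p,)
    y_mean: float
    coefficients: np.ndarray  # (p,) mapping centred X to centred y
    wavenumbers: Optional[np.ndarray] = None
    pretreatment: Optional[PretreatmentSpec] = None
    fitted_state: Optional[dict] = None


def _nipals(xc: np.ndarray, yc: np.ndarray, n_factors: int,
            allow_early_stop: bool = False):
    """Run the PLS1 NIPALS sequence on centred data.

    Returns weights W (p, a), loadings P (p, a) and y-loadings q (a,).
    Raises if the requested factor count exceeds the effective rank,
    unless ``allow_early_stop`` is set, in which case the achieved
    (truncated) decomposition is returned.
    """
    x = xc.copy()
    y = yc.copy()
    p = x.shape[1]
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    for a in range(n_factors):
        w = x.T @ y
        norm = np.linalg.norm(w)
        t = x @ w
        tt = t @ t if norm >= 1e-12 else 0.0
        if norm < 1e-12 or tt < 1e-24:
            if allow_early_stop:
                return W[:, :a], P[:, :a], q[:a]
            raise ValidationError(
                f"n_factors={n_factors} exceeds the effective rank ({a} usable)"
            )
        w /= norm
        t /= norm
        tt /= norm * norm
        pa = x.T @ t / tt
        qa = y @ t / tt
        x -= np.outer(t, pa)
        y -= qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
    return W, P, q


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Collapse latent structure to a coefficient vector B = W (P'W)^-1 q."""
    return W @ np.linalg.solve(P.T @ W, q)


def fit_plsr(X, y, n_factors: int, *, wavenumbers=None,
             pretreatment: Optional[PretreatmentSpec] = None,
             fitted_state: Optional[dict] = None) -> PLSRModel:
    """Fit a PLS1 model on (already pretreated) calibration spectra.

    ``X`` is an ``(n, p)`` array or a :class:`SpectraMatrix`; ``y`` the
    response (no missing values).  The optional pretreatment metadata is
    stored so prediction can re-apply it to raw spectra.
    """
    if isinstance(X, SpectraMatrix):
        wavenumbers = X.wavenumbers
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError(f"{y.size} responses for {n} spectra")
    if not np.all(np.isfinite(y)):
        raise ValidationError("missing or non-finite response values")
    if np.ptp(y) == 0:
        raise ValidationError("constant response: nothing to regress")
    max_a = min(n - 1, p)
    if not (1 <= n_factors <= max_a):
        raise ValidationError(
            f"n_factors must be in [1, {max_a}] for {n} samples x {p} columns"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals(X - x_mean, y - y_mean, n_factors)
    return PLSRModel(
        n_factors=n_factors, x_weights=W, x_loadings=P, y_loadings=q,
        x_mean=x_mean, y_mean=y_mean, coefficients=_coefficients(W, P, q),
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, float),
        pretreatment=pretreatment, fitted_state=fitted_state,
    )


def plsr_predict(model: PLSRModel, X) -> np.ndarray:
    """Predict responses: y_mean + (X_pretreated - x_mean) @ coefficients.

    A :class:`SpectraMatrix` is checked against the model's wavenumber
    axis and run through the stored pretreatment (with its frozen fitted
    state); a plain array is taken as already pretreated.
    """
    if isinstance(X, SpectraMatrix):
        if model.wavenumbers is not None and (
                X.n_wavenumbers != model.wavenumbers.size
                or not np.allclose(X.wavenumbers, model.wavenumbers)):
            raise ValidationError("wavenumber axis differs from the model's")
        if model.pretreatment is not None:
            X, _ = apply_pretreatment(X, model.pretreatment, model.fitted_state)
        X = X.absorbance
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coefficients.size:
        raise ValidationError(
            f"{X.shape[1]} columns but model expects {model.coefficients.size}"
        )
    return model.y_mean + (X - model.x_mean) @ model.coefficients


def select_n_factors(X, y, max_factors: int, k: int = 10, seed: int = 0,
                     margin: float = 0.02) -> int:
    """Pick the PLSR factor count by k-fold cross-validation.

    Folds come from a seeded shuffle; RMSECV pools held-out residuals.
    Returns the smallest factor count whose RMSECV is within ``margin``
    (default 2%) of the global minimum; ``margin=0`` recovers the strict
    argmin.
    """
    if isinstance(X, SpectraMatrix):
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_factors < 1:
        raise ValidationError("max_factors must be >= 1")
    if k > n or k < 2:
        raise ValidationError(f"k={k} folds invalid for n={n} samples")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    a_max = min(max_factors, min(n - len(f) - 1 for f in folds), p)
    decomps = []
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        xm = X[train].mean(axis=0)
        ym = y[train].mean()
        W, P, q = _nipals(X[train] - xm, y[train] - ym, a_max,
                          allow_early_stop=True)
        if q.size < 1:
            raise ValidationError("a fold has no usable latent variables")
        decomps.append((W, P, q, X[test_idx] - xm, y[test_idx] - ym))
        a_max = min(a_max, q.size)  # cap by the effective rank seen per fold
    press = np.zeros(a_max)
    for W, P, q, xt, yt in decomps:
        for a in range(1, a_max + 1):
            b = _coefficients(W[:, :a], P[:, :a], q[:a])
            resid = yt - xt @ b
            press[a - 1] += resid @ resid
    rmsecv = np.sqrt(press / n)
    best = rmsecv.min()
    within = np.flatnonzero(rmsecv <= (1.0 + margin) * best)
    return int(within[0]) + 1


@dataclass
class RegressionEvaluation:
    """RMSEC/RMSEP, R2cal/R2pre and mean relative error (percent)."""

    rmsec: float
    rmsep: float
    r2_cal: float
    r2_pre: float
    re_percent: Optional[float]
    n_c: int
    n_p: int


def _rmse(y, yhat) -> float:
    resid = np.asarray(yhat) - np.asarray(y)
    return float(np.sqrt(np.mean(resid ** 2)))


def _r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    resid = np.asarray(yhat) - y
    sstot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid ** 2) / sstot)


def evaluate_regression(model: PLSRModel, X_cal, y_cal, X_val, y_val,
                        compute_re: bool = True) -> RegressionEvaluation:
    """Evaluate a fitted model on calibration and validation sets.

    R2 for each set uses that set's own measured mean; the relative error
    is the mean over validation samples of ``|yhat - y| / y * 100`` and
    is undefined (error) when any validation value is zero.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if y_cal.size < 1 or y_val.size < 1:
        raise ValidationError("calibration and validation sets must be non-empty")
    yhat_cal = plsr_predict(model, X_cal)
    yhat_val = plsr_predict(model, X_val)
    re_percent = None
    if compute_re:
        if np.any(y_val == 0):
            raise ValidationError("relative error undefined: zero validation value")
        re_percent = float(np.mean(np.abs(yhat_val - y_val) / np.abs(y_val)) * 100)
    return RegressionEvaluation(
        rmsec=_rmse(y_cal, yhat_cal), rmsep=_rmse(y_val, yhat_val),
        r2_cal=_r2(y_cal, yhat_cal), r2_pre=_r2(y_val, yhat_val),
        re_percent=re_percent, n_c=y_cal.size, n_p=y_val.size,
    )


@dataclass
class GridSearchResult:
    """Pretreatment grid outcome: one evaluation row per method."""

    table: pd.DataFrame
    selected: str
    models: dict = field(default_factory=dict)


def pretreatment_grid_search(spectra: SpectraMatrix, y, split: SplitResult,
                             methods: Sequence[PretreatmentSpec], cv_seed: int = 0,
                             k: int = 10, max_factors: int = 15,
                             margin: float = 0.02) -> GridSearchResult:
    """Compare pretreatments on a fixed calibration/validation split.

    For each method: fit pretreatment state on calibration spectra only,
    select the factor count by k-fold CV, fit, and evaluate on both sets.
    The selected method minimises RMSEP (ties: higher R2pre, then first
    listed).
    """
    if not methods:
        raise ValidationError("methods list must be non-empty")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != spectra.n_samples:
        raise ValidationError("response length does not match spectra")
    ytab = dict(zip(spectra.sample_ids, y))
    cal = spectra.subset(split.calibration_ids)
    val = spectra.subset(split.validation_ids)
    y_cal = np.array([ytab[s] for s in split.calibration_ids])
    y_val = np.array([ytab[s] for s in split.validation_ids])
    rows, models = [], {}
    for spec in methods:
        try:
            cal_t, state = apply_pretreatment(cal, spec)
            val_t, _ = apply_pretreatment(val, spec, state)
            a = select_n_factors(cal_t.absorbance, y_cal, max_factors,
                                 k=k, seed=cv_seed, margin=margin)
            model = fit_plsr(cal_t.absorbance, y_cal, a,
                             wavenumbers=spectra.wavenumbers,
                             pretreatment=spec, fitted_state=state)
            ev = evaluate_regression(model, cal_t.absorbance, y_cal,
                                     val_t.absorbance, y_val)
        except ValidationError as exc:
            raise ValidationError(f"pretreatment {spec.name!r}: {exc}") from exc
        models[spec.name] = model
        rows.append({"method": spec.name, "n_factors": a,
                     "rmsec": ev.rmsec, "r2_cal": ev.r2_cal,
                     "rmsep": ev.rmsep, "r2_pre": ev.r2_pre,
                     "re_percent": ev.re_percent})
    table = pd.DataFrame(rows)
    order = table.sort_values(["rmsep", "r2_pre"], ascending=[True, False],
                              kind="stable")
    selected = str(order.iloc[0]["method"])
    return GridSearchResult(table=table, selected=selected, models=models)
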