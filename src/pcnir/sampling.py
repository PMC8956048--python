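"""Calibration-set selection and Monte-Carlo outlier screening.

Two sample-management steps precede model building: the deterministic
Kennard-Stone max-min split into calibration and validation groups, and
Monte-Carlo cross-validation (MCCV) outlier screening, which repeatedly
refits an inner PLSR model on random subsets and flags samples whose
held-out prediction residuals have an anomalous mean or spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .spectra import SpectraMatrix


@dataclass
class SplitResult:
    """Disjoint calibration/validation id lists at a target ratio."""

    calibration_ids: list
    validation_ids: list
    ratio: float

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kennard-stone split, ratio {self.ratio:g}:1\n")
            fh.write("sample_id,group\n")
            for s in self.calibration_ids:
                fh.write(f"{s},calibration\n")
            for s in self.validation_ids:
                fh.write(f"{s},validation\n")


def kennard_stone_split(spectra: SpectraMatrix, ratio: float = 4.0,
                        distance: str = "euclidean") -> SplitResult:
    """Kennard-Stone selection of a calibration set at ``ratio``:1.

    The calibration size is ``round(n * ratio / (ratio + 1))``.  Selection
    is deterministic: the first two members are the most distant pair;
    each further member maximises its minimum distance to the selected
    set.  Ties resolve to the lowest sample index.
    """
    n = spectra.n_samples
    if n < 3:
        raise ValidationError("Kennard-Stone needs at least 3 samples")
    n_cal = int(round(n * ratio / (ratio + 1.0)))
    if n_cal < 2:
        raise ValidationError(f"calibration size {n_cal} < 2 at ratio {ratio:g}:1")
    if n_cal >= n:
        raise ValidationError("ratio leaves an empty validation group")
    d = cdist(spectra.absorbance, spectra.absorbance, metric=distance)
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)  # first max: lowest indices
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, d[nxt])
        min_dist[nxt] = -np.inf
    chosen = set(selected)
    ids = spectra.sample_ids
    return SplitResult(
        calibration_ids=[ids[k] for k in selected],
        validation_ids=[ids[k] for k in range(n) if k not in chosen],
        ratio=float(ratio),
    )


@dataclass
class OutlierReport:
    """Per-sample MCCV residual statistics and the flagged ids."""

    stats: pd.DataFrame  # sample_id, residual_mean, residual_sd, flagged
    flagged_ids: list
    n_rounds: int
    seed: int
    params: dict = field(default_factory=dict)

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mccv outlier report, seed {self.seed}, "
                     f"n_rounds {self.n_rounds}, params {self.params}\n")
            self.stats.to_csv(fh, index=False)


def mccv_outlier_detect(spectra: SpectraMatrix, y, n_rounds: int = 500,
                        cal_fraction: float = 0.8, n_factors: int = 5,
                        mean_k: float = 3.0, sd_k: float = 3.0,
                        seed: int = 0) -> OutlierReport:
    """Flag outliers by Monte-Carlo cross-validated prediction residuals.

    Each round draws a random ``cal_fraction`` subset, fits an inner PLSR
    model and records absolute prediction residuals for the held-out
    samples.  A sample is flagged when its residual mean exceeds
    ``mean(residual_means) + mean_k * sd(residual_means)`` or its residual
    sd exceeds the analogous ``sd_k`` threshold.  Fully reproducible
    given ``seed``.
    """
    from .plsr import fit_plsr, plsr_predict  # local import avoids a cycle

    x = spectra.absorbance
    y = np.asarray(y, dtype=float).ravel()
    n = spectra.n_samples
    if y.size != n or not np.all(np.isfinite(y)):
        raise ValidationError("reference values must be present for all samples")
    if n_rounds < 1:
        raise ValidationError("n_rounds must be >= 1")
    if not 0.0 < cal_fraction < 1.0:
        raise ValidationError("cal_fraction must be in (0, 1)")
    n_cal = int(round(cal_fraction * n))
    n_cal = min(max(n_cal, 2), n - 1)
    if n_factors > min(n_cal - 1, x.shape[1]):
        raise ValidationError(
            f"n_factors={n_factors} exceeds the rank bound for {n_cal} samples"
        )
    rng = np.random.default_rng(seed)
    residuals: list = [[] for _ in range(n)]
    for _ in range(n_rounds):
        perm = rng.permutation(n)
        cal, held = perm[:n_cal], perm[n_cal:]
        model = fit_plsr(x[cal], y[cal], n_factors)
        pred = plsr_predict(model, x[held])
        for idx, err in zip(held, np.abs(pred - y[held])):
            residuals[idx].append(err)
    counts = np.array([len(r) for r in residuals])
    if np.any(counts < 2):
        starved = [spectra.sample_ids[i] for i in np.flatnonzero(counts < 2)]
        raise ValidationError(
            f"samples held out fewer than twice: {starved}; increase n_rounds"
        )
    means = np.array([np.mean(r) for r in residuals])
    sds = np.array([np.std(r, ddof=1) for r in residuals])
    mean_thresh = means.mean() + mean_k * means.std(ddof=1)
    sd_thresh = sds.mean() + sd_k * sds.std(ddof=1)
    flagged = (means > mean_thresh) | (sds > sd_thresh)
    stats = pd.DataFrame({
        "sample_id": spectra.sample_ids,
        "residual_mean": means,
        "residual_sd": sds,
        "flagged": flagged,
    })
    return OutlierReport(
        stats=stats,
        flagged_ids=[s for s, f in zip(spectra.sample_ids, flagged) if f],
        n_rounds=n_rounds, seed=seed,
        params={"cal_fraction": cal_fraction, "n_factors": n_factors,
                "mean_k": mean_k, "sd_k": sd_k},
    )
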