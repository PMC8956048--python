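"""End-to-end study workflow: data -> outlier screen -> split -> models.

Stages run in the order of the original analysis: (optionally simulate or
load) spectra and reference chemistry, MCCV outlier screening per quality
parameter with global exclusion, Kennard-Stone 4:1 splitting on the
spectra, a pretreatment grid search with CV-selected PLSR factor counts
for each quality parameter, and random-forest region classification on
the shared split.  A single global seed fans out to per-stage seeds by
fixed offsets so disabling one stage does not shift another's stream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemistry import region_summary
from .errors import ValidationError
from .forest import classification_report, fit_random_forest, predict_regions
from .plsr import pretreatment_grid_search
from .preprocess import PRETREATMENTS, PretreatmentSpec, apply_pretreatment
from .sampling import kennard_stone_split, mccv_outlier_detect
from .spectra import (QUALITY_PARAMETERS, SampleTable, SpectraMatrix,
                      read_sample_table, read_spectra)
from .synth import SyntheticConfig, simulate_dataset

# Fixed per-stage seed offsets fanned out from the global seed.
_SEED_MCCV = 101
_SEED_CV = 202
_SEED_RF = 303


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one data source."""

    synthetic: Optional[SyntheticConfig] = None
    spectra_path: Optional[str] = None
    table_path: Optional[str] = None
    pretreatments: Sequence[str] = PRETREATMENTS
    responses: Sequence[str] = QUALITY_PARAMETERS
    outlier_screen: bool = True
    mccv_rounds: int = 500
    mccv_cal_fraction: float = 0.8
    mccv_factors: int = 5
    mccv_mean_k: float = 3.0
    mccv_sd_k: float = 3.0
    ks_ratio: float = 4.0
    cv_folds: int = 10
    max_factors: int = 15
    parsimony_margin: float = 0.02
    rf_trees: int = 500
    rf_features: Optional[int] = None
    rf_pretreatment: str = "SNV"
    sg_window: int = 11
    sg_polyorder: int = 2
    outdir: Optional[str] = None
    seed: int = 1

    def __post_init__(self):
        from_files = self.spectra_path is not None and self.table_path is not None
        if (self.synthetic is None) == (not from_files):
            raise ValidationError(
                "provide exactly one data source: synthetic config or file paths"
            )


def _load(config: RunConfig) -> tuple[SpectraMatrix, SampleTable]:
    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        return simulate_dataset(synth)
    spectra = read_spectra(config.spectra_path)
    table = read_sample_table(config.table_path)
    if set(spectra.sample_ids) != set(table.sample_ids):
        raise ValidationError("spectra and sample table ids disagree")
    return spectra, table.subset(spectra.sample_ids)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a JSON-serialisable manifest.

    The manifest records seeds and parameters, the outlier screen
    outcome, split sizes, the full pretreatment grid plus the selected
    model per quality parameter, and the classification report.  With
    ``config.outdir`` set, the grid tables, split, outlier report,
    classification table and per-set reference summaries are written as
    delimited text alongside ``manifest.json``.
    """
    spectra, table = _load(config)
    n_input = spectra.n_samples
    manifest: dict = {
        "seed": config.seed,
        "n_input": n_input,
        "parameters": {
            "pretreatments": list(config.pretreatments),
            "responses": list(config.responses),
            "mccv": {"enabled": config.outlier_screen,
                     "n_rounds": config.mccv_rounds,
                     "cal_fraction": config.mccv_cal_fraction,
                     "n_factors": config.mccv_factors,
                     "mean_k": config.mccv_mean_k, "sd_k": config.mccv_sd_k},
            "ks_ratio": config.ks_ratio,
            "cv_folds": config.cv_folds, "max_factors": config.max_factors,
            "rf": {"n_trees": config.rf_trees,
                   "pretreatment": config.rf_pretreatment},
        },
    }
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # outlier screen: per response, union of flags, excluded globally
    flagged: set = set()
    reports = {}
    if config.outlier_screen:
        for i, resp in enumerate(config.responses):
            report = mccv_outlier_detect(
                spectra, table.response(resp), n_rounds=config.mccv_rounds,
                cal_fraction=config.mccv_cal_fraction,
                n_factors=config.mccv_factors, mean_k=config.mccv_mean_k,
                sd_k=config.mccv_sd_k, seed=config.seed + _SEED_MCCV + i)
            reports[resp] = report
            flagged.update(report.flagged_ids)
            if outdir:
                report.write_csv(outdir / f"outliers_{resp}.csv")
    kept_ids = [s for s in spectra.sample_ids if s not in flagged]
    spectra = spectra.subset(kept_ids)
    table = table.subset(kept_ids)
    manifest["outliers"] = {"flagged_ids": sorted(flagged),
                            "n_flagged": len(flagged), "n_kept": len(kept_ids)}

    # one Kennard-Stone split shared by regression and classification
    split = kennard_stone_split(spectra, ratio=config.ks_ratio)
    manifest["split"] = {"n_calibration": len(split.calibration_ids),
                         "n_validation": len(split.validation_ids),
                         "ratio": split.ratio}
    if outdir:
        split.write_csv(outdir / "split.csv")

    # reference-value summary per set (the model-scope table)
    set_summary = []
    for name, ids in (("calibration", split.calibration_ids),
                      ("validation", split.validation_ids)):
        sub = table.subset(ids)
        for resp in config.responses:
            v = sub.response(resp)
            set_summary.append({"set": name, "index": resp, "n": len(ids),
                                "min": round(float(np.nanmin(v)), 2),
                                "max": round(float(np.nanmax(v)), 2),
                                "mean": round(float(np.nanmean(v)), 2),
                                "sd": round(float(np.nanstd(v, ddof=1)), 2)})
    set_summary = pd.DataFrame(set_summary)
    if outdir:
        set_summary.to_csv(outdir / "set_summary.csv", index=False)

    # pretreatment grid + quantitative models per quality parameter
    methods = [PretreatmentSpec(name, config.sg_window, config.sg_polyorder)
               for name in config.pretreatments]
    manifest["regression"] = {}
    grids = {}
    for resp in config.responses:
        grid = pretreatment_grid_search(
            spectra, table.response(resp), split, methods,
            cv_seed=config.seed + _SEED_CV, k=config.cv_folds,
            max_factors=config.max_factors, margin=config.parsimony_margin)
        grids[resp] = grid
        best = grid.table.set_index("method").loc[grid.selected]
        manifest["regression"][resp] = {
            "selected_method": grid.selected,
            "n_factors": int(best["n_factors"]),
            "rmsec": float(best["rmsec"]), "r2_cal": float(best["r2_cal"]),
            "rmsep": float(best["rmsep"]), "r2_pre": float(best["r2_pre"]),
            "re_percent": float(best["re_percent"]),
            "grid": grid.table.to_dict(orient="records"),
        }
        if outdir:
            grid.table.to_csv(outdir / f"grid_{resp}.csv", index=False)

    # region classification on the shared split
    rf_spec = PretreatmentSpec(config.rf_pretreatment, config.sg_window,
                               config.sg_polyorder)
    cal = spectra.subset(split.calibration_ids)
    val = spectra.subset(split.validation_ids)
    cal_t, state = apply_pretreatment(cal, rf_spec)
    val_t, _ = apply_pretreatment(val, rf_spec, state)
    labels = dict(zip(table.sample_ids, table.regions))
    forest = fit_random_forest(
        cal_t, [labels[s] for s in split.calibration_ids],
        n_trees=config.rf_trees, features_per_split=config.rf_features,
        seed=config.seed + _SEED_RF)
    predicted = predict_regions(forest, val_t)
    report = classification_report([labels[s] for s in split.validation_ids],
                                   predicted, split.validation_ids)
    manifest["classification"] = {
        "pretreatment": rf_spec.name,
        "accuracy_percent": report.accuracy_percent,
        "n_validation": len(split.validation_ids),
        "false_ids": report.false_ids,
    }
    if outdir:
        report.write_csv(outdir / "classification.csv")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
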