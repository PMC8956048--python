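"""Random-forest discrimination of cultivation regions from spectra.

Bagged classification trees (Gini splits over a random feature subset at
each node) voted by majority — the canonical random forest.  Tree growth
and bootstrap resampling are delegated to scikit-learn; this module owns
the region-specific surface: the fixed class order used for tie-breaking
(YN < XQ < DBM), deterministic seeding, and the per-sample comparison
report with its accuracy summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ValidationError
from .spectra import REGIONS, SpectraMatrix

#: Tie-break priority for majority votes.
CLASS_ORDER = REGIONS  # ("YN", "XQ", "DBM")


@dataclass
class ForestModel:
    """A fitted forest plus the metadata needed to reproduce predictions."""

    estimator: RandomForestClassifier
    classes: tuple
    n_trees: int
    features_per_split: int
    seed: int
    n_columns: int


def fit_random_forest(X, labels, n_trees: int = 500,
                      features_per_split: Optional[int] = None,
                      max_depth: Optional[int] = None, min_leaf: int = 1,
                      bootstrap: bool = True, oob: bool = False,
                      seed: int = 0) -> ForestModel:
    """Grow a bagged forest of Gini-split trees on (pretreated) spectra.

    ``features_per_split`` defaults to floor(sqrt(n_columns)).  Each tree
    trains on a bootstrap resample of the calibration rows (size n, with
    replacement) unless ``bootstrap`` is disabled.  Deterministic given
    ``seed``.
    """
    if isinstance(X, SpectraMatrix):
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.size != X.shape[0]:
        raise ValidationError(f"{labels.size} labels for {X.shape[0]} spectra")
    present = set(labels.tolist())
    if len(present) < 2:
        raise ValidationError("need at least 2 classes to train a classifier")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    if features_per_split is None:
        features_per_split = max(1, int(np.sqrt(X.shape[1])))
    if features_per_split > X.shape[1]:
        raise ValidationError(
            f"features_per_split={features_per_split} > {X.shape[1]} columns"
        )
    est = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features=features_per_split,
        max_depth=max_depth, min_samples_leaf=min_leaf, bootstrap=bootstrap,
        oob_score=oob and bootstrap, random_state=seed, n_jobs=1,
    )
    est.fit(X, labels)
    classes = tuple(c for c in CLASS_ORDER if c in present)
    classes += tuple(sorted(present - set(classes)))  # non-region labels last
    return ForestModel(estimator=est, classes=classes, n_trees=n_trees,
                       features_per_split=features_per_split, seed=seed,
                       n_columns=X.shape[1])


def predict_regions(model: ForestModel, X) -> np.ndarray:
    """Majority-vote labels; ties resolve by the fixed class order."""
    if isinstance(X, SpectraMatrix):
        X = X.absorbance
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_columns:
        raise ValidationError(
            f"{X.shape[1]} columns but model expects {model.n_columns}"
        )
    proba = model.estimator.predict_proba(X)
    cols = list(model.estimator.classes_)
    ordered = np.column_stack([proba[:, cols.index(c)] for c in model.classes])
    # np.argmax returns the first maximum, so column order encodes the
    # tie-break priority
    return np.asarray(model.classes)[np.argmax(ordered, axis=1)]


def oob_error(model: ForestModel) -> float:
    """Out-of-bag error rate (requires fitting with ``oob=True``)."""
    if not getattr(model.estimator, "oob_score_", None):
        raise ValidationError("forest was not fitted with oob=True")
    return 1.0 - float(model.estimator.oob_score_)


@dataclass
class ClassificationReport:
    """Per-sample reference/predicted comparison with accuracy summary."""

    table: pd.DataFrame          # sample_id, reference, predicted, correct
    confusion: pd.DataFrame      # reference rows x predicted columns, counts
    accuracy: float              # fraction correct
    accuracy_percent: float      # rounded to 2 decimals for display

    @property
    def false_ids(self) -> list:
        return list(self.table.loc[~self.table["correct"], "sample_id"])

    def write_csv(self, path) -> None:
        out = self.table.copy()
        out["result"] = np.where(out["correct"], "Correct", "False")
        with open(path, "w") as fh:
            fh.write(f"# classification accuracy {self.accuracy_percent:.2f}%\n")
            out[["sample_id", "reference", "predicted", "result"]].to_csv(
                fh, index=False)


def classification_report(reference: Sequence, predicted: Sequence,
                          ids: Optional[Sequence] = None) -> ClassificationReport:
    """Tabulate per-sample correctness and the overall accuracy."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.size != predicted.size:
        raise ValidationError("reference and predicted label lengths differ")
    if reference.size < 1:
        raise ValidationError("empty label vectors")
    if ids is None:
        ids = [f"sample{i + 1}" for i in range(reference.size)]
    correct = reference == predicted
    table = pd.DataFrame({"sample_id": list(ids), "reference": reference,
                          "predicted": predicted, "correct": correct})
    confusion = pd.crosstab(table["reference"], table["predicted"])
    accuracy = float(correct.mean())
    return ClassificationReport(table=table, confusion=confusion,
                                accuracy=accuracy,
                                accuracy_percent=round(100 * accuracy, 2))
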