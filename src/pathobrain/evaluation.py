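"""Confusion-matrix metrics and repeated stratified k-fold cross-validation.

The pathological class is the positive class throughout: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), accuracy
(TP+TN)/total.  Stratified folds keep the class mix of every fold
within one sample of perfect proportionality; "5 x 5-fold" means five
independent repetitions of 5-fold CV, seeded seed+0 .. seed+4.

Inside ``run_cv`` the PPCA reduction and the subspace ensemble are
refitted on each training fold only; wavelet features are per-image
deterministic transforms and may safely be computed once up front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from pathobrain import ensemble as ens_mod
from pathobrain import ppca as ppca_mod
from pathobrain.config import PipelineConfig

PATHOLOGICAL = "pathological"


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one case")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def confusion(
    y_true: Sequence, y_pred: Sequence, positive: str = PATHOLOGICAL
) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with ``positive`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionMatrix(
        TP=int(np.sum(t & p)), FN=int(np.sum(t & ~p)),
        FP=int(np.sum(~t & p)), TN=int(np.sum(~t & ~p)),
    )


@dataclass
class MetricReport:
    """Raw ratios in [0,1]; undefined ratios are NaN with a reason in
    ``undefined``.  ``percentages()`` rounds to two decimals for
    reporting."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    undefined: dict[str, str] = field(default_factory=dict)

    def percentages(self) -> tuple[float, float, float, float]:
        return tuple(
            round(100.0 * r, 2) if math.isfinite(r) else float("nan")
            for r in (self.sensitivity, self.specificity, self.precision, self.accuracy)
        )


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity, specificity, precision and accuracy of a confusion matrix."""
    undefined: dict[str, str] = {}

    def ratio(num: int, den: int, name: str, reason: str) -> float:
        if den == 0:
            undefined[name] = reason
            return float("nan")
        return num / den

    return MetricReport(
        sensitivity=ratio(cm.TP, cm.TP + cm.FN, "sensitivity", "no positive cases"),
        specificity=ratio(cm.TN, cm.TN + cm.FP, "specificity", "no negative cases"),
        precision=ratio(cm.TP, cm.TP + cm.FP, "precision", "no positive predictions"),
        accuracy=ratio(cm.TP + cm.TN, cm.total, "accuracy", "empty matrix"),
        undefined=undefined,
    )


@dataclass
class CVPlan:
    """Fold assignments: shape (n_repeats, n_samples) of fold ids."""

    n_folds: int
    n_repeats: int
    seed: int
    fold_assignments: np.ndarray

    def validation_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments[repeat] == fold)

    def training_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments[repeat] != fold)


def stratified_kfold(labels: Sequence, n_folds: int, seed: int) -> CVPlan:
    """One repeat of a stratified k-fold partition.

    Within each class the (seeded-shuffled) samples are dealt
    round-robin onto the folds, with the starting fold rotating across
    classes so that total fold sizes also differ by at most one.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assign = np.full(n, -1, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples, fewer than n_folds={n_folds}"
            )
        rng.shuffle(idx)
        assign[idx] = (np.arange(len(idx)) + offset) % n_folds
        offset = (offset + len(idx)) % n_folds
    return CVPlan(
        n_folds=n_folds, n_repeats=1, seed=seed,
        fold_assignments=assign[None, :],
    )


def make_cv_plan(labels: Sequence, n_folds: int, n_repeats: int, seed: int) -> CVPlan:
    """``n_repeats`` independent stratified partitions, seeds seed+r."""
    repeats = [stratified_kfold(labels, n_folds, seed + r) for r in range(n_repeats)]
    return CVPlan(
        n_folds=n_folds, n_repeats=n_repeats, seed=seed,
        fold_assignments=np.vstack([p.fold_assignments for p in repeats]),
    )


@dataclass
class CVResult:
    rows: pd.DataFrame              # repeat, fold, TP, FN, FP, TN, metrics
    per_repeat_accuracy: np.ndarray
    mean_accuracy: float            # grand mean over repeats, percent

    def to_csv(self, path: Union[str, Path]) -> None:
        self.rows.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            f"repeats={len(self.per_repeat_accuracy)} "
            f"folds={self.rows['fold'].nunique()}",
            "per-repeat accuracy (%): "
            + ", ".join(f"{a:.2f}" for a in self.per_repeat_accuracy),
            f"mean accuracy: {self.mean_accuracy:.2f}%",
        ]
        return "\n".join(lines)


def run_cv(
    X: np.ndarray,
    y: Sequence,
    config: PipelineConfig,
    plan: CVPlan,
) -> CVResult:
    """Cross-validate the PPCA + random-subspace-ensemble stages.

    For every repeat and fold, PPCA and the ensemble are fitted on the
    training portion only, then scored on the held-out fold.  Per-repeat
    accuracy pools the confusion counts of that repeat's folds; the
    headline is the mean over repeats.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if plan.fold_assignments.shape[1] != len(y):
        raise ValueError("CV plan does not match the number of samples")
    config.validate()

    records = []
    per_repeat = []
    for r in range(plan.n_repeats):
        rep_counts = np.zeros(4, dtype=int)
        for f in range(plan.n_folds):
            tr = plan.training_indices(r, f)
            va = plan.validation_indices(r, f)
            model = ppca_mod.fit_ppca(
                X[tr], k=config.ppca_k, tol=config.ppca_tol,
                max_iter=config.ppca_max_iter, seed=config.seed + r,
            )
            Z_tr = ppca_mod.transform(model, X[tr])
            Z_va = ppca_mod.transform(model, X[va])
            ens = ens_mod.fit_ensemble(
                Z_tr, y[tr], n_members=config.n_members,
                subspace_dim=config.subspace_dim, K=config.K,
                seed=config.seed + r, tie_rule=config.tie_rule,
            )
            cm = confusion(y[va], ens_mod.predict(ens, Z_va))
            rep = metrics(cm)
            sens, spec, prec, acc = rep.percentages()
            records.append(dict(
                repeat=r, fold=f, TP=cm.TP, FN=cm.FN, FP=cm.FP, TN=cm.TN,
                sensitivity=sens, specificity=spec, precision=prec, accuracy=acc,
            ))
            rep_counts += (cm.TP, cm.FN, cm.FP, cm.TN)
        tp, fn, fp, tn = rep_counts
        per_repeat.append(100.0 * (tp + tn) / rep_counts.sum())

    per_repeat = np.asarray(per_repeat)
    return CVResult(
        rows=pd.DataFrame.from_records(records),
        per_repeat_accuracy=per_repeat,
        mean_accuracy=float(per_repeat.mean()),
    )
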