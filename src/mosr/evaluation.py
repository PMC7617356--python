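"""Model-assessment protocol for imbalanced binary outcomes.

Implements the metric panel (accuracy, sensitivity, specificity, F1, PPV,
NPV, AUC), probability-calibration bins, grid-search 10-fold
cross-validation with an inner 90/10 train/validation division, repeated
evaluation on random 90% test subsets, and train-test gap computation.

Metrics with an empty denominator (0/0) are reported as ``None`` rather
than silently coerced to 0, with one exception: F1 follows the standard
convention of 0 when TP = 0 while FP + FN > 0.  AUC uses the Mann-Whitney
formulation (probability that a random positive outscores a random
negative, ties counting one half).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from ._rng import substream

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CalibrationBin",
    "CVPlan",
    "confusion",
    "metric_panel",
    "roc_auc",
    "calibration_bins",
    "grid_search_cv",
    "repeated_test_eval",
    "overfit_gap",
    "evaluate_probabilities",
]

SCALAR_METRICS = ("accuracy", "sensitivity", "specificity", "f1", "ppv", "npv", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Scalar metric panel; undefined (0/0) metrics are ``None``."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    ppv: float | None = None
    npv: float | None = None
    auc: float | None = None
    calibration: list["CalibrationBin"] = field(default_factory=list)

    def scalars(self) -> dict[str, float | None]:
        d = asdict(self)
        d.pop("calibration")
        return d


@dataclass(frozen=True)
class CalibrationBin:
    lower: float
    upper: float
    mean_predicted: float | None
    observed_rate: float | None
    count: int


@dataclass
class CVPlan:
    """Grid-search cross-validation plan: ``folds`` outer stratified folds,
    an inner ``inner_fraction``/(1-inner_fraction) train/validation division
    inside each fold's training portion, and a named hyperparameter grid."""

    folds: int = 10
    inner_fraction: float = 0.9
    grid: dict[str, Sequence] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("CVPlan.folds must be >= 2")
        if not 0 < self.inner_fraction < 1:
            raise ValueError("CVPlan.inner_fraction must be in (0, 1)")


def _validate_labels(labels, probabilities):
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.shape != probabilities.shape:
        raise ValueError(
            f"length mismatch: {labels.shape[0]} labels vs "
            f"{probabilities.shape[0]} probabilities")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int), probabilities


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion table; prediction is 1 iff p >= threshold."""
    y, p = _validate_labels(labels, probabilities)
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metric_panel(counts: ConfusionCounts) -> MetricsReport:
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp == 0 and fp + fn > 0:
        f1 = 0.0
    else:
        f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    return MetricsReport(
        accuracy=(tp + tn) / counts.total,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        f1=f1,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def roc_auc(labels, scores) -> float | None:
    """Mann-Whitney AUC; ``None`` when only one class is present."""
    y, s = _validate_labels(labels, scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def calibration_bins(labels, probabilities, n_bins: int = 10) -> list[CalibrationBin]:
    """Equal-width probability bins on [0, 1]; the last bin is right-closed.
    Empty bins are kept (count 0) so the bin grid is always complete."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y, p = _validate_labels(labels, probabilities)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        out.append(CalibrationBin(
            lower=float(edges[b]),
            upper=float(edges[b + 1]),
            mean_predicted=float(p[mask].mean()) if count else None,
            observed_rate=float(y[mask].mean()) if count else None,
            count=count,
        ))
    return out


def evaluate_probabilities(labels, probabilities, threshold: float = 0.5,
                           n_bins: int = 10) -> MetricsReport:
    """Full report (panel + AUC + calibration) for one set of predictions."""
    report = metric_panel(confusion(labels, probabilities, threshold))
    report.auc = roc_auc(labels, probabilities)
    report.calibration = calibration_bins(labels, probabilities, n_bins)
    return report


# ---------------------------------------------------------------------------
# stratified allocation helpers (shared with preprocess.stratified_split)

def stratified_allocation(class_sizes: dict, fraction: float) -> dict:
    """Per-class training-seat counts: floor(fraction * size) per class, then
    the seats still needed to reach round(fraction * total) go to classes in
    decreasing order of size."""
    total = sum(class_sizes.values())
    n_train = round(fraction * total)
    alloc = {c: math.floor(fraction * n) for c, n in class_sizes.items()}
    order = sorted(class_sizes, key=lambda c: (-class_sizes[c], str(c)))
    i = 0
    while sum(alloc.values()) < n_train:
        c = order[i % len(order)]
        if alloc[c] < class_sizes[c]:
            alloc[c] += 1
        i += 1
    return alloc


def stratified_subset_indices(y: np.ndarray, fraction: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified ``fraction``-sized subset, drawn without
    replacement with the same allocation rule as the 80/20 split."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    alloc = stratified_allocation(dict(zip(classes.tolist(), counts.tolist())), fraction)
    picked = []
    for c in classes.tolist():
        members = np.flatnonzero(y == c)
        picked.append(rng.permutation(members)[: alloc[c]])
    return np.sort(np.concatenate(picked))


# ---------------------------------------------------------------------------
# protocols

def grid_search_cv(X: pd.DataFrame, y, plan: CVPlan,
                   trainer: Callable) -> tuple[dict, pd.DataFrame]:
    """Grid search with stratified k-fold CV and an inner 90/10 division.

    ``trainer(X_train, y_train, X_val, y_val, params, seed) -> model`` must
    return an object whose positive-class probabilities ``_pos_probs`` can
    extract.  Within each fold, the fold's training portion is divided
    ``inner_fraction``/(1 - inner_fraction) (stratified); the inner
    validation part feeds the trainer's own model selection.  Each setting
    is scored by its mean F1 on the fold hold-outs; ties go to the first
    setting in grid order.
    """
    if not plan.grid:
        raise ValueError("empty hyperparameter grid")
    y = np.asarray(y).astype(int)
    names = list(plan.grid)
    settings = [dict(zip(names, combo))
                for combo in itertools.product(*(plan.grid[n] for n in names))]

    skf = StratifiedKFold(n_splits=plan.folds, shuffle=True,
                          random_state=substream(plan.seed, "cv").integers(0, 2**31 - 1))
    try:
        folds = list(skf.split(np.zeros(len(y)), y))
    except ValueError as exc:
        raise ValueError(
            f"stratified folding failed ({exc}); a fold would contain a "
            f"single outcome class — use fewer folds") from exc
    for k, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(
                f"fold {k} contains a single outcome class; use fewer folds")

    rows = []
    best_params, best_score = None, -np.inf
    for si, params in enumerate(settings):
        fold_f1 = []
        for k, (tr, te) in enumerate(folds):
            rng = substream(plan.seed, "cv")
            inner = stratified_subset_indices(y[tr], plan.inner_fraction, rng)
            inner_mask = np.zeros(len(tr), dtype=bool)
            inner_mask[inner] = True
            it, iv = tr[inner_mask], tr[~inner_mask]
            model = trainer(X.iloc[it], y[it], X.iloc[iv], y[iv], params,
                            int(substream(plan.seed, "cv").integers(0, 2**31 - 1)) + k)
            p = _pos_probs(model, X.iloc[te])
            rep = metric_panel(confusion(y[te], p))
            fold_f1.append(rep.f1 if rep.f1 is not None else 0.0)
        mean_f1 = float(np.mean(fold_f1))
        rows.append({**params, "mean_f1": mean_f1,
                     "sd_f1": float(np.std(fold_f1, ddof=1)) if len(fold_f1) > 1 else 0.0})
        if mean_f1 > best_score:
            best_score, best_params = mean_f1, params
    return best_params, pd.DataFrame(rows)


def _pos_probs(model, X) -> np.ndarray:
    if callable(model) and not hasattr(model, "predict_proba"):
        return np.asarray(model(X), dtype=float)
    p = np.asarray(model.predict_proba(X), dtype=float)
    if p.ndim == 2:
        p = p[:, -1]
    return p


def repeated_test_eval(model, X: pd.DataFrame, y, runs: int = 10,
                       fraction: float = 0.9, seed: int = 0,
                       threshold: float = 0.5,
                       ) -> tuple[dict, list[MetricsReport]]:
    """Average test metrics over ``runs`` random stratified subsets.

    Each run draws a fresh ``fraction``-sized stratified subset of the test
    set without replacement, evaluates the full panel, and the arithmetic
    mean and SD per metric are reported; undefined metrics are excluded
    from the averages with an exclusion count.
    """
    y = np.asarray(y).astype(int)
    if len(y) == 0 or len(np.unique(y)) < 2:
        raise ValueError("test set must be non-empty with both classes")
    reports = []
    for r in range(runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(9, r)))  # test_eval stream
        idx = stratified_subset_indices(y, fraction, rng)
        if len(np.unique(y[idx])) < 2:
            idx = stratified_subset_indices(y, fraction, rng)
            if len(np.unique(y[idx])) < 2:
                raise ValueError("test subset lost an outcome class")
        p = _pos_probs(model, X.iloc[idx])
        reports.append(evaluate_probabilities(y[idx], p, threshold))
    summary: dict[str, dict] = {}
    for m in SCALAR_METRICS:
        vals = [getattr(r, m) for r in reports]
        ok = [v for v in vals if v is not None]
        summary[m] = {
            "mean": float(np.mean(ok)) if ok else None,
            "sd": float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0,
            "n_undefined": len(vals) - len(ok),
        }
    return summary, reports


def overfit_gap(train_report: MetricsReport | Mapping,
                test_report: MetricsReport | Mapping) -> dict[str, float | None]:
    """Per-metric train minus test difference (``None`` where undefined)."""

    def get(rep, m):
        if isinstance(rep, MetricsReport):
            return getattr(rep, m)
        return rep[m]["mean"] if isinstance(rep[m], Mapping) else rep[m]

    out = {}
    for m in SCALAR_METRICS:
        a, b = get(train_report, m), get(test_report, m)
        out[m] = None if a is None or b is None else a - b
    return out
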