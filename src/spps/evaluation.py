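"""Cross-validated evaluation of the pair classifier.

Performance is summarized by the four confusion-matrix ratios
sensitivity SE = TP/(TP+FN), specificity SP = TN/(TN+FP), precision
PRE = TP/(TP+FP) and accuracy ACC = (TP+TN)/(TP+TN+FP+FN), estimated
by stratified 5-fold cross-validation: each fold's model is trained
(including a fresh probability calibration) on the other folds and its
held-out pairs are classified at the 0.5 probability threshold.

A ratio with a zero denominator is reported as missing (NaN), never as
zero; fold means skip missing folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    POSITIVE_LABEL,
    PPIDataset,
    SVMParams,
    train_svm,
)
from .exceptions import ValidationError
from .protein_db import ProteinDatabase
from .search import PROBABILITY_THRESHOLD

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """SE, SP, PRE, ACC; missing (undefined) ratios are NaN."""

    se: float
    sp: float
    pre: float
    acc: float


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.info("metric %s undefined (zero denominator); reported missing", name)
        return math.nan
    return num / den


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate the four ratio definitions exactly.

    Zero-denominator cases (e.g. PRE with no predicted positives)
    yield NaN with a logged note.
    """
    return MetricSet(
        se=_ratio(c.tp, c.tp + c.fn, "SE"),
        sp=_ratio(c.tn, c.tn + c.fp, "SP"),
        pre=_ratio(c.tp, c.tp + c.fp, "PRE"),
        acc=_ratio(c.tp + c.tn, c.total, "ACC"),
    )


@dataclass
class CrossValidationResult:
    """Per-fold metrics and counts, their mean, and the pooled metrics."""

    per_fold: List[MetricSet]
    per_fold_counts: List[ConfusionCounts]
    mean: MetricSet
    pooled: MetricSet
    pooled_counts: ConfusionCounts
    k: int
    seed: int
    split: str


def _nanmean(values: List[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if np.all(np.isnan(arr)):
        return math.nan
    return float(np.nanmean(arr))


def _mean_metrics(folds: List[MetricSet]) -> MetricSet:
    return MetricSet(
        se=_nanmean([m.se for m in folds]),
        sp=_nanmean([m.sp for m in folds]),
        pre=_nanmean([m.pre for m in folds]),
        acc=_nanmean([m.acc for m in folds]),
    )


def _count_fold(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos = y_true == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int((y_pred[pos] == 1).sum()),
        fn=int((y_pred[pos] == 0).sum()),
        tn=int((y_pred[~pos] == 0).sum()),
        fp=int((y_pred[~pos] == 1).sum()),
    )


def _pair_folds(labels: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    idx = np.arange(len(labels))
    for _, test in skf.split(idx.reshape(-1, 1), labels):
        yield test


def _protein_disjoint_folds(data: PPIDataset, k: int, seed: int):
    """Assign proteins to k groups; fold i tests pairs whose both
    endpoints fall in group i.  Pairs spanning groups are evaluated in
    no fold (their training use is still leakage-free because the test
    fold's proteins never appear in its training pairs)."""
    proteins = sorted({p for a, b, _ in data.pairs for p in (a, b)})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    group = {proteins[j]: i % k for i, j in enumerate(order)}
    for i in range(k):
        test = [
            idx for idx, (a, b, _) in enumerate(data.pairs)
            if group[a] == i and group[b] == i
        ]
        yield np.asarray(test, dtype=int)


def cross_validate(
    data: PPIDataset,
    db: ProteinDatabase,
    params: Optional[SVMParams] = None,
    k: int = 5,
    seed: int = 0,
    split: str = "pair",
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of the pair classifier.

    Parameters
    ----------
    data, db
        Labeled pairs and the sequence store they resolve in.
    params
        Classifier hyperparameters; the per-fold training includes a
        fresh Platt calibration on that fold's training pairs.
    k
        Number of folds (default 5); every class needs >= k members.
    seed
        Controls fold assignment; the run is reproducible bit-for-bit
        given (data, seed, params).
    split
        ``"pair"`` (default): stratified split over pairs.
        ``"protein_disjoint"``: proteins are partitioned into k groups
        and fold i evaluates only pairs entirely inside group i, so no
        protein is shared between a test pair and any training pair.
    """
    if k < 2:
        raise ValidationError("cross-validation needs k >= 2")
    n_pos, n_neg = data.class_counts()
    if min(n_pos, n_neg) < k:
        raise ValidationError(
            f"each class needs >= {k} members for {k}-fold CV "
            f"(got {n_pos} positive / {n_neg} negative)"
        )
    params = params or SVMParams()
    labels = data.labels

    if split == "pair":
        fold_iter = _pair_folds(labels, k, seed)
    elif split == "protein_disjoint":
        fold_iter = _protein_disjoint_folds(data, k, seed)
    else:
        raise ValidationError(f"unknown split mode {split!r}")

    per_fold: List[MetricSet] = []
    per_counts: List[ConfusionCounts] = []
    for test_idx in fold_iter:
        test_set = set(test_idx.tolist())
        train_pairs = [p for i, p in enumerate(data.pairs) if i not in test_set]
        test_pairs = [data.pairs[i] for i in test_idx]
        if not test_pairs:
            continue
        model = train_svm(PPIDataset(train_pairs), db, params=params)
        y_true = np.array([y for _, _, y in test_pairs])
        y_pred = np.array([
            int(
                model.predict_probability(db.sequence(a), db.sequence(b))
                > PROBABILITY_THRESHOLD
            )
            for a, b, _ in test_pairs
        ])
        counts = _count_fold(y_true, y_pred)
        per_counts.append(counts)
        per_fold.append(confusion_metrics(counts))

    pooled_counts = per_counts[0]
    for c in per_counts[1:]:
        pooled_counts = pooled_counts + c
    return CrossValidationResult(
        per_fold=per_fold,
        per_fold_counts=per_counts,
        mean=_mean_metrics(per_fold),
        pooled=confusion_metrics(pooled_counts),
        pooled_counts=pooled_counts,
        k=k,
        seed=seed,
        split=split,
    )


def report_table(result: CrossValidationResult):
    """Per-fold and mean SE/SP/PRE/ACC as a DataFrame for reporting."""
    import pandas as pd

    rows = [
        {"fold": i + 1, "se": m.se, "sp": m.sp, "pre": m.pre, "acc": m.acc}
        for i, m in enumerate(result.per_fold)
    ]
    rows.append({
        "fold": "mean",
        "se": result.mean.se, "sp": result.mean.sp,
        "pre": result.mean.pre, "acc": result.mean.acc,
    })
    return pd.DataFrame(rows, columns=["fold", "se", "sp", "pre", "acc"])
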