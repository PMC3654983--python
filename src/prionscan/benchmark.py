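"""Statistical calibration of the classifier.

Implements the full benchmarking stack used to calibrate the scanner:
confusion-matrix metrics (TPR, FPR, accuracy, precision, FDR), ROC curves
with trapezoid AUC, the AUC / Mann-Whitney rank-sum equivalence cross-check,
precision-recall under class skew, accuracy-versus-cutoff selection of the
operating point, half-exclusion bootstrap of the training set with vertical
ROC averaging, and randomization z-scores for category enrichment.

A call is positive when ``score >= cutoff``.  Undefined ratios (zero
denominators) are reported as NaN sentinels, never raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from sklearn import metrics as _skm

logger = logging.getLogger(__name__)

NAN = float("nan")


@dataclass
class LabeledScore:
    """One benchmark observation: a score in bits with its true class."""

    score: float
    label: bool  # True = positive
    id: str = ""


def split_labeled(scores: Iterable[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s.score for s in scores if s.label], dtype=float)
    neg = np.array([s.score for s in scores if not s.label], dtype=float)
    return pos, neg


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.FP + self.TN


@dataclass
class BenchmarkMetrics:
    tpr: float
    fpr: float
    accuracy: float
    precision: float
    fdr: float


def confusion_at_cutoff(
    pos_scores: np.ndarray, neg_scores: np.ndarray, cutoff: float
) -> ConfusionCounts:
    """Confusion counts with the rule ``score >= cutoff -> positive call``."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    tp = int(np.count_nonzero(pos >= cutoff))
    fp = int(np.count_nonzero(neg >= cutoff))
    return ConfusionCounts(TP=tp, FP=fp, TN=neg.size - fp, FN=pos.size - tp)


def metrics(counts: ConfusionCounts) -> BenchmarkMetrics:
    """TPR, FPR, accuracy, precision and FDR; NaN where undefined."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else NAN

    return BenchmarkMetrics(
        tpr=ratio(counts.TP, counts.TP + counts.FN),
        fpr=ratio(counts.FP, counts.FP + counts.TN),
        accuracy=ratio(counts.TP + counts.TN, counts.P + counts.N),
        precision=ratio(counts.TP, counts.TP + counts.FP),
        fdr=ratio(counts.FP, counts.FP + counts.TP),
    )


@dataclass
class ROCCurve:
    """ROC staircase from (0,0) to (1,1) with trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(pos_scores: np.ndarray, neg_scores: np.ndarray) -> ROCCurve:
    """ROC over every distinct score threshold; ties move together.

    Identical scores everywhere give the pure diagonal (AUC 0.5), not an
    error.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_skm.auc(fpr, tpr)))


def auc_equals_rank_sum_check(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[float, float]:
    """Two independent routes to the same quantity.

    Returns (trapezoid AUC of the ROC curve, Mann-Whitney U of the positives
    over n_pos * n_neg with tie midpoints).  The two are algebraically equal;
    they must agree to 1e-12.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    auc = roc_curve(pos, neg).auc
    u = float(
        _stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").statistic
    )
    return auc, u / (pos.size * neg.size)


def precision_recall_curve(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(recall, precision, thresholds), one point per distinct threshold.

    Recall is ascending and the curve stops at the first threshold reaching
    full recall (lower thresholds only add false positives at recall 1).
    Robust to extreme class skew.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    precision, recall, thresholds = _skm.precision_recall_curve(y, s)
    # sklearn orders by ascending threshold (descending recall) and appends a
    # terminal (recall=0, precision=1) point with no threshold: drop it and
    # reorder so that precision[i]/recall[i] correspond to thresholds[i].
    precision = precision[:-1][::-1]
    recall = recall[:-1][::-1]
    thresholds = thresholds[::-1]
    full = np.flatnonzero(recall >= 1.0)
    if full.size:
        stop = full[0] + 1
        precision, recall, thresholds = precision[:stop], recall[:stop], thresholds[:stop]
    return recall, precision, thresholds


def accuracy_vs_cutoff(
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    cutoff_grid: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Accuracy at each cutoff of a grid, plus the argmax cutoff.

    Ties are broken toward the largest cutoff (the most conservative
    operating point).  Returns (table of shape (n, 2) with columns cutoff
    and accuracy, best_cutoff).
    """
    grid = np.asarray(cutoff_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("cutoff grid must be non-empty")
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    tp = (pos[None, :] >= grid[:, None]).sum(axis=1)
    fp = (neg[None, :] >= grid[:, None]).sum(axis=1)
    acc = (tp + (neg.size - fp)) / (pos.size + neg.size)
    best = float(grid[acc == acc.max()].max())
    return np.column_stack([grid, acc]), best


def rank_sum_test(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Exact enumeration when n_pos * n_neg <= 400 and the pooled scores are
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U of the positives, p-value, method label).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    pooled = np.concatenate([pos, neg])
    has_ties = np.unique(pooled).size < pooled.size
    if pos.size * neg.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


@dataclass
class BootstrapResult:
    """Vertically averaged ROC over resampled training/test splits."""

    n_iterations: int
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray
    auc_samples: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.auc_samples.mean())


def bootstrap_roc(
    positives: Sequence,
    negatives: Sequence,
    build_scorer: Callable[[Sequence], Callable[[Sequence], np.ndarray]],
    n_iterations: int = 10_000,
    seed=None,
    sample_with_replacement: bool = False,
    n_grid: int = 101,
) -> BootstrapResult:
    """Half-exclusion bootstrap of the positive training set.

    Each iteration splits the positives into two disjoint halves uniformly
    at random: the scorer is rebuilt from one half (``build_scorer`` is the
    training pipeline) and evaluated on the excluded half against the fixed
    negative set.  Per-iteration ROC curves are averaged vertically on a
    fixed FPR grid.  ``sample_with_replacement`` resamples the training half
    with replacement (a true bootstrap of the retained half) instead of
    using it as-is.
    """
    positives = list(positives)
    negatives = list(negatives)
    n = len(positives)
    if n < 4 or n % 2:
        raise ValueError(
            "positive set must have even size >= 4; pass explicit train/test "
            "sets for odd sizes"
        )
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_grid)
    tpr_sum = np.zeros(n_grid)
    tpr_sq = np.zeros(n_grid)
    aucs = np.empty(n_iterations)
    half = n // 2
    for it in range(n_iterations):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:half], perm[half:]
        if sample_with_replacement:
            train_idx = rng.choice(train_idx, size=half, replace=True)
        scorer = build_scorer([positives[i] for i in train_idx])
        pos_scores = np.asarray(scorer([positives[i] for i in test_idx]), dtype=float)
        neg_scores = np.asarray(scorer(negatives), dtype=float)
        curve = roc_curve(pos_scores, neg_scores)
        interp = np.interp(grid, curve.fpr, curve.tpr)
        tpr_sum += interp
        tpr_sq += interp**2
        aucs[it] = curve.auc
    mean = tpr_sum / n_iterations
    var = np.maximum(tpr_sq / n_iterations - mean**2, 0.0)
    return BootstrapResult(
        n_iterations=n_iterations,
        fpr_grid=grid,
        mean_tpr=mean,
        sd_tpr=np.sqrt(var),
        auc_samples=aucs,
    )


@dataclass
class EnrichmentResult:
    category: str
    observed: int
    null_mean: float
    null_sd: float
    z: float  # NaN when the null spread is zero


def enrichment_zscores(
    universe: Mapping[str, Iterable[str]],
    selection: Sequence[str],
    n_randomizations: int = 10_000,
    seed=None,
) -> list[EnrichmentResult]:
    """Randomization z-scores for category enrichment in a selection.

    ``universe`` maps every id to its (possibly multiple) category labels;
    ``selection`` is the predicted subset.  The null redraws ``|selection|``
    ids from the universe without replacement ``n_randomizations`` times and
    the z-score is computed parametrically from the null mean and standard
    deviation per category.
    """
    if n_randomizations < 100:
        raise ValueError("need at least 100 randomizations")
    ids = list(universe.keys())
    id_index = {i: k for k, i in enumerate(ids)}
    missing = [s for s in selection if s not in id_index]
    if missing:
        raise ValueError(f"selection ids not in universe: {missing[:5]}")
    categories = sorted({c for labels in universe.values() for c in labels})
    cat_index = {c: j for j, c in enumerate(categories)}
    member = np.zeros((len(ids), len(categories)), dtype=np.int32)
    for i, key in enumerate(ids):
        for c in universe[key]:
            member[i, cat_index[c]] = 1
    k = len(selection)
    sel_rows = np.array([id_index[s] for s in selection])
    observed = member[sel_rows].sum(axis=0)

    rng = np.random.default_rng(seed)
    sums = np.zeros(len(categories))
    sq = np.zeros(len(categories))
    n_ids = len(ids)
    for _ in range(n_randomizations):
        draw = rng.choice(n_ids, size=k, replace=False)
        c = member[draw].sum(axis=0)
        sums += c
        sq += c.astype(float) ** 2
    mean = sums / n_randomizations
    var = np.maximum(sq / n_randomizations - mean**2, 0.0)
    sd = np.sqrt(var * n_randomizations / max(n_randomizations - 1, 1))

    results = []
    for j, cat in enumerate(categories):
        z = (observed[j] - mean[j]) / sd[j] if sd[j] > 0 else NAN
        results.append(
            EnrichmentResult(
                category=cat,
                observed=int(observed[j]),
                null_mean=float(mean[j]),
                null_sd=float(sd[j]),
                z=float(z),
            )
        )
    return results
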