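"""Chunk sets as single-word classifiers: precision/recall/F, N-sweeps, bootstrap CIs.

Framing chunk selection as classification: MSUs inside a chunk set are
labeled *word*, those outside *non-word*; ground truth is whether the MSU's
word list has length one.  With N the chunk-set size, W_C the single-word
MSUs inside the set and W those outside,

    precision = W_C / N,    recall = W_C / (W_C + W),

and the F-score is their harmonic mean (0 when both are 0).  Percentile
bootstrap confidence intervals resample the labeled MSU pool with
replacement (one data point per MSU type); within a resample precision's
denominator is the resample's in-set count.  Difference CIs evaluate both
metrics on the same resamples, so identical metrics give an identically
zero difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .chunk_selection import ChunkSet, MSURecord, METRICS


@dataclass(frozen=True)
class ClassificationOutcome:
    metric: str
    N: int
    W_C: int
    W: int
    precision: float
    recall: float
    f_score: float


@dataclass(frozen=True)
class BootstrapCI:
    """A point estimate with a 2.5th–97.5th percentile interval.

    ``n_excluded`` counts resamples on which the statistic was undefined
    (e.g. a resample drew no in-set items); those are excluded from the
    percentiles.
    """

    point: float
    lo: float
    hi: float
    n_resamples: int
    n_excluded: int = 0

    @property
    def significant(self) -> bool:
        """True when the 95% interval excludes zero."""
        return not (self.lo <= 0.0 <= self.hi)


def label_single_word_msus(records: Sequence[MSURecord]) -> dict[MSURecord, bool]:
    """True iff the MSU is a single-word utterance."""
    return {r: r.is_single_word for r in records}


def _prf(n_in_set: int, w_c: int, w: int) -> tuple[float, float, float]:
    precision = w_c / n_in_set if n_in_set else float("nan")
    total_words = w_c + w
    recall = w_c / total_words if total_words else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f


def precision_recall_f(
    cs: ChunkSet, labels: Mapping[MSURecord, bool]
) -> ClassificationOutcome:
    """Score a chunk set against single-word labels covering the whole pool."""
    if len(cs.members) == 0:
        raise ValueError("chunk set is empty")
    member_keys = {r.syllables for r in cs.members}
    w_c = sum(1 for r in cs.members if labels[r])
    total_words = sum(1 for r, is_word in labels.items() if is_word)
    w = total_words - sum(
        1 for r, is_word in labels.items() if is_word and r.syllables in member_keys
    )
    precision, recall, f = _prf(len(cs.members), w_c, w)
    return ClassificationOutcome(
        metric=cs.metric, N=len(cs.members), W_C=w_c, W=w,
        precision=precision, recall=recall, f_score=f,
    )


def sweep_classification(
    records: Sequence[MSURecord],
    metrics: Sequence[str] = METRICS,
    N_grid: Sequence[int] = (),
) -> list[ClassificationOutcome]:
    """One classification outcome per (metric, N) cell.

    At N equal to the pool size every metric selects the same member set,
    so the three rows coincide and recall is exactly 1.
    """
    from .chunk_selection import rank_and_select

    if list(N_grid) != sorted(N_grid):
        raise ValueError("N_grid must be sorted ascending")
    labels = label_single_word_msus(records)
    out = []
    for metric in metrics:
        for N in N_grid:
            cs = rank_and_select(records, metric, N)
            out.append(precision_recall_f(cs, labels))
    return out


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals over the labeled MSU pool
# ---------------------------------------------------------------------------
#
# The bootstrap unit is the MSU: each data point is (in_set flag, word
# label).  Metric functions take the two boolean arrays of a resample and
# return a scalar, or nan when undefined on that resample.

def metric_precision(in_set: np.ndarray, is_word: np.ndarray) -> float:
    n = int(in_set.sum())
    if n == 0:
        return float("nan")
    return float((in_set & is_word).sum() / n)


def metric_recall(in_set: np.ndarray, is_word: np.ndarray) -> float:
    n = int(is_word.sum())
    if n == 0:
        return float("nan")
    return float((in_set & is_word).sum() / n)


def metric_f_score(in_set: np.ndarray, is_word: np.ndarray) -> float:
    p = metric_precision(in_set, is_word)
    r = metric_recall(in_set, is_word)
    if np.isnan(p) or np.isnan(r):
        return float("nan")
    return 2 * p * r / (p + r) if (p + r) else 0.0


METRIC_FNS = {
    "precision": metric_precision,
    "recall": metric_recall,
    "f_score": metric_f_score,
}


def labeled_pool(
    records: Sequence[MSURecord], *chunk_sets: ChunkSet
) -> tuple[np.ndarray, ...]:
    """Aligned boolean columns over the full MSU pool.

    Returns one in-set column per chunk set, followed by the single-word
    label column — the data-point table the bootstraps resample.
    """
    cols = []
    for cs in chunk_sets:
        member_keys = {r.syllables for r in cs.members}
        cols.append(np.array([r.syllables in member_keys for r in records], dtype=bool))
    cols.append(np.array([r.is_single_word for r in records], dtype=bool))
    return tuple(cols)


def bootstrap_metric_ci(
    pool: tuple[np.ndarray, ...],
    metric_fn: Callable[..., float],
    n_resamples: int = 100,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI of one classification metric.

    ``pool`` is a tuple of aligned per-MSU columns and ``metric_fn`` maps a
    resampled column tuple to a scalar (nan when undefined on that
    resample).  Resamples of the pool size are drawn with replacement;
    undefined resamples are excluded from the percentiles and counted.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    n = len(pool[0])
    rng = np.random.default_rng(seed)
    values = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        values[b] = metric_fn(*(col[idx] for col in pool))
    ok = values[~np.isnan(values)]
    if ok.size == 0:
        raise ValueError("metric undefined on every bootstrap resample")
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return BootstrapCI(
        point=metric_fn(*pool),
        lo=float(lo), hi=float(hi),
        n_resamples=n_resamples, n_excluded=int(n_resamples - ok.size),
    )


def bootstrap_difference_ci(
    pool: tuple[np.ndarray, ...],
    metric_fn_a: Callable[..., float],
    metric_fn_b: Callable[..., float],
    n_resamples: int = 100,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI of metric_a - metric_b on shared resamples.

    The paired construction makes the difference of identical metrics
    identically zero; a 95% interval excluding zero flags a significant
    difference.  To compare the same statistic across two chunk sets, build
    the pool with both in-set columns (:func:`labeled_pool`) and point each
    metric function at its own column.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    n = len(pool[0])
    rng = np.random.default_rng(seed)
    values = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        resampled = tuple(col[idx] for col in pool)
        values[b] = metric_fn_a(*resampled) - metric_fn_b(*resampled)
    ok = values[~np.isnan(values)]
    if ok.size == 0:
        raise ValueError("difference undefined on every bootstrap resample")
    lo, hi = np.percentile(ok, [2.5, 97.5])
    point = metric_fn_a(*pool) - metric_fn_b(*pool)
    return BootstrapCI(
        point=float(point), lo=float(lo), hi=float(hi),
        n_resamples=n_resamples, n_excluded=int(n_resamples - ok.size),
    )


def chunk_set_comparison(
    records: Sequence[MSURecord],
    cs_a: ChunkSet,
    cs_b: ChunkSet,
    statistic: str,
    n_resamples: int = 100,
    seed: int = 0,
) -> BootstrapCI:
    """Paired bootstrap CI of statistic(cs_a) - statistic(cs_b) over one pool."""
    base = METRIC_FNS[statistic]
    pool = labeled_pool(records, cs_a, cs_b)

    def fn_a(in_a, in_b, is_word):
        return base(in_a, is_word)

    def fn_b(in_a, in_b, is_word):
        return base(in_b, is_word)

    return bootstrap_difference_ci(pool, fn_a, fn_b, n_resamples=n_resamples, seed=seed)
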