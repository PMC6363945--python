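"""#MSU predictors, covariates, AoFP regressions, and bootstrap comparisons.

For a target word and a chunk set, #MSU counts the distinct MSU types in
the set whose word list contains the target.  AoFP is regressed on
log(#MSU + 1) together with four covariates: log child-directed-speech
frequency (Freq), concreteness (Con), log syllable count (Nsyl), and log
phonological neighborhood density + 1 (PhonN; homophones plus one-phoneme
add/delete/substitute neighbors, which can be zero).  All variables,
dependent included, are log-transformed and standardized to z-scores on
the analysis sample before an ordinary-least-squares fit; the #MSU effect
is summarized by its standardized coefficient and by the increase in R²
over the covariate-only baseline (ΔR²).

Uncertainty comes from a percentile bootstrap that resamples target words
(the regression's data points) with replacement and refits — including the
standardization — inside each resample.  Metric comparisons (S vs F, S vs
P, P vs F) reuse the same word resamples for both members of a pair, so
the difference CIs are paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .aofp_estimation import AoFPTable
from .chunk_selection import ChunkSet
from .corpus_io import PronLexicon, SyllabifiedUtterance, Utterance
from .word_classification import BootstrapCI

MSU_TERM = "log_msu1"
COVARIATE_TERMS = ("log_freq", "con", "log_nsyl", "log_phonn1")


@dataclass(frozen=True)
class TargetWordFeatures:
    word: str
    aofp: float
    msu_count: int
    freq: int
    concreteness: float
    n_syll: int
    phon_neighbors: int


@dataclass(frozen=True)
class FitResult:
    params: dict[str, float]
    r2: float
    n_words: int


@dataclass(frozen=True)
class RegressionResult:
    metric: str
    N: int
    beta_msu: BootstrapCI
    r2_full: float
    r2_baseline: float
    delta_r2: BootstrapCI
    n_words: int


# ---------------------------------------------------------------------------
# Predictors and covariates
# ---------------------------------------------------------------------------

def count_msu_per_word(
    targets: Sequence[str], cs: ChunkSet
) -> dict[str, int]:
    """#MSU: distinct MSU types in the chunk set containing each target.

    An MSU containing the target word twice is counted once (type count).
    """
    counts = {w: 0 for w in targets}
    for msu in cs.members:
        for w in set(msu.words):
            if w in counts:
                counts[w] += 1
    return counts


class NeighborhoodIndex:
    """Phoneme edit-distance <= 1 lookups over a whole lexicon.

    Buckets pronunciations by their single-position deletion variants, so a
    query touches only candidate words sharing a variant with the target
    instead of scanning the lexicon.
    """

    def __init__(self, lex: PronLexicon):
        self._lex = lex
        self._by_pron: dict[tuple[str, ...], set[str]] = {}
        self._by_deletion: dict[tuple[str, ...], set[str]] = {}
        for w in lex:
            p = lex.phonemes(w)
            self._by_pron.setdefault(p, set()).add(w)
            for i in range(len(p)):
                self._by_deletion.setdefault(p[:i] + p[i + 1:], set()).add(w)

    def neighborhood(self, word: str) -> int:
        key = word.lower()
        p = self._lex.phonemes(key)
        candidates: set[str] = set(self._by_pron.get(p, ()))          # homophones
        candidates |= self._by_deletion.get(p, set())                 # additions
        for i in range(len(p)):
            d = p[:i] + p[i + 1:]
            candidates |= self._by_pron.get(d, set())                 # deletions
            candidates |= self._by_deletion.get(d, set())             # substitutions
        candidates.discard(key)
        return sum(
            1 for c in candidates if _edit_distance_le1(p, self._lex.phonemes(c))
        )


def phonological_neighborhood(
    word: str, lex: PronLexicon, index: NeighborhoodIndex | None = None
) -> int:
    """PhonN: homophones plus words at one phoneme add/delete/substitute.

    Counted over distinct other lexicon words by phoneme edit distance 0
    (homophony) or 1 between flattened pronunciations.  Pass a prebuilt
    :class:`NeighborhoodIndex` when querying many words.
    """
    if word not in lex:
        raise KeyError(f"word {word!r} not in lexicon")
    if index is None:
        index = NeighborhoodIndex(lex)
    return index.neighborhood(word)


def _edit_distance_le1(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # one insertion into the shorter: skip at the first mismatch
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


def assemble_features(
    aofp: AoFPTable,
    cs: ChunkSet,
    adult_corpus: Sequence[Utterance] | Sequence[SyllabifiedUtterance],
    lex: PronLexicon,
    concreteness: Mapping[str, float],
) -> list[TargetWordFeatures]:
    """Inner join of AoFP, #MSU, frequency, and lexical covariates.

    A word enters iff it has an AoFP estimate, a lexicon entry (for Nsyl
    and PhonN), a concreteness rating, and a nonzero token frequency in
    the adult corpus.  #MSU may be zero.
    """
    from collections import Counter

    freq: Counter = Counter()
    for utt in adult_corpus:
        src = utt.source if isinstance(utt, SyllabifiedUtterance) else utt
        freq.update(src.words)
    targets = sorted(w for w in aofp.estimates
                     if w in lex and w in concreteness and freq[w] > 0)
    msu_counts = count_msu_per_word(targets, cs)
    index = NeighborhoodIndex(lex)
    return [
        TargetWordFeatures(
            word=w,
            aofp=aofp[w],
            msu_count=msu_counts[w],
            freq=freq[w],
            concreteness=float(concreteness[w]),
            n_syll=len(lex.syllables(w)),
            phon_neighbors=phonological_neighborhood(w, lex, index),
        )
        for w in targets
    ]


# ---------------------------------------------------------------------------
# Regression fits
# ---------------------------------------------------------------------------

def design_frame(features: Sequence[TargetWordFeatures]) -> pd.DataFrame:
    """Log-transformed (not yet standardized) variables for the fit."""
    return pd.DataFrame(
        {
            "log_aofp": [np.log(f.aofp) for f in features],
            MSU_TERM: [np.log(f.msu_count + 1) for f in features],
            "log_freq": [np.log(f.freq) for f in features],
            "con": [np.log(f.concreteness) for f in features],
            "log_nsyl": [np.log(f.n_syll) for f in features],
            "log_phonn1": [np.log(f.phon_neighbors + 1) for f in features],
        },
        index=[f.word for f in features],
    )


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance variable(s): {', '.join(zero.index)}")
    return (df - df.mean()) / sd


def _fit(df: pd.DataFrame, terms: Sequence[str]) -> FitResult:
    z = _zscore(df[["log_aofp", *terms]])
    X = sm.add_constant(z[list(terms)], has_constant="add")
    res = sm.OLS(z["log_aofp"], X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return FitResult(
        params={t: float(res.params[t]) for t in terms},
        r2=float(res.rsquared),
        n_words=len(df),
    )


def fit_aofp_model(
    features: Sequence[TargetWordFeatures], include_msu: bool = True
) -> FitResult:
    """OLS of standardized log AoFP on the standardized log predictors.

    The full model includes log(#MSU+1) plus the four covariates; the
    baseline omits the #MSU term.
    """
    terms = (MSU_TERM, *COVARIATE_TERMS) if include_msu else COVARIATE_TERMS
    if len(features) < len(terms) + 2:
        raise ValueError("too few words for the number of predictors")
    return _fit(design_frame(features), terms)


def delta_r2(full: FitResult, baseline: FitResult) -> float:
    """R² gain of the full over the baseline model (nested OLS, >= 0)."""
    if full.n_words != baseline.n_words:
        raise ValueError("full and baseline fits use different rows")
    return full.r2 - baseline.r2


# ---------------------------------------------------------------------------
# Bootstrap sweep over (metric, N) cells
# ---------------------------------------------------------------------------

def _cell_stats(df: pd.DataFrame) -> tuple[float, float, float]:
    full = _fit(df, (MSU_TERM, *COVARIATE_TERMS))
    base = _fit(df, COVARIATE_TERMS)
    return full.params[MSU_TERM], full.r2, full.r2 - base.r2


def _percentile_ci(point: float, draws: np.ndarray, n_resamples: int) -> BootstrapCI:
    ok = draws[~np.isnan(draws)]
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return BootstrapCI(point=point, lo=float(lo), hi=float(hi),
                       n_resamples=n_resamples,
                       n_excluded=int(n_resamples - ok.size))


def sweep_regression(
    features_by_cell: Mapping[tuple[str, int], Sequence[TargetWordFeatures]],
    n_resamples: int = 100,
    seed: int = 0,
) -> tuple[list[RegressionResult], list[dict]]:
    """Bootstrap β and ΔR² per (metric, N) cell, plus paired metric differences.

    Resampling draws target words with replacement and refits (with
    standardization) inside each resample.  For every N present for two
    metrics, the difference CIs for β and ΔR² between the metric pair use
    the same word resamples on both sides, so a pairing of identical cells
    gives an identically zero difference.  Cells with too few words are
    skipped.

    Returns (per-cell results, pairwise-difference records).
    """
    min_rows = len(COVARIATE_TERMS) + 3
    frames: dict[tuple[str, int], pd.DataFrame] = {}
    words_by_cell: dict[tuple[str, int], tuple[str, ...]] = {}
    for cell, feats in features_by_cell.items():
        if len(feats) < min_rows:
            import logging
            logging.getLogger("chunklex").warning(
                "cell %s skipped: only %d words", cell, len(feats))
            continue
        frames[cell] = design_frame(feats)
        words_by_cell[cell] = tuple(f.word for f in feats)

    rng = np.random.default_rng(seed)
    # Shared resample index draws per word-list signature, so paired
    # differences are well-defined whenever two cells share their rows.
    index_draws: dict[tuple[str, ...], np.ndarray] = {}
    for cell in sorted(frames):
        sig = words_by_cell[cell]
        if sig not in index_draws:
            n = len(sig)
            index_draws[sig] = rng.integers(0, n, size=(n_resamples, n))

    boot: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    results: list[RegressionResult] = []
    for cell in sorted(frames):
        df = frames[cell]
        idx = index_draws[words_by_cell[cell]]
        betas = np.empty(n_resamples)
        deltas = np.empty(n_resamples)
        for b in range(n_resamples):
            sub = df.iloc[idx[b]]
            try:
                betas[b], _, deltas[b] = _cell_stats(sub)
            except ValueError:  # degenerate resample (zero variance)
                betas[b] = deltas[b] = np.nan
        beta_pt, r2_full, delta_pt = _cell_stats(df)
        base = _fit(df, COVARIATE_TERMS)
        metric, N = cell
        results.append(RegressionResult(
            metric=metric, N=N,
            beta_msu=_percentile_ci(beta_pt, betas, n_resamples),
            r2_full=r2_full, r2_baseline=base.r2,
            delta_r2=_percentile_ci(delta_pt, deltas, n_resamples),
            n_words=len(df),
        ))
        boot[cell] = (betas, deltas)

    diffs: list[dict] = []
    by_N: dict[int, dict[str, tuple[str, int]]] = {}
    for metric, N in frames:
        by_N.setdefault(N, {})[metric] = (metric, N)
    point = {(r.metric, r.N): r for r in results}
    for N in sorted(by_N):
        cells = by_N[N]
        for a, b in (("S", "F"), ("S", "P"), ("P", "F")):
            if a not in cells or b not in cells:
                continue
            if words_by_cell[cells[a]] != words_by_cell[cells[b]]:
                continue  # unpaired rows: difference CI undefined
            beta_d = boot[cells[a]][0] - boot[cells[b]][0]
            delta_d = boot[cells[a]][1] - boot[cells[b]][1]
            ra, rb = point[cells[a]], point[cells[b]]
            diffs.append({
                "N": N, "pair": f"{a}-{b}",
                "beta_diff": _percentile_ci(
                    ra.beta_msu.point - rb.beta_msu.point, beta_d, n_resamples),
                "delta_r2_diff": _percentile_ci(
                    ra.delta_r2.point - rb.delta_r2.point, delta_d, n_resamples),
            })
    return results, diffs


# ---------------------------------------------------------------------------
# Cross-corpus analysis plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisPlan:
    """One corpus–AoFP pairing: where predictors and outcomes come from."""

    name: str
    predictor_corpora: tuple[str, ...]
    aofp_source: str  # a corpus id, or "cdi"
    max_msu_child_age: float | None = None  # age cap for CDI pairings


def cross_corpus_pairing(
    corpus_ids: Sequence[str],
    cdi_available: bool = False,
    cdi_age_cap: float = 30.0,
) -> list[AnalysisPlan]:
    """The cross-corpus design: predictors from one corpus, AoFP from the other.

    Two corpora yield two crossed plans; a CDI table adds a third plan with
    predictors from the age-restricted union of both corpora.
    """
    plans: list[AnalysisPlan] = []
    if len(corpus_ids) >= 2:
        a, b = corpus_ids[0], corpus_ids[1]
        plans.append(AnalysisPlan(
            name=f"{a}-predicts-{b}", predictor_corpora=(a,), aofp_source=b))
        plans.append(AnalysisPlan(
            name=f"{b}-predicts-{a}", predictor_corpora=(b,), aofp_source=a))
    if cdi_available:
        plans.append(AnalysisPlan(
            name="pooled-predicts-cdi",
            predictor_corpora=tuple(corpus_ids),
            aofp_source="cdi",
            max_msu_child_age=cdi_age_cap,
        ))
    if not plans:
        raise ValueError("need at least two corpora or a CDI table")
    return plans
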