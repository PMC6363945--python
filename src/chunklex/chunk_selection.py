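"""Candidate-chunk extraction, ranking metrics, and top-N chunk sets.

A multi-syllable utterance (MSU) is a full caregiver utterance of at least
two syllables — the candidate unit for undersegmented chunk storage.  Three
filters define candidacy: (1) at least two syllables, (2) not a repetition
of a single word, (3) used by caretakers in at least two source corpora.
Surviving MSU types are ranked by syllable length (S), token frequency (F),
or syllabic predictability (P), and the top N under each ranking form a
chunk set.

The predictability score of an MSU u_1..u_n averages the conditional
probabilities between adjacent syllables, forward and backward: medial
syllables contribute p(u_i|u_{i-1}) and p(u_i|u_{i+1}), the first syllable
only the backward term, the last only the forward term — 2(n-1) values in
total.  Conditionals are estimated from bigram counts over adjacent
within-utterance syllable pairs of the adult corpus: the forward
denominator counts occurrences of the conditioning syllable that have a
right neighbor, the backward denominator occurrences with a left neighbor,
so each conditional is a proper distribution over observed alternatives.
"""

from __future__ import annotations

import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .corpus_io import SyllabifiedUtterance

METRIC_SHORT = "S"
METRIC_FREQUENT = "F"
METRIC_PREDICTABLE = "P"
METRICS = (METRIC_SHORT, METRIC_FREQUENT, METRIC_PREDICTABLE)


@dataclass
class SyllableBigramModel:
    """Adjacency counts between within-utterance neighboring syllables.

    ``left_counts[u]`` counts occurrences of u that have a right neighbor;
    ``right_counts[v]`` occurrences of v with a left neighbor;
    ``bigram_counts[(u, v)]`` adjacency tokens of the ordered pair.
    """

    left_counts: Counter = field(default_factory=Counter)
    right_counts: Counter = field(default_factory=Counter)
    bigram_counts: Counter = field(default_factory=Counter)

    def forward(self, u: str, v: str) -> float:
        """p(v | u): probability that u's right neighbor is v."""
        denom = self.left_counts[u]
        if denom == 0:
            raise ValueError(f"syllable {u!r} never observed with a right neighbor")
        return self.bigram_counts[(u, v)] / denom

    def backward(self, u: str, v: str) -> float:
        """p(u | v): probability that v's left neighbor is u."""
        denom = self.right_counts[v]
        if denom == 0:
            raise ValueError(f"syllable {v!r} never observed with a left neighbor")
        return self.bigram_counts[(u, v)] / denom


@dataclass(frozen=True)
class MSURecord:
    """One distinct multi-syllable utterance type.

    ``frequency`` is the token count over the aggregated adult corpus (before
    the two-corpus membership filter); ``source_corpora`` the corpora whose
    caretakers produced it.  ``predictability`` is filled in once a bigram
    model is available.
    """

    syllables: tuple[str, ...]
    words: tuple[str, ...]
    frequency: int
    source_corpora: frozenset[str]
    predictability: float | None = None

    @property
    def length_syll(self) -> int:
        return len(self.syllables)

    @property
    def is_single_word(self) -> bool:
        return len(self.words) == 1


@dataclass(frozen=True)
class ChunkSet:
    """The top-N MSU records under one ranking metric."""

    metric: str
    size_N: int
    members: tuple[MSURecord, ...]

    def __len__(self) -> int:
        return len(self.members)


def extract_candidate_msus(
    adult_utts: Sequence[SyllabifiedUtterance],
) -> list[MSURecord]:
    """Extract the filtered MSU candidate pool from adult speech.

    One record per distinct syllable sequence (two word strings with the
    same syllabification collapse).  Records must have >=2 syllables, must
    not consist of repeated occurrences of a single word, and must occur in
    >=2 source corpora.  Frequencies are token counts over the whole
    aggregated corpus, accumulated before the two-corpus filter.
    """
    freq: Counter = Counter()
    sources: dict[tuple[str, ...], set[str]] = defaultdict(set)
    words_of: dict[tuple[str, ...], tuple[str, ...]] = {}
    for u in adult_utts:
        key = u.syllables
        freq[key] += 1
        sources[key].add(u.source.corpus_id)
        if key not in words_of:
            words_of[key] = u.source.words
    out: list[MSURecord] = []
    for key in sorted(freq):
        words = words_of[key]
        if len(key) < 2:
            continue
        if len(set(words)) == 1 and len(words) > 1:
            continue  # single-word repetition like "no no no"
        if len(sources[key]) < 2:
            continue
        out.append(
            MSURecord(
                syllables=key,
                words=words,
                frequency=freq[key],
                source_corpora=frozenset(sources[key]),
            )
        )
    return out


def build_bigram_model(
    adult_utts: Sequence[SyllabifiedUtterance],
) -> SyllableBigramModel:
    """Accumulate adjacency counts over every within-utterance syllable pair.

    Every adult utterance token contributes; no pairs span utterance
    boundaries.
    """
    model = SyllableBigramModel()
    for u in adult_utts:
        s = u.syllables
        for i in range(len(s) - 1):
            model.bigram_counts[(s[i], s[i + 1])] += 1
            model.left_counts[s[i]] += 1
            model.right_counts[s[i + 1]] += 1
    return model


def predictability_score(
    syllables: Sequence[str], model: SyllableBigramModel
) -> float:
    """Mean of the 2(n-1) adjacent-syllable conditional probabilities.

    Raises if the sequence is shorter than two syllables or contains an
    adjacency the model never observed (a model/corpus mismatch).
    """
    n = len(syllables)
    if n < 2:
        raise ValueError("predictability is defined for sequences of >=2 syllables")
    probs: list[float] = []
    for i in range(1, n):
        u, v = syllables[i - 1], syllables[i]
        if model.bigram_counts[(u, v)] == 0:
            raise ValueError(f"adjacency {(u, v)!r} not observed in the model")
        probs.append(model.forward(u, v))   # p(u_i | u_{i-1}), i = 2..n
        probs.append(model.backward(u, v))  # p(u_{i-1} | u_i), i.e. p(u_j | u_{j+1}), j = 1..n-1
    return sum(probs) / len(probs)


def annotate_predictability(
    records: Iterable[MSURecord], model: SyllableBigramModel
) -> list[MSURecord]:
    """Return records with their predictability scores filled in."""
    return [
        replace(r, predictability=predictability_score(r.syllables, model))
        for r in records
    ]


def _sort_key(metric: str):
    # Primary metric, then descending frequency, then ascending syllable
    # string — a deterministic, seed-free total order.
    if metric == METRIC_SHORT:
        return lambda r: (r.length_syll, -r.frequency, r.syllables)
    if metric == METRIC_FREQUENT:
        return lambda r: (-r.frequency, r.syllables)
    if metric == METRIC_PREDICTABLE:
        return lambda r: (-r.predictability, -r.frequency, r.syllables)
    raise ValueError(f"unknown metric: {metric!r}")


def rank_and_select(
    records: Sequence[MSURecord], metric: str, N: int
) -> ChunkSet:
    """Select the top-N records under a ranking metric.

    S ranks shortest first, F most frequent first, P most predictable first;
    ties break by descending frequency then ascending syllable string.  N
    larger than the pool returns the whole pool.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if metric == METRIC_PREDICTABLE and any(r.predictability is None for r in records):
        raise ValueError("records must carry predictability scores for metric P")
    ranked = sorted(records, key=_sort_key(metric))
    return ChunkSet(metric=metric, size_N=N, members=tuple(ranked[:N]))


def chunk_set_stats(cs: ChunkSet, others: Sequence[ChunkSet] = ()) -> dict:
    """Summary statistics for a chunk set, plus pairwise overlap percentages.

    Overlap with another equal-N set is |intersection| / N * 100; comparing
    sets of unequal size is an error.
    """
    members = cs.members
    freqs = [r.frequency for r in members]
    lengths = [r.length_syll for r in members]
    preds = [r.predictability for r in members if r.predictability is not None]

    def _mean_sd(xs):
        if not xs:
            return (float("nan"), float("nan"))
        mean = statistics.fmean(xs)
        sd = statistics.pstdev(xs) if len(xs) > 1 else 0.0
        return (mean, sd)

    stats = {
        "metric": cs.metric,
        "n": len(members),
        "mean_frequency": _mean_sd(freqs)[0],
        "sd_frequency": _mean_sd(freqs)[1],
        "mean_length": _mean_sd(lengths)[0],
        "sd_length": _mean_sd(lengths)[1],
        "mean_predictability": _mean_sd(preds)[0],
        "sd_predictability": _mean_sd(preds)[1],
        "overlap_pct": {},
    }
    own = {r.syllables for r in members}
    for other in others:
        if len(other.members) != len(members):
            raise ValueError("overlap is only defined between equal-N chunk sets")
        shared = own & {r.syllables for r in other.members}
        stats["overlap_pct"][other.metric] = 100.0 * len(shared) / len(members)
    return stats
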