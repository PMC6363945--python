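"""Age-of-first-production estimation, corpus- and CDI-derived.

Corpus-derived AoFP treats a word as acquired at the earliest
*developmental stage* at which any child produces it outside of
adult-produced MSU contexts.  Developmental stage is the transcript's mean
length of utterance (MLU) in word tokens, estimated by bootstrapping the
transcript's child utterances (transcripts vary in length, and the plain
per-transcript mean is biased with respect to transcript size).  A child
production of a target word counts as valid only if no contiguous word
n-gram (n >= 2) of the child utterance covering that occurrence matches a
contiguous sub-sequence (length >= 2) of any adult MSU — isolated
productions are always valid.  A word's AoFP is the minimum MLU over
transcripts containing a valid production, subject to the word being
validly produced in at least two corpora.

CDI-derived AoFP reads a parent-report table of per-month production
proportions (months 16–30 for the emulated instrument) and takes the
earliest month at which the proportion reaches the threshold (default
50%); non-monotone curves use the first crossing.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .chunk_selection import MSURecord
from .corpus_io import CHILD, SyllabifiedUtterance, Utterance

CDI_MONTHS = tuple(range(16, 31))


@dataclass(frozen=True)
class TranscriptMLU:
    transcript_id: str
    mlu: float
    n_child_utterances: int


@dataclass(frozen=True)
class AoFPTable:
    """Per-word age-of-first-production estimates.

    ``provenance`` is "corpus" (MLU units) or "cdi" (months).
    """

    estimates: dict[str, float]
    provenance: str

    def __len__(self) -> int:
        return len(self.estimates)

    def __contains__(self, word: str) -> bool:
        return word in self.estimates

    def __getitem__(self, word: str) -> float:
        return self.estimates[word]


# ---------------------------------------------------------------------------
# Transcript MLU via bootstrap
# ---------------------------------------------------------------------------

def bootstrap_transcript_mlu(
    child_utts: Sequence[Utterance],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> TranscriptMLU:
    """Bootstrap estimate of a transcript's mean length of utterance.

    Each resample draws, with replacement, as many utterances as the
    transcript contains; the estimate is the mean over resamples of the
    resample's mean utterance length (in word tokens).
    """
    if not child_utts:
        raise ValueError("transcript has no child utterances")
    tids = {u.transcript_id for u in child_utts}
    if len(tids) != 1:
        raise ValueError(f"utterances span multiple transcripts: {sorted(tids)}")
    lengths = np.array([len(u.words) for u in child_utts], dtype=float)
    n = len(lengths)
    rng = np.random.default_rng(seed)
    resample_means = lengths[rng.integers(0, n, size=(n_resamples, n))].mean(axis=1)
    return TranscriptMLU(
        transcript_id=next(iter(tids)),
        mlu=float(resample_means.mean()),
        n_child_utterances=n,
    )


def transcript_mlus(
    child_corpus: Sequence[Utterance],
    n_resamples: int = 10_000,
    base_seed: int = 0,
) -> dict[str, TranscriptMLU]:
    """Bootstrap MLUs for every transcript in a child corpus.

    Each transcript's bootstrap is seeded from the base seed and a stable
    hash of its identifier, so estimates do not depend on corpus order.
    """
    by_transcript: dict[str, list[Utterance]] = defaultdict(list)
    for u in child_corpus:
        by_transcript[u.transcript_id].append(u)
    out = {}
    for tid in sorted(by_transcript):
        seed = (base_seed * 1_000_003 + _stable_hash(tid)) % (2**31)
        out[tid] = bootstrap_transcript_mlu(
            by_transcript[tid], n_resamples=n_resamples, seed=seed
        )
    return out


def _stable_hash(s: str) -> int:
    h = 2166136261
    for ch in s.encode("utf-8"):
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


# ---------------------------------------------------------------------------
# Valid production contexts
# ---------------------------------------------------------------------------

def msu_subsequences(adult_msus: Iterable[MSURecord]) -> set[tuple[str, ...]]:
    """All contiguous word sub-sequences (length >= 2) of the adult MSUs."""
    subs: set[tuple[str, ...]] = set()
    for msu in adult_msus:
        words = msu.words
        for i in range(len(words)):
            for j in range(i + 2, len(words) + 1):
                subs.add(words[i:j])
    return subs


def valid_production_contexts(
    child_utt: Utterance,
    target: str,
    adult_msus: Sequence[MSURecord] | set[tuple[str, ...]],
) -> bool:
    """Does the child utterance contain a valid production of ``target``?

    An occurrence is invalid when some contiguous n-gram (n >= 2) of the
    utterance containing it matches a length >= 2 contiguous sub-sequence
    of an adult MSU; isolated productions (and occurrences only embeddable
    in single-word matches) are valid.  With multiple occurrences, one
    valid occurrence suffices.
    """
    words = child_utt.words
    positions = [i for i, w in enumerate(words) if w == target]
    if not positions:
        raise ValueError(f"target {target!r} does not occur in the utterance")
    subs = (
        adult_msus if isinstance(adult_msus, set) else msu_subsequences(adult_msus)
    )
    covered = _covered_positions(words, subs)
    return any(pos not in covered for pos in positions)


def _covered_positions(
    words: tuple[str, ...], subs: set[tuple[str, ...]]
) -> set[int]:
    """Positions covered by some utterance n-gram (n >= 2) matching an MSU sub-sequence."""
    if not subs:
        return set()
    max_len = max(map(len, subs))
    covered: set[int] = set()
    n = len(words)
    for i in range(n):
        for j in range(i + 2, min(n, i + max_len) + 1):
            if words[i:j] in subs:
                covered.update(range(i, j))
    return covered


# ---------------------------------------------------------------------------
# Corpus-derived AoFP
# ---------------------------------------------------------------------------

def corpus_aofp(
    child_corpus: Sequence[Utterance],
    adult_msus: Sequence[MSURecord],
    mlus: Mapping[str, TranscriptMLU],
    min_corpora: int = 2,
) -> AoFPTable:
    """Corpus-derived AoFP: minimum transcript MLU over valid productions.

    For each word validly produced (outside adult-MSU contexts) in at least
    ``min_corpora`` distinct corpora, AoFP is the smallest MLU among the
    transcripts containing a valid production.  Words failing the corpus
    threshold are omitted.
    """
    subs = msu_subsequences(adult_msus)
    valid_transcripts: dict[str, set[str]] = defaultdict(set)
    valid_corpora: dict[str, set[str]] = defaultdict(set)
    for utt in child_corpus:
        if utt.speaker_role != CHILD:
            continue
        covered = _covered_positions(utt.words, subs)
        for i, word in enumerate(utt.words):
            if i not in covered:
                valid_transcripts[word].add(utt.transcript_id)
                valid_corpora[word].add(utt.corpus_id)
    estimates: dict[str, float] = {}
    for word in sorted(valid_transcripts):
        if len(valid_corpora[word]) < min_corpora:
            continue
        tids = valid_transcripts[word]
        missing = [t for t in tids if t not in mlus]
        if missing:
            raise ValueError(f"no MLU estimate for transcripts: {sorted(missing)}")
        estimates[word] = min(mlus[t].mlu for t in tids)
    return AoFPTable(estimates=estimates, provenance="corpus")


# ---------------------------------------------------------------------------
# CDI-derived AoFP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDITable:
    """Word-by-month grid of reported production proportions."""

    rows: "pd.DataFrame"  # index: word; columns: months

    def __post_init__(self) -> None:
        vals = self.rows.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
            raise ValueError("CDI proportions must lie in [0, 1]")

    @property
    def months(self) -> tuple[int, ...]:
        return tuple(int(m) for m in self.rows.columns)


def read_cdi_table(path: str | Path) -> CDITable:
    """Read a CDI TSV: word column, then one proportion column per month."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [int(c) for c in df.columns]
    return CDITable(rows=df)


def write_cdi_table(table: CDITable, path: str | Path) -> None:
    df = table.rows.copy()
    df.index.name = "word"
    df.to_csv(path, sep="\t")


def cdi_aofp(table: CDITable, threshold: float = 0.5) -> AoFPTable:
    """CDI-derived AoFP: earliest month reaching the production threshold.

    Words whose proportion never reaches the threshold are omitted; for
    non-monotone curves the first crossing is used.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    estimates: dict[str, float] = {}
    months = table.months
    vals = table.rows.to_numpy(dtype=float)
    for word, row in zip(table.rows.index, vals):
        hit = np.nonzero(row >= threshold)[0]
        if hit.size:
            estimates[str(word)] = float(months[hit[0]])
    return AoFPTable(estimates=estimates, provenance="cdi")


# ---------------------------------------------------------------------------
# Age restriction of MSUs (for CDI analyses)
# ---------------------------------------------------------------------------

def restrict_msus_by_child_age(
    records: Sequence[MSURecord],
    adult_utts: Sequence[SyllabifiedUtterance],
    max_age_months: float,
) -> list[MSURecord]:
    """Keep MSUs produced in the presence of children at or under an age cap.

    An MSU survives iff at least one of its utterance tokens was addressed
    to a child aged <= ``max_age_months``; frequencies are recomputed over
    the qualifying tokens.  Utterances with missing age never qualify.
    """
    from dataclasses import replace

    qualifying: dict[tuple[str, ...], int] = defaultdict(int)
    for u in adult_utts:
        age = u.source.child_age_months
        if age is not None and age <= max_age_months:
            qualifying[u.syllables] += 1
    out = []
    for r in records:
        count = qualifying.get(r.syllables, 0)
        if count >= 1:
            out.append(replace(r, frequency=count))
    return out


# ---------------------------------------------------------------------------
# External validation via rank correlation
# ---------------------------------------------------------------------------

def rank_validation(
    a: AoFPTable, b: Mapping[str, float]
) -> tuple[float, int, float]:
    """Spearman correlation between AoFP estimates and an external age table.

    Computed over the shared word set; returns (rho, n_shared, p).  Below
    n = 10 the p-value is an exact permutation p; otherwise the
    large-sample t approximation.
    """
    shared = sorted(set(a.estimates) & set(b))
    n = len(shared)
    if n < 3:
        raise ValueError("need at least 3 shared words for rank validation")
    x = np.array([a.estimates[w] for w in shared])
    y = np.array([b[w] for w in shared])
    rho, p = sstats.spearmanr(x, y)
    if n < 10:
        rx = sstats.rankdata(x)
        ry = sstats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), n, float(p)
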