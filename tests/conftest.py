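"""Shared fixtures: tiny handcrafted corpora/lexica and a reusable synthetic bundle."""

from __future__ import annotations

import numpy as np
import pytest

from chunklex import PronLexicon, Utterance, syllabify_corpus
from chunklex.synthetic_data import GeneratorConfig, PlantedEffect, generate_bundle


def U(words, corpus="A", transcript="t1", role="adult", age=30.0):
    """Terse utterance factory for fixtures."""
    if isinstance(words, str):
        words = words.split()
    return Utterance(
        corpus_id=corpus, transcript_id=transcript, speaker_role=role,
        child_age_months=age, words=tuple(words),
    )


@pytest.fixture
def toy_lexicon():
    """A small lexicon with known syllabifications."""
    lex = PronLexicon()
    lex.add("window", [["W", "IH", "N"], ["D", "OW"]])
    lex.add("what", [["W", "AH", "T"]])
    lex.add("a", [["AH"]])
    lex.add("great", [["G", "R", "EY", "T"]])
    lex.add("day", [["D", "EY"]])
    lex.add("no", [["N", "OW"]])
    lex.add("stop", [["S", "T", "AA", "P"]])
    lex.add("there", [["DH", "EH", "R"]])
    lex.add("quiet", [["K", "W", "AY"], ["AH", "T"]])
    lex.add("okay", [["OW"], ["K", "EY"]])
    return lex


def syllabify_all(utts, lex):
    syll, coverage = syllabify_corpus(utts, lex)
    assert coverage == 1.0
    return syll


def random_toy_corpus(rng, n_utts=20, n_syll_types=8, max_len=5):
    """Random syllable-level corpus for oracle-equivalence tests.

    Builds single-corpus adult utterances over an artificial lexicon of
    one-syllable words w0..wk, so syllable tokens equal word identities.
    """
    lex = PronLexicon()
    for i in range(n_syll_types):
        lex.add(f"w{i}", [[f"S{i}"]])
    utts = []
    for j in range(n_utts):
        length = int(rng.integers(1, max_len + 1))
        words = tuple(f"w{int(rng.integers(n_syll_types))}" for _ in range(length))
        utts.append(U(words, corpus=f"c{int(rng.integers(2))}", transcript=f"t{j}"))
    syll, _ = syllabify_corpus(utts, lex)
    return syll


@pytest.fixture(scope="session")
def small_bundle():
    """One moderately sized synthetic bundle shared across the suite."""
    cfg = GeneratorConfig(
        seed=42,
        n_target_words=150,
        vocab_size=500,
        n_filler_utterances=1200,
        n_single_word_types=40,
        n_sealed_words=6,
        planted_effect=PlantedEffect(predictor="S", slope=0.5),
    )
    return generate_bundle(cfg)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_predictability(syllables, utterance_tokens):
    """Literal piecewise-definition oracle for the predictability score.

    Recounts everything from the raw syllable sequences: for each position i
    the set P_i holds p(u_i|u_{i-1}) (if i > 1) and p(u_i|u_{i+1}) (if
    i < n), with conditionals as ratios of adjacency counts to counts of
    the conditioning syllable in the relevant neighbor position.  The score
    is the mean over the multiset union of all P_i.
    """
    from collections import Counter

    big = Counter()
    left = Counter()
    right = Counter()
    for seq in utterance_tokens:
        for a, b in zip(seq, seq[1:]):
            big[(a, b)] += 1
            left[a] += 1
            right[b] += 1
    n = len(syllables)
    values = []
    for i in range(n):
        if i > 0:
            u_prev, u = syllables[i - 1], syllables[i]
            values.append(big[(u_prev, u)] / left[u_prev])
        if i < n - 1:
            u, u_next = syllables[i], syllables[i + 1]
            values.append(big[(u, u_next)] / right[u_next])
    return sum(values) / len(values)


def oracle_valid_production(child_words, target, msu_word_lists):
    """Brute-force n-gram matcher for the production-context rule."""
    subs = set()
    for words in msu_word_lists:
        for i in range(len(words)):
            for j in range(i + 2, len(words) + 1):
                subs.add(tuple(words[i:j]))
    child_words = tuple(child_words)
    occurrences = [k for k, w in enumerate(child_words) if w == target]
    for k in occurrences:
        hit = False
        for i in range(len(child_words)):
            for j in range(i + 2, len(child_words) + 1):
                if i <= k < j and child_words[i:j] in subs:
                    hit = True
        if not hit:
            return True
    return False


def oracle_ols(X, y):
    """Normal-equations OLS: coefficients and R^2 with an intercept column."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
    resid = y - X1 @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return beta[1:], 1.0 - ss_res / ss_tot
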