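"""Synthetic corpora, lexica, and CDI tables with planted chunk structure.

The generator emulates the statistical shape the pipeline assumes without
requiring any external corpus downloads: Zipfian word frequencies, short
utterances (mean about four words, roughly a quarter single-word), several
sub-corpora that share a controlled family of recurring template MSUs while
each also producing idiosyncratic speech, child transcripts whose MLU grows
over developmental stages, a planted negative effect of #MSU on age of
first production, and CDI-style proportion curves.

Structure of the adult corpus
-----------------------------
Every target word appears in an independent Poisson number of *short*
templates (2-3 syllables, low token frequency) and of *long frequent*
templates (>= 6 syllables, high token frequency).  The two frequency bands
are separated, so selecting the top N = (number of long templates) MSUs by
frequency recovers exactly the long-template family while the equally sized
shortest set is dominated by the short family — giving per-word #MSU-S and
#MSU-F counts that are statistically independent across target words.
Controlled single-word MSU types come from a disyllabic pool plus a few
"sealed" words whose syllables occur nowhere else in the corpus (their
predictability score is exactly 1 by construction).  Idiosyncratic filler
utterances carry a per-corpus marker word (a caregiver/child name), which
guarantees they never survive the two-corpus filter; single-word filler
utterances use monosyllabic words, so they never enter the MSU pool.

The planted effect
------------------
The generator runs the package's own extraction and ranking on the corpus
it just produced, counts #MSU per target word from the realized chunk sets,
and plants log AoFP = a - slope * z(log(1 + #MSU_predictor)) + noise.  The
truth record keeps the continuous planted values, the realized counts, and
the realized per-transcript MLUs, so every recovery test can be expressed
against the truth alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aofp_estimation import CDI_MONTHS, CDITable, write_cdi_table
from .chunk_selection import (
    METRIC_FREQUENT,
    METRIC_PREDICTABLE,
    METRIC_SHORT,
    extract_candidate_msus,
    rank_and_select,
)
from .corpus_io import (
    ADULT,
    CHILD,
    PronLexicon,
    Utterance,
    syllabify_corpus,
    write_pron_lexicon,
    write_utterances,
)
from .msu_regression import count_msu_per_word

_CONSONANTS = ("P", "T", "K", "B", "D", "G", "M", "N", "S", "Z",
               "L", "R", "F", "V", "W", "Y")
_VOWELS = ("AA", "AE", "AH", "EH", "IY", "IH", "OW", "UW", "EY", "AY")
# Reserved onsets for sealed words: never used by the general inventory, so
# sealed syllables cannot collide with any other syllable in the corpus.
_SEALED_ONSETS = ("CH", "JH", "SH", "TH", "ZH", "NG", "DH", "HH")


@dataclass(frozen=True)
class PlantedEffect:
    """Which #MSU predictor drives AoFP, and how strongly.

    ``slope`` is in SD units of log AoFP; ``noise_sd`` defaults to
    sqrt(1 - slope^2) so planted log AoFP has approximately unit variance.
    """

    predictor: str = METRIC_SHORT  # S | F | P | none
    slope: float = 0.5
    noise_sd: float | None = None

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return float(np.sqrt(max(0.0, 1.0 - self.slope**2)))


@dataclass(frozen=True)
class MLUGrowth:
    """Linear MLU-by-stage trajectory for child transcripts."""

    start: float = 1.5
    slope: float = 0.35
    noise_sd: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_corpora: int = 2
    n_transcripts_per_corpus: int = 12
    vocab_size: int = 1200            # general Zipf filler vocabulary
    zipf_exponent: float = 1.0
    mean_utterance_len: float = 4.0
    syllable_count_probs: tuple[float, ...] = (0.45, 0.35, 0.15, 0.05)
    homophone_rate: float = 0.05      # among filler words
    neighbor_rate: float = 0.10       # targets derived by one-phoneme edits
    n_target_words: int = 300
    short_templates_per_word: float = 1.5   # Poisson mean
    freq_templates_per_word: float = 2.0    # Poisson mean
    short_template_freq: float = 2.5        # mean tokens, band [2, 3]
    freq_template_freq: float = 5.5         # mean tokens, floor 4
    target_usage_logmean: float = 4.0       # lognormal base usage of targets
    target_usage_logsd: float = 1.1
    n_single_word_types: int = 100          # shared disyllabic single-word MSUs
    n_sealed_words: int = 10
    n_filler_utterances: int = 4000         # idiosyncratic utterances per corpus
    single_word_rate: float = 0.25          # of filler utterances
    child_age_range_months: tuple[float, float] = (12.0, 48.0)
    planted_effect: PlantedEffect = field(default_factory=PlantedEffect)
    mlu_growth: MLUGrowth = field(default_factory=MLUGrowth)
    child_utterances_per_transcript: int = 120
    child_length_noise: float = 1.0   # 0 -> constant-length transcripts
    contamination_rate: float = 0.1   # productions embedded in adult MSUs

    def __post_init__(self) -> None:
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")
        if self.n_corpora < 2:
            raise ValueError("need >= 2 corpora (the two-corpus filter is structural)")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.planted_effect.noise_sd is not None and self.planted_effect.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "planted_effect" in d and isinstance(d["planted_effect"], Mapping):
            d["planted_effect"] = PlantedEffect(**d["planted_effect"])
        if "mlu_growth" in d and isinstance(d["mlu_growth"], Mapping):
            d["mlu_growth"] = MLUGrowth(**d["mlu_growth"])
        for key in ("syllable_count_probs", "child_age_range_months"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticBundle:
    config: GeneratorConfig
    lexicon: PronLexicon
    concreteness: dict[str, float]
    adult_corpus: list[Utterance]
    child_corpus: list[Utterance]
    cdi: CDITable
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_utterances(self.adult_corpus, out / "adult_corpus.tsv")
        write_utterances(self.child_corpus, out / "child_corpus.tsv")
        write_pron_lexicon(self.lexicon, out / "lexicon.tsv")
        with (out / "concreteness.tsv").open("w", encoding="utf-8") as fh:
            fh.write("lemma\trating\n")
            for w in sorted(self.concreteness):
                fh.write(f"{w}\t{self.concreteness[w]:.4f}\n")
        write_cdi_table(self.cdi, out / "cdi.tsv")
        with (out / "truth.json").open("w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

class _LexBuilder:
    """Deterministic lexicon assembly with pronunciation-uniqueness pools."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.lex = PronLexicon()
        self.used_prons: set[tuple[tuple[str, ...], ...]] = set()
        self._sealed_cursor = 0

    def _syllable(self) -> tuple[str, ...]:
        r = self.rng
        onset = _CONSONANTS[r.integers(len(_CONSONANTS))]
        nucleus = _VOWELS[r.integers(len(_VOWELS))]
        if r.random() < 0.5:
            coda = _CONSONANTS[r.integers(len(_CONSONANTS))]
            return (onset, nucleus, coda)
        return (onset, nucleus)

    def _pron(self, n_syll: int) -> tuple[tuple[str, ...], ...]:
        return tuple(self._syllable() for _ in range(n_syll))

    def add(self, word: str, n_syll: int, unique: bool = False) -> None:
        for _ in range(200):
            pron = self._pron(n_syll)
            if not unique or pron not in self.used_prons:
                break
        self.used_prons.add(pron)
        self.lex.add(word, pron)

    def add_variant(self, word: str, of: str) -> None:
        """One-phoneme substitution variant of an existing word (PhonN plant)."""
        base = [list(s) for s in self.lex.syllables(of)]
        for _ in range(200):
            pron = [list(s) for s in base]
            si = self.rng.integers(len(pron))
            pi = self.rng.integers(len(pron[si]))
            pool = _VOWELS if pron[si][pi] in _VOWELS else _CONSONANTS
            pron[si][pi] = pool[self.rng.integers(len(pool))]
            key = tuple(tuple(s) for s in pron)
            if key not in self.used_prons:
                self.used_prons.add(key)
                self.lex.add(word, key)
                return
        self.add(word, len(base), unique=True)

    def add_homophone(self, word: str, of: str) -> None:
        self.lex.add(word, self.lex.syllables(of))

    def add_sealed(self, word: str, n_syll: int) -> None:
        """Word built entirely from reserved, never-reused syllables."""
        sylls = []
        for _ in range(n_syll):
            onset = _SEALED_ONSETS[self._sealed_cursor % len(_SEALED_ONSETS)]
            nucleus = _VOWELS[(self._sealed_cursor // len(_SEALED_ONSETS)) % len(_VOWELS)]
            coda = _CONSONANTS[self._sealed_cursor % len(_CONSONANTS)]
            self._sealed_cursor += 1
            sylls.append((onset, nucleus, coda))
        self.lex.add(word, tuple(sylls))


@dataclass
class _Pools:
    targets: list[str]
    partners: list[str]
    singles: list[str]
    sealed: list[str]
    fillers: list[str]
    fillers_1syll: list[str]
    child_vocab: list[str]
    markers: dict[str, list[str]]  # corpus_id -> marker words


def _build_world(cfg: GeneratorConfig, rng: np.random.Generator
                 ) -> tuple[PronLexicon, dict[str, float], _Pools]:
    lb = _LexBuilder(rng)
    pools = _Pools([], [], [], [], [], [], [], {})

    for i in range(cfg.n_target_words):
        w = f"t{i:05d}"
        n_syll = 1 if rng.random() < 0.5 else 2
        if pools.targets and rng.random() < cfg.neighbor_rate:
            lb.add_variant(w, pools.targets[int(rng.integers(len(pools.targets)))])
        else:
            lb.add(w, n_syll, unique=True)
        pools.targets.append(w)

    n_partners = max(30, cfg.n_target_words // 4)
    for i in range(n_partners):
        w = f"p{i:04d}"
        lb.add(w, 1, unique=True)
        pools.partners.append(w)

    for i in range(cfg.n_single_word_types):
        w = f"s{i:04d}"
        lb.add(w, 2, unique=True)
        pools.singles.append(w)

    for i in range(cfg.n_sealed_words):
        w = f"q{i:03d}"
        lb.add_sealed(w, 2 + int(rng.random() < 0.3))
        pools.sealed.append(w)

    for i in range(cfg.vocab_size):
        w = f"f{i:05d}"
        if pools.fillers and rng.random() < cfg.homophone_rate:
            lb.add_homophone(w, pools.fillers[int(rng.integers(len(pools.fillers)))])
        else:
            n_syll = 1 + int(rng.choice(len(cfg.syllable_count_probs),
                                        p=cfg.syllable_count_probs))
            lb.add(w, n_syll)
        pools.fillers.append(w)
        if len(lb.lex.syllables(w)) == 1:
            pools.fillers_1syll.append(w)

    for i in range(max(50, cfg.vocab_size // 6)):
        w = f"c{i:04d}"
        lb.add(w, 1 + int(rng.integers(2)))
        pools.child_vocab.append(w)

    for c in range(cfg.n_corpora):
        cid = f"corpus{c}"
        pools.markers[cid] = []
        for i in range(3):
            w = f"name{c}x{i}"
            lb.add(w, 2)
            pools.markers[cid].append(w)

    concreteness = {
        w: float(np.round(1.0 + 4.0 * rng.random(), 4)) for w in sorted(lb.lex)
    }
    return lb.lex, concreteness, pools


def _rngs(cfg: GeneratorConfig) -> list[np.random.Generator]:
    """Independent streams for (lexicon, adult corpus, child corpus, plant)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(4)]


def generate_lexicon(cfg: GeneratorConfig) -> tuple[PronLexicon, dict[str, float]]:
    """The bundle's pronouncing lexicon and per-lemma concreteness ratings."""
    lex, con, _ = _build_world(cfg, _rngs(cfg)[0])
    return lex, con


# ---------------------------------------------------------------------------
# Adult corpus
# ---------------------------------------------------------------------------

def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks**-exponent
    return p / p.sum()


@dataclass
class _AdultWorld:
    lexicon: PronLexicon
    concreteness: dict[str, float]
    pools: _Pools
    adult_corpus: list[Utterance]
    short_templates: list[tuple[str, ...]]
    freq_templates: list[tuple[str, ...]]
    planted_N: int


def _cap_pois(rng, mean: float, lo: int, hi: int) -> int:
    return int(min(hi, max(lo, rng.poisson(mean))))


def _build_adult(cfg: GeneratorConfig, rng: np.random.Generator,
                 lexicon: PronLexicon, concreteness, pools: _Pools) -> _AdultWorld:
    corpora = [f"corpus{c}" for c in range(cfg.n_corpora)]
    n_tr = max(3, cfg.n_transcripts_per_corpus)
    lo_age, hi_age = cfg.child_age_range_months
    transcript_age = {
        (cid, j): float(np.round(lo_age + (hi_age - lo_age) * rng.random(), 1))
        for cid in corpora for j in range(n_tr)
    }

    used_seqs: set[tuple[str, ...]] = set()

    def template_syllables(words: Sequence[str]) -> tuple[str, ...]:
        return tuple(t for w in words for t in lexicon.syllable_tokens(w))

    def register(words: tuple[str, ...]) -> bool:
        seq = template_syllables(words)
        if seq in used_seqs:
            return False
        used_seqs.add(seq)
        return True

    for w in pools.singles + pools.sealed:
        used_seqs.add(template_syllables((w,)))

    # -- template families -------------------------------------------------
    short_templates: list[tuple[str, ...]] = []
    freq_templates: list[tuple[str, ...]] = []
    for w in pools.targets:
        k_s = int(rng.poisson(cfg.short_templates_per_word))
        k_f = int(rng.poisson(cfg.freq_templates_per_word))
        partner_idx = rng.permutation(len(pools.partners))
        cursor = 0
        made = 0
        while made < k_s and cursor < len(partner_idx):
            p = pools.partners[partner_idx[cursor]]
            cursor += 1
            words = (w, p) if rng.random() < 0.5 else (p, w)
            if register(words):
                short_templates.append(words)
                made += 1
        made = 0
        tries = 0
        while made < k_f and tries < 50:
            tries += 1
            ws = [w] + [pools.partners[i] for i in
                        rng.choice(len(pools.partners), size=4, replace=False)]
            while sum(len(lexicon.syllables(x)) for x in ws) < 6:
                ws.append(pools.partners[int(rng.integers(len(pools.partners)))])
            order = rng.permutation(len(ws))
            words = tuple(ws[i] for i in order)
            if register(words):
                freq_templates.append(words)
                made += 1

    # -- padding templates --------------------------------------------------
    # 4-5 syllable shared types built from partner words only.  They top up
    # the pool so that the N shortest MSUs (N = number of long templates)
    # cover the whole short family regardless of target syllable counts,
    # without contributing to any target word's #MSU count.
    n_pad = max(0, len(freq_templates) - len(short_templates)
                - len(pools.singles) - len(pools.sealed))
    padding: list[tuple[str, ...]] = []
    tries = 0
    while len(padding) < n_pad and tries < 20 * n_pad + 100:
        tries += 1
        k = 4 + int(rng.integers(2))
        ws = tuple(pools.partners[i] for i in
                   rng.choice(len(pools.partners), size=k, replace=False))
        if register(ws):
            padding.append(ws)

    # -- token realization --------------------------------------------------
    utts: list[Utterance] = []

    def emit(words: tuple[str, ...], freq: int) -> None:
        cs = rng.choice(cfg.n_corpora, size=2, replace=False)
        assignment = [corpora[cs[0]], corpora[cs[1]]]
        assignment += [corpora[c] for c in rng.integers(0, cfg.n_corpora, size=freq - 2)]
        for cid in assignment:
            j = int(rng.integers(n_tr))
            utts.append(Utterance(
                corpus_id=cid, transcript_id=f"{cid}_a{j:02d}",
                speaker_role=ADULT,
                child_age_months=transcript_age[(cid, j)],
                words=words,
            ))

    # Frequency bands keep the top-N-by-frequency set equal to the long
    # template family: long templates get >= 4 tokens, every other MSU type
    # at most 3.
    for words in short_templates:
        emit(words, _cap_pois(rng, cfg.short_template_freq, 2, 3))
    for words in freq_templates:
        emit(words, 4 + int(rng.poisson(max(0.0, cfg.freq_template_freq - 4))))
    for words in padding:
        emit(words, _cap_pois(rng, 2.5, 2, 3))
    for w in pools.singles:
        emit((w,), _cap_pois(rng, 2.5, 2, 3))
    for w in pools.sealed:
        emit((w,), _cap_pois(rng, 2.5, 2, 3))

    # -- idiosyncratic fillers (Zipf usage; marker word per corpus) ---------
    zipf_vocab = pools.fillers
    zp = _zipf_probs(len(zipf_vocab), cfg.zipf_exponent)
    single_pool = pools.fillers_1syll or pools.fillers
    for cid in corpora:
        markers = pools.markers[cid]
        for _ in range(cfg.n_filler_utterances):
            j = int(rng.integers(n_tr))
            age = transcript_age[(cid, j)]
            if rng.random() < cfg.single_word_rate:
                words = (single_pool[int(rng.integers(len(single_pool)))],)
            else:
                length = max(2, 1 + int(rng.poisson(cfg.mean_utterance_len - 1)))
                draw = [zipf_vocab[i] for i in
                        rng.choice(len(zipf_vocab), size=length - 1, p=zp)]
                pos = int(rng.integers(length))
                draw.insert(pos, markers[int(rng.integers(len(markers)))])
                words = tuple(draw)
            utts.append(Utterance(
                corpus_id=cid, transcript_id=f"{cid}_a{j:02d}",
                speaker_role=ADULT, child_age_months=age, words=words,
            ))
    # -- base usage of target words -----------------------------------------
    # Each target gets a heavy-tailed lognormal number of ordinary-speech
    # tokens, so its corpus frequency is dominated by running usage rather
    # than template membership (keeping Freq from acting as a collider
    # between the two #MSU counts).  Every such utterance carries a corpus
    # marker, so these types never survive the two-corpus filter.
    n_t = len(pools.targets)
    base_counts = np.clip(
        np.round(np.exp(rng.normal(cfg.target_usage_logmean,
                                   cfg.target_usage_logsd, size=n_t))),
        10, 2000,
    ).astype(int)
    tok_target = np.repeat(np.arange(n_t), base_counts)
    n_base = len(tok_target)
    tok_len = np.maximum(2, 1 + rng.poisson(max(0.0, cfg.mean_utterance_len - 1),
                                            size=n_base))
    n_extra = int((tok_len - 2).sum())
    extra = rng.choice(len(zipf_vocab), size=n_extra, p=zp)
    tok_corpus = rng.integers(0, cfg.n_corpora, size=n_base)
    tok_tr = rng.integers(0, n_tr, size=n_base)
    tok_marker = rng.integers(0, 3, size=n_base)
    pos_draw = rng.random(size=n_base)
    cursor = 0
    for i in range(n_base):
        L = int(tok_len[i])
        w = pools.targets[int(tok_target[i])]
        cid = corpora[int(tok_corpus[i])]
        words = [w] + [zipf_vocab[k] for k in extra[cursor:cursor + L - 2]]
        cursor += L - 2
        words.insert(int(pos_draw[i] * len(words) + 0.5) % (len(words) + 1),
                     pools.markers[cid][int(tok_marker[i])])
        j = int(tok_tr[i])
        utts.append(Utterance(
            corpus_id=cid, transcript_id=f"{cid}_a{j:02d}",
            speaker_role=ADULT,
            child_age_months=transcript_age[(cid, j)],
            words=tuple(words),
        ))

    order = rng.permutation(len(utts))
    utts = [utts[i] for i in order]
    planted_N = len(freq_templates)
    return _AdultWorld(lexicon, concreteness, pools, utts,
                       short_templates, freq_templates, planted_N)


def generate_adult_corpus(cfg: GeneratorConfig) -> list[Utterance]:
    """The adult (child-directed) utterance corpus of the bundle."""
    return _adult_world(cfg).adult_corpus


def _adult_world(cfg: GeneratorConfig) -> _AdultWorld:
    rngs = _rngs(cfg)
    lex, con, pools = _build_world(cfg, rngs[0])
    return _build_adult(cfg, rngs[1], lex, con, pools)


# ---------------------------------------------------------------------------
# Planted truth, child corpus, CDI
# ---------------------------------------------------------------------------

def _plant_truth(cfg: GeneratorConfig, rng: np.random.Generator,
                 world: _AdultWorld) -> dict:
    syll, _ = syllabify_corpus(world.adult_corpus, world.lexicon)
    pool = extract_candidate_msus(syll)
    N = world.planted_N
    metrics = [METRIC_SHORT, METRIC_FREQUENT]
    if cfg.planted_effect.predictor == METRIC_PREDICTABLE:
        from .chunk_selection import annotate_predictability, build_bigram_model

        pool = annotate_predictability(pool, build_bigram_model(syll))
        metrics.append(METRIC_PREDICTABLE)
    targets = world.pools.targets
    if N >= 1 and pool:
        sets = {m: rank_and_select(pool, m, N) for m in metrics}
        counts = {m: count_msu_per_word(targets, cs) for m, cs in sets.items()}
    else:
        counts = {m: {w: 0 for w in targets} for m in metrics}

    pe = cfg.planted_effect
    if pe.predictor in counts:
        x = np.log1p([counts[pe.predictor][w] for w in targets])
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(len(x))
    else:
        z = np.zeros(len(targets))
    eps = rng.normal(0.0, pe.resolved_noise_sd(), size=len(targets))
    y = -pe.slope * z + eps

    mu_log, sigma_log = 1.0, 0.25
    aofp_mlu = np.exp(mu_log + sigma_log * y)
    aofp_month = 23.0 + 4.0 * y

    truth = {
        "planted_N": N,
        "predictor": pe.predictor,
        "slope": pe.slope,
        "noise_sd": pe.resolved_noise_sd(),
        "n_short_templates": len(world.short_templates),
        "n_freq_templates": len(world.freq_templates),
        "n_msu_pool": len(pool),
        "sealed_words": list(world.pools.sealed),
        "targets": {
            w: {
                "y_std": float(y[i]),
                "aofp_mlu": float(aofp_mlu[i]),
                "aofp_month": float(aofp_month[i]),
                **{f"msu_{m}": counts[m][w] for m in metrics},
            }
            for i, w in enumerate(targets)
        },
    }
    return truth


def generate_child_corpus(
    cfg: GeneratorConfig,
    adult_truth: dict,
    world: _AdultWorld | None = None,
) -> tuple[list[Utterance], dict]:
    """Child transcripts with growing MLU and planted first productions.

    Each target word's first *valid* production (isolated, or embedded in
    child-only vocabulary) lands in the transcript whose MLU best matches
    its planted AoFP, in every corpus; with probability
    ``contamination_rate`` a corpus's production is instead embedded inside
    an adult MSU (and must be excluded by the AoFP estimator).  Returns the
    corpus and a realization record mapping words to the expected
    corpus-derived AoFP (``None`` when fewer than two corpora hold a valid
    production) and transcripts to their exact mean utterance lengths.
    """
    if world is None:
        world = _adult_world(cfg)
    rng = _rngs(cfg)[2]
    corpora = [f"corpus{c}" for c in range(cfg.n_corpora)]
    T = cfg.n_transcripts_per_corpus
    lo_age, hi_age = cfg.child_age_range_months
    cv = world.pools.child_vocab

    lengths_by_tid: dict[str, list[int]] = {}
    words_by_tid: dict[str, list[tuple[str, ...]]] = {}
    meta: dict[str, tuple[str, float]] = {}
    for cid in corpora:
        for t in range(T):
            tid = f"{cid}_ch{t:02d}"
            age = lo_age + (hi_age - lo_age) * (t / max(1, T - 1))
            mlu_t = cfg.mlu_growth.start + cfg.mlu_growth.slope * t
            if cfg.mlu_growth.noise_sd:
                mlu_t += rng.normal(0.0, cfg.mlu_growth.noise_sd)
            mlu_t = max(1.0, mlu_t)
            n = cfg.child_utterances_per_transcript
            if cfg.child_length_noise == 0:
                lengths = [max(1, round(mlu_t))] * n
            else:
                lengths = [1 + int(rng.poisson(max(0.0, mlu_t - 1))) for _ in range(n)]
            lengths_by_tid[tid] = lengths
            words_by_tid[tid] = [
                tuple(cv[i] for i in rng.integers(0, len(cv), size=L))
                for L in lengths
            ]
            meta[tid] = (cid, float(np.round(age, 1)))

    filler_mean = {tid: float(np.mean(ls)) for tid, ls in lengths_by_tid.items()}
    templates_by_word: dict[str, list[tuple[str, ...]]] = {}
    for words in world.short_templates + world.freq_templates:
        for w in set(words):
            templates_by_word.setdefault(w, []).append(words)

    truth_targets = adult_truth["targets"]
    placements: dict[str, dict[str, tuple[str, bool]]] = {}
    for w in sorted(truth_targets):
        aofp = truth_targets[w]["aofp_mlu"]
        placements[w] = {}
        for cid in corpora:
            tids = [f"{cid}_ch{t:02d}" for t in range(T)]
            tau = min(tids, key=lambda tid: abs(filler_mean[tid] - aofp))
            contaminated = rng.random() < cfg.contamination_rate
            if contaminated:
                # embed the production inside a verbatim adult MSU, in the
                # earliest transcript: must be excluded downstream.  A word
                # contained in no adult MSU cannot be produced inside one,
                # so its contaminated corpus simply yields no production.
                if w in templates_by_word:
                    tmpls = templates_by_word[w]
                    tmpl = tmpls[int(rng.integers(len(tmpls)))]
                    words_by_tid[tids[0]].append(tuple(tmpl))
                    lengths_by_tid[tids[0]].append(len(tmpl))
                placements[w][cid] = (tids[0], False)
            else:
                if rng.random() < 0.7:
                    prod = (w,)
                else:
                    prod = (cv[int(rng.integers(len(cv)))], w,
                            cv[int(rng.integers(len(cv)))])
                words_by_tid[tau].append(prod)
                lengths_by_tid[tau].append(len(prod))
                placements[w][cid] = (tau, True)

    realized_mlu = {tid: float(np.mean(ls)) for tid, ls in lengths_by_tid.items()}
    realized_aofp: dict[str, float | None] = {}
    for w, per_corpus in placements.items():
        valid = [tid for tid, ok in per_corpus.values() if ok]
        realized_aofp[w] = min(realized_mlu[t] for t in valid) if len(valid) >= 2 else None

    utts: list[Utterance] = []
    for tid in sorted(words_by_tid):
        cid, age = meta[tid]
        for words in words_by_tid[tid]:
            utts.append(Utterance(
                corpus_id=cid, transcript_id=tid, speaker_role=CHILD,
                child_age_months=age, words=words,
            ))
    realization = {
        "transcript_mlu": realized_mlu,
        "expected_corpus_aofp": realized_aofp,
    }
    return utts, realization


def generate_cdi_table(
    cfg: GeneratorConfig, aofp_months: Mapping[str, float]
) -> CDITable:
    """Logistic production-proportion curves crossing 50% at the planted month.

    A word planted at month m first reaches 0.5 at ceil(m); months planted
    past the instrument's 30-month ceiling never cross and are omitted by
    the 50% rule downstream.
    """
    months = np.array(CDI_MONTHS, dtype=float)
    scale = 0.4
    rows = {}
    for w in sorted(aofp_months):
        m0 = aofp_months[w]
        rows[w] = 1.0 / (1.0 + np.exp(-(months - m0) / scale))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CDI_MONTHS))
    df.index.name = "word"
    return CDITable(rows=df)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def generate_bundle(cfg: GeneratorConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle deterministically from the config."""
    world = _adult_world(cfg)
    truth = _plant_truth(cfg, _rngs(cfg)[3], world)
    child, realization = generate_child_corpus(cfg, truth, world=world)
    truth.update(realization)
    cdi = generate_cdi_table(
        cfg, {w: d["aofp_month"] for w, d in truth["targets"].items()}
    )
    return SyntheticBundle(
        config=cfg,
        lexicon=world.lexicon,
        concreteness=world.concreteness,
        adult_corpus=world.adult_corpus,
        child_corpus=child,
        cdi=cdi,
        truth=truth,
    )
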