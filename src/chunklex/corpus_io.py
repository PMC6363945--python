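"""Corpus and lexicon I/O, syllabification, speaker partitioning.

Utterance corpora arrive as line-oriented tables (TSV or JSONL) of tokenized
speaker turns with corpus/transcript/speaker/age metadata.  Words are mapped
to syllable representations through a syllabified pronouncing lexicon in the
CMU-dictionary dialect (``word<TAB>syllables``, syllables separated by
`` - ``, phonemes by single spaces).  Only utterances whose every word has a
lexicon entry survive syllabification; the surviving fraction is reported as
coverage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("chunklex")

ADULT = "adult"
CHILD = "child"

#: Canonical separator used to render a syllable (a phoneme sequence) as a
#: single string token.  Syllable identity is by phoneme sequence, not
#: orthography.
SYLLABLE_JOIN = "."

_UTTERANCE_COLUMNS = (
    "corpus_id",
    "transcript_id",
    "speaker_role",
    "child_age_months",
    "utterance",
)


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


@dataclass(frozen=True)
class Utterance:
    """One tokenized speaker turn.

    ``child_age_months`` is the age of the addressed (or speaking) child and
    may be ``None`` when the transcript does not record it.
    """

    corpus_id: str
    transcript_id: str
    speaker_role: str
    child_age_months: float | None
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("utterance must contain at least one word")
        if any((" " in w) or ("\t" in w) or not w for w in self.words):
            raise ValueError("word tokens must be non-empty and whitespace-free")
        if self.speaker_role not in (ADULT, CHILD):
            raise ValueError(f"unknown speaker role: {self.speaker_role!r}")
        if self.child_age_months is not None and self.child_age_months < 0:
            raise ValueError("child_age_months must be non-negative")


class PronLexicon:
    """Case-insensitive word -> syllabification lookup.

    Each entry maps a word to an ordered list of syllables, each syllable an
    ordered tuple of phoneme symbols.  Stress digits are stripped at parse
    time, so phoneme identity ignores lexical stress.
    """

    def __init__(self, entries: dict[str, tuple[tuple[str, ...], ...]] | None = None):
        self._entries: dict[str, tuple[tuple[str, ...], ...]] = {}
        self._tokens: dict[str, tuple[str, ...]] = {}
        if entries:
            for word, sylls in entries.items():
                self.add(word, sylls)

    def add(self, word: str, syllables: Sequence[Sequence[str]]) -> bool:
        """Add an entry; first pronunciation wins.  Returns False if duplicate."""
        key = word.lower()
        sylls = tuple(tuple(s) for s in syllables)
        if not sylls or any(not s for s in sylls):
            raise ValueError(f"entry for {word!r} must have >=1 syllable, each with >=1 phoneme")
        if key in self._entries:
            return False
        self._entries[key] = sylls
        self._tokens[key] = tuple(SYLLABLE_JOIN.join(s) for s in sylls)
        return True

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def syllables(self, word: str) -> tuple[tuple[str, ...], ...]:
        return self._entries[word.lower()]

    def phonemes(self, word: str) -> tuple[str, ...]:
        """Flattened phoneme sequence of the word's pronunciation."""
        return tuple(p for syll in self.syllables(word) for p in syll)

    def syllable_tokens(self, word: str) -> tuple[str, ...]:
        """Syllables rendered as canonical string tokens."""
        return self._tokens[word.lower()]

    def items(self):
        return self._entries.items()


@dataclass(frozen=True)
class SyllabifiedUtterance:
    """An utterance mapped to syllable tokens, with per-word syllable spans.

    ``word_boundaries[i] = (start, stop)`` gives the half-open span of
    ``syllables`` produced by ``source.words[i]``.
    """

    source: Utterance
    syllables: tuple[str, ...]
    word_boundaries: tuple[tuple[int, int], ...]

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)


def _strip_stress(phoneme: str) -> str:
    return phoneme.rstrip("0123456789")


# ---------------------------------------------------------------------------
# Reading and writing utterance tables
# ---------------------------------------------------------------------------

def _parse_row(corpus_id: str, transcript_id: str, speaker_role: str,
               age: str, utterance: str) -> Utterance | None:
    words = tuple(w.lower() for w in utterance.split())
    if not words:
        return None
    age_val: float | None
    age_str = age.strip()
    age_val = float(age_str) if age_str not in ("", "NA", "nan", "None") else None
    return Utterance(
        corpus_id=corpus_id.strip(),
        transcript_id=transcript_id.strip(),
        speaker_role=speaker_role.strip().lower(),
        child_age_months=age_val,
        words=words,
    )


def read_utterances(path: str | Path, format: str = "tsv") -> list[Utterance]:
    """Read an utterance table; one :class:`Utterance` per row, order preserved.

    Rows with an empty token list are rejected with a logged warning.
    """
    path = Path(path)
    out: list[Utterance] = []
    if format == "tsv":
        with path.open(encoding="utf-8") as fh:
            header_line = fh.readline()
            if not header_line:
                return out
            header = header_line.rstrip("\n").split("\t")
            for col in _UTTERANCE_COLUMNS:
                if col not in header:
                    raise FormatError(f"missing required column: {col!r}")
            idx = {col: header.index(col) for col in _UTTERANCE_COLUMNS}
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < len(header):
                    raise FormatError(f"line {lineno}: expected {len(header)} fields")
                utt = _parse_row(*(fields[idx[c]] for c in _UTTERANCE_COLUMNS))
                if utt is None:
                    logger.warning("line %d: empty utterance, row rejected", lineno)
                    continue
                out.append(utt)
    elif format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                for col in _UTTERANCE_COLUMNS:
                    if col not in rec:
                        raise FormatError(f"line {lineno}: missing required field: {col!r}")
                utt = _parse_row(
                    str(rec["corpus_id"]), str(rec["transcript_id"]),
                    str(rec["speaker_role"]),
                    "" if rec["child_age_months"] is None else str(rec["child_age_months"]),
                    str(rec["utterance"]),
                )
                if utt is None:
                    logger.warning("line %d: empty utterance, row rejected", lineno)
                    continue
                out.append(utt)
    else:
        raise ValueError(f"unknown format: {format!r}")
    return out


def write_utterances(utts: Iterable[Utterance], path: str | Path) -> None:
    """Write utterances as TSV (inverse of :func:`read_utterances`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_UTTERANCE_COLUMNS) + "\n")
        for u in utts:
            age = "" if u.child_age_months is None else format(u.child_age_months, "g")
            fh.write("\t".join([
                u.corpus_id, u.transcript_id, u.speaker_role, age, " ".join(u.words),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Pronouncing lexicon
# ---------------------------------------------------------------------------

def read_pron_lexicon(path: str | Path) -> PronLexicon:
    """Parse a syllabified pronouncing dictionary.

    Format: ``word<TAB>syllables`` where syllables are separated by " - "
    and phonemes within a syllable by single spaces.  Duplicate words keep
    the first pronunciation (a warning is logged).  Stress digits on
    phonemes are stripped.
    """
    path = Path(path)
    lex = PronLexicon()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(f"line {lineno}: expected 'word<TAB>syllables'")
            word, syll_field = parts
            syllables = []
            for syll in syll_field.split(" - "):
                phonemes = tuple(_strip_stress(p) for p in syll.split() if p)
                if not phonemes:
                    raise FormatError(f"line {lineno}: empty syllable in {word!r}")
                syllables.append(phonemes)
            if not lex.add(word, syllables):
                logger.warning("line %d: duplicate entry for %r, keeping first", lineno, word)
    return lex


def write_pron_lexicon(lex: PronLexicon, path: str | Path) -> None:
    """Write a lexicon in the same dialect :func:`read_pron_lexicon` parses."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for word, sylls in lex.items():
            fh.write(word + "\t" + " - ".join(" ".join(s) for s in sylls) + "\n")


# ---------------------------------------------------------------------------
# Syllabification and speaker partitioning
# ---------------------------------------------------------------------------

def syllabify_utterance(utt: Utterance, lex: PronLexicon) -> SyllabifiedUtterance | None:
    """Map one utterance to syllables; None if any word lacks a lexicon entry."""
    syllables: list[str] = []
    boundaries: list[tuple[int, int]] = []
    for word in utt.words:
        if word not in lex:
            return None
        toks = lex.syllable_tokens(word)
        start = len(syllables)
        syllables.extend(toks)
        boundaries.append((start, len(syllables)))
    return SyllabifiedUtterance(
        source=utt, syllables=tuple(syllables), word_boundaries=tuple(boundaries)
    )


def syllabify_corpus(
    utts: Sequence[Utterance], lex: PronLexicon
) -> tuple[list[SyllabifiedUtterance], float]:
    """Syllabify a corpus, keeping only fully covered utterances.

    Returns the retained syllabified utterances (input order preserved) and
    the coverage fraction retained/total (1.0 for an empty input).
    """
    out: list[SyllabifiedUtterance] = []
    for utt in utts:
        syl = syllabify_utterance(utt, lex)
        if syl is not None:
            out.append(syl)
    coverage = len(out) / len(utts) if utts else 1.0
    return out, coverage


def split_speakers(
    utts: Sequence[SyllabifiedUtterance],
) -> tuple[list[SyllabifiedUtterance], list[SyllabifiedUtterance]]:
    """Partition syllabified utterances into (adult, child) streams."""
    adult: list[SyllabifiedUtterance] = []
    child: list[SyllabifiedUtterance] = []
    for u in utts:
        role = u.source.speaker_role
        if role == ADULT:
            adult.append(u)
        elif role == CHILD:
            child.append(u)
        else:  # pragma: no cover - Utterance validation forbids this
            raise ValueError(f"unknown speaker role: {role!r}")
    return adult, child
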