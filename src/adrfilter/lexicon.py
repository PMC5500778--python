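"""Disorder lexicon (MedDRA-like LLT→PT→SOC) and drug list handling.

The disorder lexicon maps surface terms — including lay expressions and
common misspellings — to lowest-level-term (LLT) identifiers, each LLT
belonging to exactly one preferred term (PT) and each PT to one system organ
class (SOC).  MedDRA itself is licensed content, so the package ships only a
small synthetic fixture with the same schema; real terminologies are
user-supplied CSVs.

Two canonicalisation keys drive matching:

* :func:`stem` — a light French stem; disorder terms are matched by exact
  equality of per-token stems.
* :func:`fuzzy_key` — an aggressive misspelling-conflation key: accents
  folded, every vowel after the first removed, runs of identical consonants
  collapsed.  "modeling" and "modelling" share a key.  Drug names are
  matched by equality of fuzzy keys of stems.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence, Union

from .preprocess import normalize, separate_punctuation
from .stemming import french_minimal_stem

__all__ = [
    "LexiconEntry",
    "DrugEntry",
    "MatchIndex",
    "fuzzy_key",
    "stem",
    "load_disorder_lexicon",
    "load_drug_list",
    "build_index",
    "LexiconFormatError",
    "LexiconAmbiguityError",
]

VOWELS = set("aeiouy")


class LexiconFormatError(ValueError):
    """Raised when a lexicon CSV is malformed (e.g. a missing column)."""


class LexiconAmbiguityError(ValueError):
    """Raised when one surface term maps to two different LLT ids."""


@dataclass(frozen=True)
class LexiconEntry:
    surface_term: str  # normalized, possibly multi-word
    llt_id: str
    llt_label: str
    pt_id: str
    pt_label: str
    soc_label: str


@dataclass(frozen=True)
class DrugEntry:
    drug_name: str  # normalized
    drug_id: str


def _fold_accents(word: str) -> str:
    return "".join(
        ch for ch in unicodedata.normalize("NFD", word) if not unicodedata.combining(ch)
    )


def fuzzy_key(word: str) -> str:
    """Misspelling-conflation key for one token.

    Accents are folded to base letters, every vowel after the first vowel
    occurrence is removed, then runs of identical consecutive consonants
    collapse to a single letter.  'y' counts as a vowel.  Deterministic;
    empty token maps to empty key.
    """
    word = _fold_accents(word)
    out: list[str] = []
    seen_vowel = False
    for ch in word:
        if ch in VOWELS:
            if not seen_vowel:
                out.append(ch)
                seen_vowel = True
        else:
            out.append(ch)
    collapsed: list[str] = []
    for ch in out:
        if not (collapsed and collapsed[-1] == ch and ch not in VOWELS):
            collapsed.append(ch)
    return "".join(collapsed)


def stem(word: str, stemmer: Callable[[str], str] = french_minimal_stem) -> str:
    """Stem a single normalized token with the pluggable stemmer."""
    return stemmer(word)


def _normalize_term(term: str) -> str:
    return normalize(separate_punctuation(term))


_DISORDER_COLUMNS = ["surface_term", "llt_id", "llt_label", "pt_id", "pt_label", "soc_label"]


def load_disorder_lexicon(path: Union[str, Path]) -> list[LexiconEntry]:
    """Load and normalize the disorder lexicon CSV.

    Surface terms are normalised exactly as message text (punctuation
    separation + lowercasing) so a term's token span length is the same on
    both sides of a match.  Duplicate surface terms under the same LLT are
    deduplicated; the same surface under two different LLT ids is a fatal
    ambiguity.
    """
    entries: dict[tuple[str, str], LexiconEntry] = {}
    surface_to_llt: dict[str, str] = {}
    with open(path, encoding="utf-8-sig", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _DISORDER_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise LexiconFormatError(
                f"{path}: missing column(s) {', '.join(missing)}"
            )
        for row in reader:
            surface = _normalize_term(row["surface_term"])
            if not surface:
                raise LexiconFormatError(f"{path}: empty surface_term in row {row}")
            llt_id = row["llt_id"].strip()
            prior = surface_to_llt.get(surface)
            if prior is not None and prior != llt_id:
                raise LexiconAmbiguityError(
                    f"surface term {surface!r} maps to two LLT ids: {prior} and {llt_id}"
                )
            surface_to_llt[surface] = llt_id
            entries[(surface, llt_id)] = LexiconEntry(
                surface_term=surface,
                llt_id=llt_id,
                llt_label=row["llt_label"].strip(),
                pt_id=row["pt_id"].strip(),
                pt_label=row["pt_label"].strip(),
                soc_label=row["soc_label"].strip(),
            )
    return sorted(entries.values(), key=lambda e: (e.llt_id, e.surface_term))


def load_drug_list(path: Union[str, Path]) -> list[DrugEntry]:
    """Load the drug-name CSV (columns: drug_name, drug_id)."""
    out: dict[str, DrugEntry] = {}
    with open(path, encoding="utf-8-sig", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("drug_name", "drug_id") if c not in (reader.fieldnames or [])]
        if missing:
            raise LexiconFormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for row in reader:
            name = _normalize_term(row["drug_name"])
            if not name:
                raise LexiconFormatError(f"{path}: empty drug_name in row {row}")
            out[name] = DrugEntry(drug_name=name, drug_id=row["drug_id"].strip())
    return sorted(out.values(), key=lambda d: d.drug_id)


Entry = Union[LexiconEntry, DrugEntry]


@dataclass
class MatchIndex:
    """Key-sequence → candidate-entries map used by the NER stage.

    Keys are tuples of per-token canonical forms: per-token stems in
    ``exact-stemmed`` mode (disorders), fuzzy keys of stems in ``fuzzy``
    mode (drugs).  Colliding entries are retained as multi-candidate keys;
    the NER longest-match policy resolves them.
    """

    mode: Literal["exact-stemmed", "fuzzy"]
    mapping: dict[tuple[str, ...], tuple[Entry, ...]] = field(default_factory=dict)
    max_term_length: int = 0

    def key_for_tokens(self, tokens: Sequence[str]) -> tuple[str, ...]:
        if self.mode == "exact-stemmed":
            return tuple(stem(t) for t in tokens)
        return tuple(fuzzy_key(stem(t)) for t in tokens)

    def lookup(self, tokens: Sequence[str]) -> tuple[Entry, ...]:
        return self.mapping.get(self.key_for_tokens(tokens), ())


def build_index(
    entries: Iterable[Entry], mode: Literal["exact-stemmed", "fuzzy"]
) -> MatchIndex:
    """Index entries under their canonical key sequences.

    Deterministic regardless of input order: candidates under one key are
    sorted by id.
    """
    index = MatchIndex(mode=mode)
    buckets: dict[tuple[str, ...], list[Entry]] = {}
    for entry in entries:
        term = entry.surface_term if isinstance(entry, LexiconEntry) else entry.drug_name
        tokens = term.split()
        key = index.key_for_tokens(tokens)
        buckets.setdefault(key, []).append(entry)
        index.max_term_length = max(index.max_term_length, len(tokens))

    def _id(e: Entry) -> str:
        return e.llt_id if isinstance(e, LexiconEntry) else e.drug_id

    index.mapping = {k: tuple(sorted(v, key=_id)) for k, v in buckets.items()}
    return index
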