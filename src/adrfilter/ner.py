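"""Lexicon-based recognition of drug and disorder mentions.

Matching runs in two passes over the positioned token sequence:

1. drugs, by equality of fuzzy-keyed stems (robust to misspellings such as
   a dropped vowel or doubled consonant) — matched tokens are *consumed* so
   a drug name that happens to be a lexicon word cannot double-count;
2. disorders, by exact equality of per-token stems, longest-match-wins:
   candidate spans are resolved longer-first (ties leftmost), so
   "mal de tête" beats its prefix "mal".

Every emitted mention records the surface span, the canonical id (drug_id
or LLT id, with the PT id for disorders) and the 1-based token position of
the first token — the position the distance statistic uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .lexicon import DrugEntry, LexiconEntry, MatchIndex
from .preprocess import TokenSequence

__all__ = ["Mention", "match_drugs", "match_disorders", "recognize"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Mention:
    message_id: str
    kind: Literal["drug", "disorder"]
    surface: str            # matched tokens joined by single spaces
    canonical_id: str       # drug_id or llt_id
    start_pos: int          # 1-based token index of first token of span
    span_len: int
    pt_id: Optional[str] = None   # disorders only
    pt_label: str = ""            # disorders only
    canonical_label: str = ""     # drug_name or llt_label

    @property
    def end_pos(self) -> int:
        return self.start_pos + self.span_len - 1


def _longest_match(
    tokens: TokenSequence,
    index: MatchIndex,
    kind: Literal["drug", "disorder"],
    consumed: set[int],
) -> list[Mention]:
    """Longest-match-wins over non-consumed positions.

    All candidate spans are enumerated, then resolved greedily longest span
    first (ties: leftmost), consuming positions as matches are accepted —
    so a long term always beats any shorter term it overlaps, regardless of
    which starts first.
    """
    n = len(tokens)
    max_len = index.max_term_length
    candidates: list[tuple[int, int]] = []  # (0-based start, span length)
    for i in range(n):
        for span in range(1, min(max_len, n - i) + 1):
            if index.lookup(tokens.tokens[i : i + span]):
                candidates.append((i, span))
    candidates.sort(key=lambda c: (-c[1], c[0]))

    mentions: list[Mention] = []
    for i, span in candidates:
        pos = i + 1
        span_positions = range(pos, pos + span)
        if any(p in consumed for p in span_positions):
            continue
        entries = index.lookup(tokens.tokens[i : i + span])
        entry = entries[0]  # smallest id wins (sorted at indexing)
        if len(entries) > 1:
            ids = [getattr(c, "llt_id", getattr(c, "drug_id", "?")) for c in entries]
            logger.warning(
                "ambiguous surface at %s pos %d: candidates %s; keeping %s",
                tokens.message_id, pos, ids, ids[0],
            )
        if isinstance(entry, LexiconEntry):
            mention = Mention(
                message_id=tokens.message_id,
                kind=kind,
                surface=" ".join(tokens.tokens[i : i + span]),
                canonical_id=entry.llt_id,
                start_pos=pos,
                span_len=span,
                pt_id=entry.pt_id,
                pt_label=entry.pt_label,
                canonical_label=entry.llt_label,
            )
        else:
            mention = Mention(
                message_id=tokens.message_id,
                kind=kind,
                surface=" ".join(tokens.tokens[i : i + span]),
                canonical_id=entry.drug_id,
                start_pos=pos,
                span_len=span,
                canonical_label=entry.drug_name,
            )
        mentions.append(mention)
        consumed.update(span_positions)
    mentions.sort(key=lambda m: m.start_pos)
    return mentions


def match_drugs(tokens: TokenSequence, drug_index: MatchIndex) -> list[Mention]:
    """Recognize drug mentions by fuzzy matching; marks tokens consumed.

    Returns mentions in reading order.  The consumed positions are those
    covered by the returned mentions (reconstructable from start_pos and
    span_len).
    """
    if drug_index.mode != "fuzzy":
        raise ValueError("drug index must be built in fuzzy mode")
    return _longest_match(tokens, drug_index, "drug", set())


def match_disorders(
    tokens: TokenSequence,
    disorder_index: MatchIndex,
    consumed: Iterable[int] = (),
) -> list[Mention]:
    """Recognize disorder mentions by exact match of stems.

    ``consumed`` holds the token positions already claimed by drug
    mentions; no disorder span may overlap them.
    """
    if disorder_index.mode != "exact-stemmed":
        raise ValueError("disorder index must be built in exact-stemmed mode")
    return _longest_match(tokens, disorder_index, "disorder", set(consumed))


def recognize(
    tokens: TokenSequence, drug_index: MatchIndex, disorder_index: MatchIndex
) -> list[Mention]:
    """Both passes in precedence order (drugs first); reading-order output."""
    drugs = match_drugs(tokens, drug_index)
    consumed = {p for m in drugs for p in range(m.start_pos, m.end_pos + 1)}
    disorders = match_disorders(tokens, disorder_index, consumed)
    return sorted(drugs + disorders, key=lambda m: m.start_pos)
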