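"""Drug–disorder pairs and the signed word-distance statistic.

For a drug mention *a* and a disorder mention *b* in the same message,

    distance(a, b) = (position of b) − (position of a)

in words, negative when the disorder precedes the drug.  When the same drug
name occurs several times in a message, each disorder keeps only the
occurrence minimising |distance|; distinct drug names each yield their own
pair.  Ties between an equally distant occurrence before and after the
disorder keep the positive distance (disorder after drug) — fixed so the
rule is deterministic and oracle-checkable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from .ner import Mention

__all__ = ["Pair", "distance", "enumerate_pairs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pair:
    message_id: str
    drug_mention: Mention
    disorder_mention: Mention
    distance: int                  # signed, words; never 0
    relative_position: Literal["before", "after"]
    message_length: int            # tokens

    @property
    def llt_id(self) -> str:
        return self.disorder_mention.canonical_id

    @property
    def pt_id(self) -> str:
        return self.disorder_mention.pt_id or ""

    @property
    def drug_name(self) -> str:
        return self.drug_mention.canonical_label


def distance(drug_pos: int, disorder_pos: int) -> int:
    """Signed word distance: disorder position minus drug position."""
    if drug_pos < 1 or disorder_pos < 1:
        raise ValueError("token positions are 1-based")
    if drug_pos == disorder_pos:
        raise ValueError("drug and disorder cannot share a position")
    return disorder_pos - drug_pos


def _pair_sort_key(d: int) -> tuple[int, int]:
    # minimise |d|; tie between -d and +d keeps the positive
    return (abs(d), 0 if d > 0 else 1)


def enumerate_pairs(mentions: Sequence[Mention], message_length: int) -> list[Pair]:
    """Build deduplicated pairs for one message.

    For each disorder mention and each *distinct drug name*, the distances
    to every occurrence of that drug name are computed and only the
    occurrence with minimal |distance| is kept.  Messages with no drug
    mention yield no pairs (logged as drug-free); messages with drugs but
    no disorder yield zero pairs.
    """
    drugs = [m for m in mentions if m.kind == "drug"]
    disorders = [m for m in mentions if m.kind == "disorder"]
    if not drugs:
        if disorders:
            logger.info("message %s has disorders but no drug mention", disorders[0].message_id)
        return []
    by_name: dict[str, list[Mention]] = {}
    for d in drugs:
        by_name.setdefault(d.canonical_id, []).append(d)

    pairs: list[Pair] = []
    for disorder in disorders:
        for _drug_id, occurrences in sorted(by_name.items()):
            best = min(
                occurrences,
                key=lambda occ: _pair_sort_key(distance(occ.start_pos, disorder.start_pos)),
            )
            d = distance(best.start_pos, disorder.start_pos)
            pairs.append(
                Pair(
                    message_id=disorder.message_id,
                    drug_mention=best,
                    disorder_mention=disorder,
                    distance=d,
                    relative_position="before" if d < 0 else "after",
                    message_length=message_length,
                )
            )
    return pairs
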