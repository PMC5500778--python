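"""Text normalisation and positioned tokenisation of forum messages.

The distance statistic downstream is defined purely in words — a word being
a maximal run of non-whitespace characters — so preprocessing fixes the word
positions everything else depends on.  Three steps, applied in order:

1. ``separate_punctuation`` — insert a space on both sides of every
   punctuation character, so punctuation glued to words ("mal!!") does not
   hide lexicon terms;
2. ``normalize`` — lowercase (Unicode-aware, accents preserved) and collapse
   whitespace;
3. ``tokenize`` — split on whitespace, recording 1-based positions.

Stop words are never removed: dropping them would change word distances.
Punctuation marks become tokens of their own and count as words.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Message",
    "TokenSequence",
    "separate_punctuation",
    "normalize",
    "tokenize",
    "preprocess_message",
]

#: ASCII symbols treated as punctuation in addition to Unicode category P*.
#: Covers emoticon building blocks and math symbols glued to words.
ASCII_SYMBOLS = set("!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~")


@dataclass(frozen=True)
class Message:
    """A raw forum post with its corpus metadata."""

    message_id: str
    text: str
    source: str = ""
    date: Optional[str] = None  # ISO-8601 or None


@dataclass(frozen=True)
class TokenSequence:
    """Ordered tokens of one message with 1-based positions.

    Invariants: no token contains whitespace; ``positions == 1..n``;
    ``" ".join(tokens)`` reproduces the normalised text.
    """

    tokens: tuple[str, ...]
    message_id: str = ""

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.tokens) + 1))

    def __len__(self) -> int:
        return len(self.tokens)


def _is_punct(ch: str) -> bool:
    if ch in ASCII_SYMBOLS:
        return True
    return unicodedata.category(ch).startswith("P")


def separate_punctuation(text: str) -> str:
    """Insert whitespace around every punctuation character.

    Letters and digits are untouched; digits count as word characters.
    Idempotent after the first application (the inserted spaces are later
    collapsed by :func:`normalize`).
    """
    out: list[str] = []
    n = len(text)
    for i, ch in enumerate(text):
        if _is_punct(ch):
            # skip the pad if a space is already there, so the function is
            # idempotent: f(f(x)) == f(x)
            if out and not out[-1].isspace():
                out.append(" ")
            out.append(ch)
            if i + 1 < n and not text[i + 1].isspace():
                out.append(" ")
        else:
            out.append(ch)
    return "".join(out)


def normalize(text: str) -> str:
    """Lowercase and collapse runs of whitespace to single spaces.

    Unicode-aware lowering; accented characters are preserved, never
    transliterated (accent folding happens only inside the fuzzy matching
    key, not here).  Idempotent.
    """
    return " ".join(text.lower().split())


def tokenize(text: str, message_id: str = "") -> TokenSequence:
    """Split normalised text on whitespace into positioned tokens.

    ``text`` is expected to have passed through :func:`separate_punctuation`
    and :func:`normalize`; the function itself only splits.  Empty text
    yields an empty sequence — empty messages are retained, not rejected, so
    corpus bookkeeping stays auditable.
    """
    return TokenSequence(tokens=tuple(text.split()), message_id=message_id)


def preprocess_message(msg: Message) -> TokenSequence:
    """Full preprocessing chain for one message."""
    return tokenize(normalize(separate_punctuation(msg.text)), message_id=msg.message_id)
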