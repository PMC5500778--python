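"""Light French stemming.

Forum posts are colloquial French; matching lexicon terms against them
requires conflating inflected forms (plurals, feminines, infinitives).  The
default stemmer is a light suffix-stripping algorithm in the Savoy family
for French: it removes plural/feminine markers (-s, -x, -r, -e, -é), maps
-aux to -al, and collapses a doubled final consonant.  One pass can expose a
new strippable suffix, so the pass is iterated to a fixed point — this makes
``stem(stem(w)) == stem(w)`` hold by construction.

The stemmer is deliberately pluggable (see :func:`adrfilter.lexicon.stem`):
light stemmers differ in the margins and any deterministic token→token map
with the fixpoint property can be swapped in.
"""

from __future__ import annotations

__all__ = ["french_minimal_stem"]


def _one_pass(word: str) -> str:
    n = len(word)
    if n < 6:
        return word
    if word.endswith("x"):
        if word.endswith("aux"):
            return word[:-2] + "l"  # chevaux -> cheval
        return word[:-1]
    if word.endswith("s"):
        word = word[:-1]
    if word.endswith("r"):
        word = word[:-1]
    if word.endswith("e"):
        word = word[:-1]
    if word.endswith("é"):
        word = word[:-1]
    if len(word) >= 2 and word[-1] == word[-2]:
        word = word[:-1]
    return word


def french_minimal_stem(word: str) -> str:
    """Stem one normalized token; idempotent and deterministic.

    Tokens shorter than 6 characters pass through unchanged — stripping
    short French words (``mal``, ``os``) destroys them.
    """
    prev = word
    cur = _one_pass(word)
    while cur != prev:
        prev = cur
        cur = _one_pass(cur)
    return cur
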