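"""Tokenize a colloquial forum post and recognize its entities.

Punctuation is split off so glued terms match, everything is lowercased,
and every token gets a 1-based position — the positions the distance
statistic is built on.  Drug names match through a misspelling-tolerant
fuzzy key; disorders match by exact stem equality, longest term first.
"""

from adrfilter import (
    DrugEntry,
    LexiconEntry,
    Message,
    build_index,
    preprocess_message,
    recognize,
)

lexicon = [
    LexiconEntry("mal de tête", "L006", "mal de tête", "P005", "headache", "nervous system"),
    LexiconEntry("insomnie", "L001", "insomnie", "P001", "insomnia", "psychiatric"),
]
drugs = [DrugEntry("zolpidem", "D001")]

msg = Message("m1", "J'ai pris du zolpidme hier soir, toujours mal de tête!!")
tokens = preprocess_message(msg)
print("tokens:", list(tokens.tokens))

mentions = recognize(tokens, build_index(drugs, "fuzzy"), build_index(lexicon, "exact-stemmed"))
for m in mentions:
    print(f"{m.kind:8s} {m.surface!r:16s} position {m.start_pos} (span {m.span_len})")
# The misspelled 'zolpidme' still matches zolpidem because both collapse to
# the same vowel-stripped key; 'mal de tête' matches as one 3-token span.
# Note disorder matching is exact after stemming (accents preserved), so the
# lexicon surface must carry the accent the forum text uses.
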