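"""Signed word distances between a drug and the disorders around it.

distance = (position of disorder) − (position of drug); negative means the
disorder is narrated before the drug.  When a drug name occurs twice, each
disorder keeps only the occurrence with the smallest |distance|.
"""

from adrfilter import (
    DrugEntry,
    LexiconEntry,
    Message,
    build_index,
    enumerate_pairs,
    preprocess_message,
    recognize,
)

lexicon = [
    LexiconEntry("headache", "L005", "headache", "P005", "headache", "nervous system"),
    LexiconEntry("insomnia", "L001", "insomnia", "P001", "insomnia", "psychiatric"),
]
drugs = [DrugEntry("aspirin", "D003")]

msg = Message("m1", "i took aspirin , it gave me a terrible headache")
tokens = preprocess_message(msg)
pairs = enumerate_pairs(
    recognize(tokens, build_index(drugs, "fuzzy"), build_index(lexicon, "exact-stemmed")),
    len(tokens),
)
for p in pairs:
    print(
        f"{p.drug_name} (pos {p.drug_mention.start_pos}) -> "
        f"{p.disorder_mention.surface} (pos {p.disorder_mention.start_pos}): "
        f"distance {p.distance:+d} words, {p.relative_position} the drug"
    )
# 'headache' sits 7 words after 'aspirin': the short positive distance is
# the signature of an ADR narration.
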