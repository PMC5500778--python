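"""Synthetic forum-like corpora with planted mentions and gold labels.

The original study corpus (French patient-forum posts) and its MedDRA-
derived lexicon are proprietary, so every pipeline stage is exercised on
generated data instead.  A generated message is a sequence of filler tokens
(a closed vocabulary disjoint from the lexicon, plus punctuation marks)
into which one drug name and zero or more disorder terms are planted at
signed word offsets drawn from class-conditional laws:

* ADR pairs    — a tight normal around a small positive offset
  (default N(+10, 30) words: reactions are narrated shortly after the drug);
* other pairs  — a zero-centred two-component mixture, 0.6·N(0, 80) +
  0.4·N(0, 450), giving the wide, heavy-tailed spread of incidental
  co-occurrences.

Default condition parameters emulate the corpus the method was developed
on: 648 messages, ≈11.4% ADR prevalence among pairs, ≈41% of messages with
a drug but no disorder term, log-normal message lengths whose tail reaches
past 1000 words, and distances spanning roughly −1200…+1500.  Because the
planted offset of every disorder is recorded, the generator doubles as an
exact oracle: with no misspellings the pipeline must recover every planted
distance.

Misspelling perturbations (consonant doubling, post-first-vowel drop,
adjacent swap) model the colloquial spelling of forum text; the first two
preserve the fuzzy matching key by construction, the third generally breaks
it — documenting the limit of fuzzy matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .evaluate import GoldLabel
from .lexicon import VOWELS, LexiconEntry, fuzzy_key
from .preprocess import Message

__all__ = ["SimConfig", "generate_corpus", "plant_misspelling", "default_disorder_lexicon", "FILLER_VOCAB"]

logger = logging.getLogger(__name__)

#: Closed filler vocabulary, chosen disjoint (under stemming and fuzzy keys)
#: from the default synthetic lexicon and drug names.
FILLER_VOCAB = (
    "bonjour", "alors", "depuis", "toujours", "vraiment", "beaucoup",
    "quand", "pense", "trouve", "chose", "temps", "encore", "aussi",
    "merci", "forum", "matin", "soir", "semaine", "mois", "jour",
    "enfin", "voila", "peut", "etre", "faire", "dire", "avis",
    "question", "reponse", "suite", ",", ".", "!", "?",
)

#: Synthetic disorder lexicon (fixture content, not real terminology):
#: (surface, llt_id, llt_label, pt_id, pt_label, soc_label)
_SYNTH_DISORDERS = (
    ("insomnie", "L001", "insomnie", "P001", "insomnia", "psychiatric disorders"),
    ("vertige", "L002", "vertige", "P002", "dizziness", "nervous system disorders"),
    ("nausee", "L003", "nausee", "P003", "nausea", "gastrointestinal disorders"),
    ("fatigue", "L004", "fatigue", "P004", "fatigue", "general disorders"),
    ("migraine", "L005", "migraine", "P005", "headache", "nervous system disorders"),
    ("mal de tete", "L006", "mal de tete", "P005", "headache", "nervous system disorders"),
    ("eruption cutanee", "L007", "eruption cutanee", "P007", "rash", "skin disorders"),
    ("diarrhee", "L008", "diarrhee", "P008", "diarrhoea", "gastrointestinal disorders"),
    ("somnolence", "L009", "somnolence", "P009", "somnolence", "nervous system disorders"),
    ("palpitation", "L010", "palpitation", "P010", "palpitations", "cardiac disorders"),
    ("crampe", "L011", "crampe", "P011", "muscle spasms", "musculoskeletal disorders"),
    ("angoisse", "L012", "angoisse", "P012", "anxiety", "psychiatric disorders"),
)


def default_disorder_lexicon() -> list[LexiconEntry]:
    """The built-in synthetic disorder lexicon (LLT→PT→SOC schema)."""
    return [LexiconEntry(*row) for row in _SYNTH_DISORDERS]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic corpus."""

    n_messages: int = 648
    drug_names: tuple[str, ...] = ("teriflunomide", "glargine", "zolpidem")
    adr_prevalence: float = 0.114
    adr_distance_law: tuple[float, float] = (10.0, 30.0)          # (mean, sd)
    other_distance_law: tuple[tuple[float, float, float], ...] = (  # (mean, sd, weight)
        (0.0, 80.0, 0.6),
        (0.0, 450.0, 0.4),
    )
    message_length_law: tuple[float, float] = (4.6, 1.1)          # lognormal (meanlog, sdlog)
    no_disorder_fraction: float = 0.41
    disorders_per_message: float = 3.3    # Poisson mean of extra disorders (>=1 planted)
    duplicate_drug_rate: float = 0.2      # chance of a far echo occurrence of the drug
    misspelling_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.adr_prevalence, self.no_disorder_fraction,
                  self.duplicate_drug_rate, self.misspelling_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.adr_distance_law[1] <= 0:
            raise ValueError("sds must be positive")
        if any(sd <= 0 for _, sd, _ in self.other_distance_law):
            raise ValueError("sds must be positive")
        if abs(sum(w for _, _, w in self.other_distance_law) - 1.0) > 1e-9:
            raise ValueError("other_distance_law weights must sum to 1")


def plant_misspelling(token: str, rate: float, rng: np.random.Generator) -> str:
    """Perturb a token with probability ``rate``.

    Perturbations: double a consonant, drop a vowel after the first vowel
    (both preserve the fuzzy key), or swap two adjacent letters (which in
    general does not).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if len(token) < 3 or rng.random() >= rate:
        return token
    kind = rng.integers(0, 3)
    if kind == 0:  # double a consonant
        idx = [i for i, ch in enumerate(token) if ch.isalpha() and ch not in VOWELS]
        if idx:
            i = int(rng.choice(idx))
            return token[: i + 1] + token[i] + token[i + 1 :]
    elif kind == 1:  # drop a post-first vowel
        vowel_positions = [i for i, ch in enumerate(token) if ch in VOWELS]
        if len(vowel_positions) > 1:
            i = int(rng.choice(vowel_positions[1:]))
            return token[:i] + token[i + 1 :]
    else:  # swap adjacent letters
        i = int(rng.integers(0, len(token) - 1))
        return token[:i] + token[i + 1] + token[i] + token[i + 2 :]
    return token


def _draw_offset(is_adr: bool, config: SimConfig, rng: np.random.Generator) -> int:
    if is_adr:
        mu, sd = config.adr_distance_law
        d = rng.normal(mu, sd)
    else:
        weights = [w for _, _, w in config.other_distance_law]
        comp = rng.choice(len(config.other_distance_law), p=weights)
        mu, sd, _ = config.other_distance_law[comp]
        d = rng.normal(mu, sd)
    d = int(round(d))
    if d == 0:
        d = 1 if rng.random() < 0.5 else -1
    return d


@dataclass(frozen=True)
class PlantedPair:
    """Ground truth for one planted disorder."""

    message_id: str
    drug_name: str
    llt_id: str
    start_pos: int       # first token of the planted disorder span
    drug_pos: int
    offset: int          # signed planted distance == start_pos - drug_pos
    label: str           # ADR | OTHER


def generate_corpus(
    config: SimConfig,
    lexicon: Optional[Sequence[LexiconEntry]] = None,
) -> tuple[list[Message], list[GoldLabel], list[PlantedPair]]:
    """Generate messages, gold labels, and the planted ground truth.

    Deterministic given ``config`` (which carries the seed).  Every message
    contains exactly one drug name; with probability ``duplicate_drug_rate``
    a second, strictly more distant occurrence of the same name is added so
    the minimum-distance deduplication rule downstream is exercised without
    disturbing the planted offsets.  If a drawn offset does not fit in the
    drawn message length, the message is extended (and the event logged).
    """
    lexicon = list(lexicon) if lexicon is not None else default_disorder_lexicon()
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    rng = np.random.default_rng(config.seed)
    messages: list[Message] = []
    gold: list[GoldLabel] = []
    truth: list[PlantedPair] = []

    for m in range(config.n_messages):
        message_id = f"msg{m:05d}"
        drug = config.drug_names[rng.integers(0, len(config.drug_names))]
        length = max(10, int(round(rng.lognormal(*config.message_length_law))))
        has_disorders = rng.random() >= config.no_disorder_fraction
        n_disorders = (1 + int(rng.poisson(config.disorders_per_message))) if has_disorders else 0

        entries = [lexicon[int(i)] for i in rng.integers(0, len(lexicon), n_disorders)]
        labels = ["ADR" if rng.random() < config.adr_prevalence else "OTHER" for _ in entries]
        offsets = [_draw_offset(lab == "ADR", config, rng) for lab in labels]

        # place the drug so every offset can land at position >= 1
        min_off = min(offsets, default=0)
        drug_pos = int(rng.integers(1, length + 1))
        if drug_pos + min_off < 1:
            drug_pos = 1 - min_off
        max_span = max((len(e.surface_term.split()) for e in entries), default=1)
        needed = max(length, drug_pos, *[drug_pos + off + max_span - 1 for off in offsets] or [1])
        if needed > length:
            logger.info("message %s extended from %d to %d tokens", message_id, length, needed)
            length = needed

        occupied: dict[int, str] = {drug_pos: drug}  # position -> token
        planted: list[PlantedPair] = []
        for entry, label, off in zip(entries, labels, offsets):
            term_tokens = entry.surface_term.split()
            target = drug_pos + off
            # shift until the span is free of the drug and earlier plants
            step = 0
            while True:
                cand = target + step
                span = range(cand, cand + len(term_tokens))
                if cand >= 1 and cand != drug_pos and not any(p in occupied for p in span):
                    target = cand
                    break
                step = -step + 1 if step <= 0 else -step  # 0,1,-1,2,-2,...
            length = max(length, target + len(term_tokens) - 1)
            for j, tok in enumerate(term_tokens):
                occupied[target + j] = tok
            planted.append(
                PlantedPair(
                    message_id=message_id,
                    drug_name=drug,
                    llt_id=entry.llt_id,
                    start_pos=target,
                    drug_pos=drug_pos,
                    offset=target - drug_pos,
                    label=label,
                )
            )

        # optional far echo of the same drug name: strictly farther from every
        # disorder than its planted occurrence, so dedup must discard it
        if planted and rng.random() < config.duplicate_drug_rate:
            max_abs = max(abs(p.offset) for p in planted)
            echo = max(p.start_pos for p in planted) + max_abs + 2
            while echo in occupied:
                echo += 1
            occupied[echo] = drug
            length = max(length, echo)

        tokens = [
            occupied.get(pos, FILLER_VOCAB[int(rng.integers(0, len(FILLER_VOCAB)))])
            for pos in range(1, length + 1)
        ]
        if config.misspelling_rate > 0:
            # perturb only planted entity tokens: misspelled fillers cannot
            # create spurious matches, so they would only slow the tests
            tokens = [
                plant_misspelling(tok, config.misspelling_rate, rng)
                if (i + 1) in occupied and tok not in (",", ".", "!", "?")
                else tok
                for i, tok in enumerate(tokens)
            ]

        messages.append(
            Message(message_id=message_id, text=" ".join(tokens), source="synthetic", date=None)
        )
        for pp in planted:
            gold.append(
                GoldLabel(
                    message_id=pp.message_id,
                    llt_id=pp.llt_id,
                    start_pos=pp.start_pos,
                    label=pp.label,
                )
            )
        truth.extend(planted)

    return messages, gold, truth
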