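"""Synthetic-corpus generator: determinism, planted truth, calibration."""

import io

import numpy as np
import pytest

from adrfilter import io as adrio
from adrfilter.lexicon import DrugEntry, build_index, fuzzy_key, stem
from adrfilter.mixture import em_fit, map_assign
from adrfilter.ner import recognize
from adrfilter.pairing import enumerate_pairs
from adrfilter.preprocess import preprocess_message
from adrfilter.simulate import (
    FILLER_VOCAB,
    SimConfig,
    default_disorder_lexicon,
    generate_corpus,
    plant_misspelling,
)


def run_pipeline_on(messages, drug_names):
    lex = default_disorder_lexicon()
    didx = build_index(lex, "exact-stemmed")
    gidx = build_index([DrugEntry(n, f"D{i}") for i, n in enumerate(drug_names)], "fuzzy")
    pairs = []
    for m in messages:
        ts = preprocess_message(m)
        pairs.extend(enumerate_pairs(recognize(ts, gidx, didx), len(ts)))
    return pairs


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(n_messages=40, seed=11)
        for run in ("a", "b"):
            msgs, gold, _ = generate_corpus(cfg)
            adrio.write_corpus_jsonl(tmp_path / f"{run}.jsonl", msgs)
            adrio.write_gold_csv(tmp_path / f"{run}.csv", gold)
        assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seed_differs(self):
        a, _, _ = generate_corpus(SimConfig(n_messages=20, seed=1))
        b, _, _ = generate_corpus(SimConfig(n_messages=20, seed=2))
        assert [m.text for m in a] != [m.text for m in b]


class TestPlantedTruth:
    def test_clean_corpus_distances_equal_planted_offsets(self):
        cfg = SimConfig(n_messages=120, seed=5, misspelling_rate=0.0)
        msgs, gold, truth = generate_corpus(cfg)
        pairs = run_pipeline_on(msgs, cfg.drug_names)
        planted = {(t.message_id, t.llt_id, t.start_pos): t.offset for t in truth}
        assert len(pairs) == len(truth)
        for p in pairs:
            key = (p.message_id, p.llt_id, p.disorder_mention.start_pos)
            assert planted[key] == p.distance

    def test_gold_matches_truth(self):
        cfg = SimConfig(n_messages=60, seed=9)
        _, gold, truth = generate_corpus(cfg)
        assert {(g.message_id, g.llt_id, g.start_pos) for g in gold} == {
            (t.message_id, t.llt_id, t.start_pos) for t in truth
        }

    def test_empty_corpus(self):
        msgs, gold, truth = generate_corpus(SimConfig(n_messages=0))
        assert msgs == [] and gold == [] and truth == []

    def test_adr_offsets_follow_their_law(self):
        """With prevalence 1 and a tight law the empirical mean ≈ the law mean."""
        cfg = SimConfig(
            n_messages=500, seed=21, adr_prevalence=1.0,
            adr_distance_law=(10.0, 3.0), duplicate_drug_rate=0.0,
        )
        _, _, truth = generate_corpus(cfg)
        offsets = np.array([t.offset for t in truth])
        assert len(offsets) > 1000
        assert abs(offsets.mean() - 10.0) < 0.5


class TestMisspellings:
    def test_rate_zero_identity(self):
        rng = np.random.default_rng(0)
        assert plant_misspelling("insomnie", 0.0, rng) == "insomnie"

    def test_consonant_doubling_preserves_fuzzy_key(self):
        assert fuzzy_key("modeling") == fuzzy_key("modelling")
        rng = np.random.default_rng(0)
        for _ in range(200):
            word = "migraine"
            out = plant_misspelling(word, 1.0, rng)
            if len(out) == len(word) + 1 or (len(out) == len(word) - 1):
                # doubling or vowel-drop: fuzzy key is preserved by construction
                assert fuzzy_key(out) == fuzzy_key(word)

    def test_adjacent_swap_can_break_fuzzy_key(self):
        # a vowel-consonant swap is erased by vowel stripping ...
        assert fuzzy_key("zolipdem") == fuzzy_key("zolpidem")
        # ... but a consonant-consonant swap survives into the key
        assert fuzzy_key("zoplidem") != fuzzy_key("zolpidem")


class TestCalibration:
    """The generator's defaults emulate the study conditions it stands in
    for: pair-level ADR prevalence near 11.4%, ≈41% of messages without a
    disorder term, heavy-tailed lengths past 1000 words, distances spanning
    several hundred words on both sides."""

    @pytest.fixture(scope="class")
    @staticmethod
    def default_corpus():
        return generate_corpus(SimConfig(seed=123))

    def test_prevalence(self, default_corpus):
        _, gold, _ = default_corpus
        adr = sum(g.label == "ADR" for g in gold)
        assert 0.08 < adr / len(gold) < 0.15

    def test_no_disorder_fraction(self, default_corpus):
        msgs, gold, _ = default_corpus
        with_disorder = {g.message_id for g in gold}
        frac = 1 - len(with_disorder) / len(msgs)
        assert 0.33 < frac < 0.49

    def test_long_tail_message_lengths(self, default_corpus):
        msgs, _, _ = default_corpus
        lengths = [len(preprocess_message(m)) for m in msgs]
        assert max(lengths) > 1000

    def test_distance_span_two_sided(self, default_corpus):
        _, _, truth = default_corpus
        offsets = [t.offset for t in truth]
        assert min(offsets) < -400 and max(offsets) > 400


def test_adrs_concentrate_in_tightest_cluster():
    """Class-conditional laws separate: a 3-component fit puts >=80% of
    planted ADRs into the smallest-sigma cluster (10 seeds, ~2000 pairs)."""
    for seed in range(10):
        cfg = SimConfig(n_messages=800, seed=seed)
        _, _, truth = generate_corpus(cfg)
        offsets = np.array([t.offset for t in truth], dtype=float)
        adr = np.array([t.label == "ADR" for t in truth])
        model = em_fit(offsets, K=3, seed=seed).model
        clusters = map_assign(model, offsets)
        assert (clusters[adr] == 0).mean() >= 0.80


def test_filler_vocabulary_disjoint_from_lexicon():
    """No filler can ever match a disorder stem key or drug fuzzy key."""
    lex = default_disorder_lexicon()
    disorder_stems = {stem(tok) for e in lex for tok in e.surface_term.split()}
    drug_keys = {fuzzy_key(stem(n)) for n in SimConfig().drug_names}
    for f in FILLER_VOCAB:
        assert stem(f) not in disorder_stems
        assert fuzzy_key(stem(f)) not in drug_keys
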