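"""SCFG training, inside algorithm, shuffling and cutoff calibration."""

import math

import numpy as np
import pytest

from mirkit.scfg import (
    Grammar,
    MultiloopStructureError,
    calibrate_cutoff,
    classify,
    cutoff_from_scores,
    default_production_set,
    dinucleotide_shuffle,
    inside_log_probability,
    parse_structure_path,
    train_grammar,
)
from oracles import enumerate_language

#: small single-nonterminal-per-production grammar over {A, C} for enumeration
TOY_GRAMMAR = Grammar({
    ("S", "", "Stem", ""): 1.0,
    ("Stem", "A", "Stem", "C"): 0.3,
    ("Stem", "C", "Stem", "A"): 0.2,
    ("Stem", "A", "AsymBulge", ""): 0.1,
    ("Stem", "", "Loop", ""): 0.4,
    ("AsymBulge", "A", "AsymBulge", ""): 0.3,
    ("AsymBulge", "", "Stem", ""): 0.7,
    ("Loop", "A", "Loop", ""): 0.2,
    ("Loop", "C", "Loop", ""): 0.1,
    ("Loop", "A", "", ""): 0.4,
    ("Loop", "C", "", ""): 0.3,
})


class TestTraining:
    def test_hand_parsed_hairpin_gives_exact_usage_fractions(self):
        # "GGAGAAACCC" / "((.(...)))": 3 stem pairs, 1 left bulge open,
        # 1 bulge close, 1 loop transition, 2 loop continuations, 1 loop end
        g = train_grammar([("GGAGAAACCC", "((.(...)))")], smoothing=0)
        p = g.probabilities
        assert p[("Stem", "G", "Stem", "C")] == pytest.approx(3 / 5)
        assert p[("Stem", "A", "AsymBulge", "")] == pytest.approx(1 / 5)
        assert p[("Stem", "", "Loop", "")] == pytest.approx(1 / 5)
        assert p[("AsymBulge", "", "Stem", "")] == pytest.approx(1.0)
        assert p[("Loop", "A", "Loop", "")] == pytest.approx(2 / 3)
        assert p[("Loop", "A", "", "")] == pytest.approx(1 / 3)

    def test_simple_stem_loop_fractions(self):
        g = train_grammar([("GGCAAAAGCC", "(((....)))")], smoothing=0)
        p = g.probabilities
        assert p[("Stem", "G", "Stem", "C")] == pytest.approx(2 / 4)
        assert p[("Stem", "C", "Stem", "G")] == pytest.approx(1 / 4)
        assert p[("Stem", "", "Loop", "")] == pytest.approx(1 / 4)

    def test_per_nonterminal_probabilities_sum_to_one(self):
        g = train_grammar([("GGAGAAACCC", "((.(...)))")], smoothing=1)
        sums = {}
        for (lhs, *_), prob in g.probabilities.items():
            sums[lhs] = sums.get(lhs, 0.0) + prob
        assert all(abs(s - 1) < 1e-9 for s in sums.values())

    def test_large_smoothing_approaches_uniform(self):
        g = train_grammar([("GGAGAAACCC", "((.(...)))")], smoothing=1e7)
        stem_probs = [p for (lhs, *_), p in g.probabilities.items() if lhs == "Stem"]
        assert max(stem_probs) - min(stem_probs) < 1e-5

    def test_multiloop_structure_rejected_by_name(self):
        with pytest.raises(MultiloopStructureError, match="record 0"):
            train_grammar([("GAAACGAAAC", "(...)(...)")])

    def test_parse_covers_symmetric_bulges(self):
        # columns unpaired on both ends inside the stem -> SymBulge
        usages = parse_structure_path("GGAGAAAACACC", "((.(....).))")
        assert ("Stem", "A", "SymBulge", "A") in usages


class TestInside:
    def test_degenerate_loop_grammar_closed_form(self):
        g = Grammar({
            ("S", "", "Loop", ""): 1.0,
            ("Loop", "A", "Loop", ""): 0.5,
            ("Loop", "A", "", ""): 0.5,
        })
        score = inside_log_probability(g, "AAA")
        assert score.log_probability == pytest.approx(3 * math.log(0.5))
        assert score.normalized_score == pytest.approx(math.log(0.5))

    def test_underivable_sequence_has_minus_infinity(self):
        g = Grammar({
            ("S", "", "Loop", ""): 1.0,
            ("Loop", "A", "Loop", ""): 0.5,
            ("Loop", "A", "", ""): 0.5,
        })
        assert inside_log_probability(g, "AC").log_probability == float("-inf")

    def test_inside_matches_derivation_enumeration(self):
        language = enumerate_language(TOY_GRAMMAR, max_len=8)
        assert len(language) > 50
        for seq, expected in language.items():
            got = math.exp(inside_log_probability(TOY_GRAMMAR, seq).log_probability)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_probability_mass_at_most_one(self):
        language = enumerate_language(TOY_GRAMMAR, max_len=10)
        assert sum(language.values()) <= 1.0 + 1e-12

    def test_log_probability_never_positive(self):
        g = train_grammar([("GGAGAAACCC", "((.(...)))")])
        rng = np.random.default_rng(0)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            assert inside_log_probability(g, seq).log_probability <= 0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            inside_log_probability(TOY_GRAMMAR, "ACXG")


class TestShuffle:
    def test_preserves_dinucleotide_counts(self):
        from collections import Counter

        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert Counter(zip(shuf, shuf[1:])) == Counter(zip(seq, seq[1:]))
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_seeded_determinism(self):
        seq = "GGGCACGTAAGCTTACGCGCATATAT"
        a = dinucleotide_shuffle(seq, np.random.default_rng(3))
        b = dinucleotide_shuffle(seq, np.random.default_rng(3))
        assert a == b


class TestCutoff:
    def test_separated_case_all_positives_pass(self):
        cutoff = cutoff_from_scores([-10.0] * 60, target_specificity=0.95)
        assert cutoff == -10.0
        assert -1.0 > cutoff

    def test_specificity_one_is_max_negative(self):
        scores = [-5.0, -3.0, -8.0, -1.5]
        assert cutoff_from_scores(scores, target_specificity=1.0) == -1.5

    def test_quantile_bounds_pass_rate(self):
        rng = np.random.default_rng(2)
        scores = list(rng.normal(-5, 1, size=200))
        cutoff = cutoff_from_scores(scores, target_specificity=0.95)
        assert sum(s > cutoff for s in scores) <= 0.05 * len(scores)

    def test_empty_sets_are_errors(self):
        g = TOY_GRAMMAR
        with pytest.raises(ValueError):
            calibrate_cutoff(g, positives=[], negatives=["ACA"])
        with pytest.raises(ValueError):
            cutoff_from_scores([], 0.95)


def test_trained_grammar_prefers_real_hairpins_over_shuffles(refs):
    """Mean normalized score of training hairpins exceeds their shuffles'."""
    from mirkit.fold import fold

    seqs = [r.precursor_seq for r in refs.known_records.values()]
    training = [(s, fold(s).dot_bracket) for s in seqs]
    training = [(s, db) for s, db in training if db.count("(") > 0]
    g = train_grammar(training)
    rng = np.random.default_rng(5)
    pos = np.mean([
        inside_log_probability(g, s).normalized_score for s, _ in training
    ])
    neg = np.mean([
        inside_log_probability(g, dinucleotide_shuffle(s, rng)).normalized_score
        for s, _ in training
    ])
    assert pos > neg


def test_grammar_yaml_round_trip(tmp_path):
    g = train_grammar([("GGAGAAACCC", "((.(...)))")], smoothing=0.5)
    path = tmp_path / "grammar.yaml"
    g.to_yaml(path)
    g2 = Grammar.from_yaml(path)
    assert g2.probabilities == g.probabilities
    assert g2.start == g.start


def test_classify_sets_pass_flag():
    s = classify(TOY_GRAMMAR, "AAC", cutoff=-100.0)
    assert s.cutoff_pass is True
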