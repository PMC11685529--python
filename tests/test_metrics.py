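"""Similarity, structure, generalization and convergence measures."""

import random

import numpy as np
import pytest

from complang.corpus import Language, Scene
from complang.fixtures import oracle_edit_distance, table2_pairs
from complang.metrics import (
    convergence_score,
    generalization_score,
    normalized_edit_distance,
    production_similarity,
    semantic_difference,
    similarity_to_reference,
    structure_score,
)
from complang.synthetic import GeneratorSpec, make_compositional_language


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("abc", "abc", 0.0),
            ("muif-a", "muif-i", 1 / 6),
            ("wangsus", "wangsuus", 1 / 8),
            ("ab", "ac", 1 / 2),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert normalized_edit_distance(a, b) == pytest.approx(expected)

    def test_matches_oracle_on_random_pairs(self):
        rng = random.Random(42)
        for _ in range(300):
            a = "".join(rng.choices("abcd", k=rng.randint(1, 8)))
            b = "".join(rng.choices("abcd", k=rng.randint(1, 8)))
            expected = oracle_edit_distance(a, b) / max(len(a), len(b))
            assert normalized_edit_distance(a, b) == pytest.approx(expected)

    def test_metric_axioms(self):
        rng = random.Random(7)
        triples = [
            tuple("".join(rng.choices("abcd", k=rng.randint(1, 8))) for _ in range(3))
            for _ in range(300)
        ]
        for a, b, c in triples:
            dab = normalized_edit_distance(a, b)
            assert dab == normalized_edit_distance(b, a)
            assert (dab == 0) == (a == b)
            # unnormalized triangle inequality
            assert oracle_edit_distance(a, c) <= oracle_edit_distance(a, b) + oracle_edit_distance(b, c)

    def test_production_similarity(self):
        assert production_similarity("muif-a", "muif-i") == pytest.approx(5 / 6)
        assert production_similarity("same", "same") == 1.0
        assert production_similarity("abcd", "efgh") == 0.0


class TestSemanticDifference:
    def test_identical_scenes(self):
        assert semantic_difference(Scene(1, 90), Scene(1, 90)) == 0.0

    def test_shape_only(self):
        assert semantic_difference(Scene(1, 90), Scene(2, 90)) == 1.0

    def test_angle_only(self):
        assert semantic_difference(Scene(1, 90), Scene(1, 180)) == 0.5

    def test_circular_vs_linear(self):
        near_north = semantic_difference(Scene(1, 15), Scene(1, 360), circular=True)
        assert near_north == pytest.approx(15 / 180)
        linear = semantic_difference(Scene(1, 15), Scene(1, 360), circular=False)
        assert linear == pytest.approx(345 / 180)

    def test_bounds(self):
        assert semantic_difference(Scene(1, 90), Scene(2, 270)) == 2.0


class TestStructureScore:
    def test_compositional_language_scores_high(self):
        lang = make_compositional_language(GeneratorSpec(), seed=3)
        assert structure_score(lang).score >= 0.7

    def test_identical_labels_degenerate(self):
        items = [(Scene(s, a), "same") for s in (1, 2) for a in (90.0, 180.0)]
        lang = Language("flat", items, test_scenes=[])
        report = structure_score(lang)
        assert report.degenerate and report.score == 0.0

    def test_pair_count(self):
        lang = make_compositional_language(GeneratorSpec(), seed=3)
        assert structure_score(lang).n_pairs == 23 * 22 // 2

    def test_too_few_items(self):
        lang = Language("small", [(Scene(1, 90), "aa"), (Scene(1, 180), "bb")], [])
        with pytest.raises(ValueError):
            structure_score(lang)

    def test_invariant_to_item_order_and_shape_relabeling(self):
        lang = make_compositional_language(GeneratorSpec(), seed=5)
        base = structure_score(lang).score
        shuffled = Language(
            "shuffled", list(reversed(lang.items)), lang.test_scenes, lang.alphabet
        )
        assert structure_score(shuffled).score == pytest.approx(base)
        perm = {1: 3, 2: 4, 3: 1, 4: 2}  # permuting categories preserves 0/1 mismatch
        relabeled = Language(
            "relabeled",
            [(Scene(perm[s.shape], s.angle), l) for s, l in lang.items],
            [Scene(perm[s.shape], s.angle) for s in lang.test_scenes],
            lang.alphabet,
        )
        assert structure_score(relabeled).score == pytest.approx(base)


class TestGeneralizationScore:
    def test_affine_distances_give_perfect_correlation(self):
        # cross-pair semantic differences (0.5, 1.0, 1.0, 1.5) and form
        # distances (0.1, 0.4, 0.4, 0.7): affine relation, Pearson r = 1
        train = [(Scene(1, 90), "aaaaaaaaaa"), (Scene(1, 360), "acdbaadaab")]
        test = [(Scene(1, 180), "aaaaaaaaab"), (Scene(2, 90), "baacaabbaa")]
        report = generalization_score(train, test)
        assert report.n_pairs == 4
        assert report.score == pytest.approx(1.0)

    def test_recombining_learner_scores_high(self):
        lang = make_compositional_language(GeneratorSpec(), seed=2)
        from complang.synthetic import ReferenceLearnerSpec, make_reference_productions

        learner = make_reference_productions(
            lang, ReferenceLearnerSpec(n_learners=1, noise_rate=0.0, recombination_fidelity=1.0)
        )[0]
        assert generalization_score(learner["train"], learner["test"]).score >= 0.7

    def test_degenerate_when_all_labels_identical(self):
        train = [(Scene(1, 90), "x"), (Scene(1, 180), "x")]
        test = [(Scene(2, 90), "x"), (Scene(2, 180), "x")]
        report = generalization_score(train, test)
        assert report.degenerate and report.score == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            generalization_score([], [(Scene(1, 90), "a")])


class TestConvergenceScore:
    def test_identical_productions(self):
        assert convergence_score([["aa", "bb"]] * 4).score == 1.0

    def test_disjoint_alphabets(self):
        prods = [["aaa", "aa"], ["bbb", "bb"], ["ccc", "cc"]]
        assert convergence_score(prods).score == 0.0

    def test_two_agents_one_scene(self):
        report = convergence_score([["ab"], ["ac"]])
        assert report.score == pytest.approx(0.5)
        assert report.score == pytest.approx(production_similarity("ab", "ac"))
        assert report.n_pairs == 1

    def test_pair_count_and_order_invariance(self):
        rng = random.Random(3)
        prods = [
            ["".join(rng.choices("abcd", k=rng.randint(1, 6))) for _ in range(5)]
            for _ in range(4)
        ]
        report = convergence_score(prods)
        assert report.n_pairs == 5 * 4 * 3 // 2
        assert convergence_score(prods[::-1]).score == pytest.approx(report.score)

    def test_mismatched_coverage_rejected(self):
        with pytest.raises(ValueError):
            convergence_score([["a", "b"], ["a"]])


class TestSimilarityToReference:
    def test_exact_match(self):
        prods = [(Scene(1, 90), "fas-a")]
        assert similarity_to_reference(prods, {Scene(1, 90): ["fas-a"]}).score == 1.0

    def test_averages_over_reference_labels(self):
        prods = [(Scene(1, 90), "muif-a")]
        ref = {Scene(1, 90): ["muif-i", "muif-i"]}
        assert similarity_to_reference(prods, ref).score == pytest.approx(5 / 6)

    def test_disjoint_labels(self):
        prods = [(Scene(1, 90), "abcd")]
        assert similarity_to_reference(prods, {Scene(1, 90): ["efgh"]}).score == 0.0

    def test_missing_scene_rejected(self):
        with pytest.raises(ValueError):
            similarity_to_reference([(Scene(1, 90), "a")], {Scene(2, 90): ["b"]})


def test_mantel_permutation_p_discriminates():
    from complang.metrics import mantel_permutation_p

    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    assert mantel_permutation_p(x, 2 * x + 0.01 * rng.normal(size=30), seed=1) < 0.01
    assert mantel_permutation_p(x, rng.normal(size=30), seed=1) > 0.05


def test_table2_examples_score_consistently():
    """Published worked examples: identical triples score similarity 1."""
    for ex in table2_pairs():
        if ex.human == ex.rnn == ex.gpt:
            assert production_similarity(ex.human, ex.rnn) == 1.0
    by_scene = {(ex.shape, ex.angle, ex.structure_bin): ex for ex in table2_pairs()}
    hi = by_scene[(2, 360, "high")]
    assert (hi.human, hi.rnn, hi.gpt) == ("nif-k", "nif-kks", "nif-k")
    lo = by_scene[(2, 360, "low")]
    assert (lo.human, lo.rnn, lo.gpt) == ("koko", "kesee", "fetik-tik")
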