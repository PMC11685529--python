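"""Synthetic language generator: calibration, determinism, reference learners."""

import numpy as np
import pytest

from complang.metrics import (
    convergence_score,
    generalization_score,
    similarity_to_reference,
    structure_score,
)
from complang.synthetic import (
    GeneratorSpec,
    ReferenceLearnerSpec,
    interpolate_language,
    make_compositional_language,
    make_holistic_language,
    make_language_suite,
    make_reference_productions,
    reference_lookup,
)


class TestCompositional:
    def test_high_structure(self):
        for seed in range(5):
            lang = make_compositional_language(GeneratorSpec(), seed=seed)
            assert structure_score(lang).score >= 0.7

    def test_same_shape_adjacent_angles_share_morpheme(self):
        lang = make_compositional_language(GeneratorSpec(), seed=0)
        by_shape = {}
        for scene, label in lang.items:
            by_shape.setdefault(scene.shape, set()).add(label.split("-")[0])
        for morphemes in by_shape.values():
            assert len(morphemes) == 1

    def test_deterministic(self):
        a = make_compositional_language(GeneratorSpec(), seed=4)
        b = make_compositional_language(GeneratorSpec(), seed=4)
        assert a.items == b.items and a.test_scenes == b.test_scenes
        assert a.distractor_sets == b.distractor_sets

    def test_split_sizes_and_disjointness(self):
        lang = make_compositional_language(GeneratorSpec(), seed=1)
        assert len(lang.items) == 23 and len(lang.test_scenes) == 13
        assert not set(lang.train_scenes) & set(lang.test_scenes)

    def test_distractor_sets(self):
        lang = make_compositional_language(GeneratorSpec(), seed=1)
        for (target, _), cands in zip(lang.items, lang.distractor_sets):
            assert len(cands) == 5 and target in cands
            assert any(s.shape == target.shape and s != target for s in cands)


class TestHolistic:
    def test_low_structure_across_seeds(self):
        hits = sum(
            abs(structure_score(make_holistic_language(GeneratorSpec(), seed=s)).score) <= 0.2
            for s in range(10)
        )
        assert hits >= 9

    def test_labels_distinct(self):
        lang = make_holistic_language(GeneratorSpec(), seed=2)
        assert len(set(lang.labels)) == len(lang.labels)

    def test_deterministic(self):
        assert (
            make_holistic_language(GeneratorSpec(), seed=6).items
            == make_holistic_language(GeneratorSpec(), seed=6).items
        )


class TestInterpolation:
    def test_fraction_zero_is_identity(self):
        base = make_compositional_language(GeneratorSpec(), seed=0)
        assert interpolate_language(base, 0.0, seed=1).items == base.items

    def test_fraction_one_matches_holistic_level(self):
        scores = [
            structure_score(
                interpolate_language(make_compositional_language(GeneratorSpec(), seed=s), 1.0, seed=s)
            ).score
            for s in range(10)
        ]
        assert abs(np.mean(scores)) <= 0.2

    def test_monotone_degradation_in_expectation(self):
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for frac in fractions:
            scores = [
                structure_score(
                    interpolate_language(
                        make_compositional_language(GeneratorSpec(), seed=s), frac, seed=100 + s
                    )
                ).score
                for s in range(10)
            ]
            means.append(np.mean(scores))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_midpoint_between_endpoints(self):
        lo, mid, hi = (
            np.mean(
                [
                    structure_score(
                        interpolate_language(
                            make_compositional_language(GeneratorSpec(), seed=s), f, seed=200 + s
                        )
                    ).score
                    for s in range(10)
                ]
            )
            for f in (1.0, 0.5, 0.0)
        )
        assert lo < mid < hi

    def test_invalid_fraction(self):
        base = make_compositional_language(GeneratorSpec(), seed=0)
        with pytest.raises(ValueError):
            interpolate_language(base, 1.5)


class TestSuite:
    def test_span_and_ordering(self):
        suite = make_language_suite(GeneratorSpec(seed=1))
        scores = [l.structure_score for l in suite]
        assert len(suite) == 5
        assert scores == sorted(scores)
        assert min(scores) <= 0.2 and max(scores) >= 0.7

    def test_shared_scene_split(self):
        suite = make_language_suite(GeneratorSpec(seed=2))
        first = suite[0]
        for lang in suite[1:]:
            assert lang.train_scenes == first.train_scenes
            assert lang.test_scenes == first.test_scenes

    def test_reproducible(self):
        a = make_language_suite(GeneratorSpec(seed=3))
        b = make_language_suite(GeneratorSpec(seed=3))
        assert [l.items for l in a] == [l.items for l in b]


class TestReferenceLearners:
    def test_perfect_learners_on_compositional_language(self):
        lang = make_compositional_language(GeneratorSpec(), seed=0)
        spec = ReferenceLearnerSpec(n_learners=4, noise_rate=0.0, recombination_fidelity=1.0)
        learners = make_reference_productions(lang, spec, seed=0)
        gen = generalization_score(learners[0]["train"], learners[0]["test"])
        assert gen.score >= 0.7
        conv = convergence_score([[l for _, l in lr["test"]] for lr in learners])
        assert conv.score == 1.0

    def test_noise_free_memorization_is_exact(self):
        lang = make_compositional_language(GeneratorSpec(), seed=1)
        spec = ReferenceLearnerSpec(n_learners=2, noise_rate=0.0)
        learners = make_reference_productions(lang, spec, seed=0)
        ref = reference_lookup(learners, "train")
        assert similarity_to_reference(list(lang.items), ref).score == 1.0

    def test_reproducible_under_seed(self):
        lang = make_compositional_language(GeneratorSpec(), seed=2)
        spec = ReferenceLearnerSpec()
        a = make_reference_productions(lang, spec, seed=5)
        b = make_reference_productions(lang, spec, seed=5)
        assert a == b

    def test_noise_rate_bounds_validated(self):
        with pytest.raises(ValueError):
            ReferenceLearnerSpec(noise_rate=1.5)
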