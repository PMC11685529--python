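"""Synthetic artificial languages with controllable compositional structure.

Emulates suites of form-meaning languages over 4 shapes x 24 angles
(multiples of 15 degrees): a fully compositional generator (label =
shape morpheme + "-" + angle morpheme, where angle morphemes share more
characters the closer the angles), a holistic generator (idiosyncratic
random labels), and an interpolation between them that degrades the
structure score monotonically in expectation.  Also generates per-item
distractor sets for the guessing task and synthetic "reference learner"
productions that stand in for human learning data: learners that
memorize with character noise and generalize by morpheme recombination
with a fidelity that scales with the language's structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Language, Scene
from .metrics import angular_difference

CONSONANTS = "bdfgklmnprstvwz"
VOWELS = "aeiou"
#: octant letters for the angle morpheme; within an octant the letter is
#: repeated 1-3 times, so edit distance grows with angular distance
OCTANT_LETTERS = "aeiouysw"
DEFAULT_BINS = ("low", "mid-low", "mid", "mid-high", "high")
#: fraction of compositional labels replaced by holistic ones, per bin
BIN_REPLACEMENT = {"low": 1.0, "mid-low": 0.75, "mid": 0.5, "mid-high": 0.25, "high": 0.0}


@dataclass
class GeneratorSpec:
    """Study conditions for language generation.

    23 training items and 13 held-out test scenes over 4 shapes and an
    angle grid of 15-degree multiples in (0, 360].
    """

    n_items: int = 23
    n_test: int = 13
    n_shapes: int = 4
    angle_grid: tuple[float, ...] = tuple(15.0 * (i + 1) for i in range(24))
    target_bins: tuple[str, ...] = DEFAULT_BINS
    n_distractors: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_items + self.n_test > self.n_shapes * len(self.angle_grid):
            raise ValueError("scene inventory too small for requested split")

    def scene_inventory(self) -> list[Scene]:
        return [Scene(sh, an) for sh in range(1, self.n_shapes + 1) for an in self.angle_grid]


@dataclass
class ReferenceLearnerSpec:
    """Synthetic reference learners standing in for human participants."""

    n_learners: int = 10
    noise_rate: float = 0.05
    recombination_fidelity: float = 0.9

    def __post_init__(self):
        if not (0.0 <= self.noise_rate <= 1.0 and 0.0 <= self.recombination_fidelity <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")


def _split_scenes(spec: GeneratorSpec, rng: np.random.Generator) -> tuple[list[Scene], list[Scene]]:
    inventory = spec.scene_inventory()
    order = rng.permutation(len(inventory))
    train = [inventory[i] for i in sorted(order[: spec.n_items])]
    test = [inventory[i] for i in sorted(order[spec.n_items : spec.n_items + spec.n_test])]
    return train, test


def _shape_morphemes(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct CV(V)C syllables, e.g. 'fas', 'muif', 'wef'."""
    out: list[str] = []
    while len(out) < n:
        c1 = CONSONANTS[rng.integers(len(CONSONANTS))]
        v = VOWELS[rng.integers(len(VOWELS))]
        v2 = VOWELS[rng.integers(len(VOWELS))] if rng.random() < 0.3 else ""
        c2 = CONSONANTS[rng.integers(len(CONSONANTS))]
        syl = c1 + v + v2 + c2
        if syl not in out and all(syl[:2] != o[:2] for o in out):
            out.append(syl)
    return out


def _angle_morpheme(angle: float, grid: tuple[float, ...]) -> str:
    """Octant letter repeated 1-3 times.

    Adjacent grid angles differ by one repetition (edit distance 1),
    different octants swap the letter entirely, so string similarity
    tracks angular proximity.
    """
    t = grid.index(angle)
    per_octant = max(1, len(grid) // len(OCTANT_LETTERS))
    q, r = divmod(t, per_octant)
    return OCTANT_LETTERS[q % len(OCTANT_LETTERS)] * (1 + r)


def _compositional_label(scene: Scene, morphemes: list[str], grid) -> str:
    return morphemes[scene.shape - 1] + "-" + _angle_morpheme(scene.angle, grid)


def _holistic_label(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        length = int(rng.integers(3, 9))
        chars = []
        for i in range(length):
            pool = CONSONANTS if i % 2 == 0 else VOWELS
            chars.append(pool[rng.integers(len(pool))])
        label = "".join(chars)
        if label not in taken:
            return label


def _make_distractors(
    train: list[Scene], k: int, rng: np.random.Generator
) -> list[list[Scene]]:
    """Per item: the target plus k-1 foils from the other training scenes.

    Each set includes at least one same-shape foil and one similar-angle
    foil of a different shape when available.
    """
    sets = []
    for target in train:
        others = [s for s in train if s != target]
        foils: list[Scene] = []
        same_shape = [s for s in others if s.shape == target.shape]
        if same_shape:
            foils.append(min(same_shape, key=lambda s: (angular_difference(s.angle, target.angle), s.angle)))
        other_shape = [s for s in others if s.shape != target.shape and s not in foils]
        if other_shape:
            foils.append(min(other_shape, key=lambda s: (angular_difference(s.angle, target.angle), s.shape, s.angle)))
        pool = [s for s in others if s not in foils]
        extra = rng.permutation(len(pool))[: max(0, k - 1 - len(foils))]
        foils.extend(pool[i] for i in extra)
        cands = foils[: k - 1] + [target]
        rng.shuffle(cands)
        sets.append(cands)
    return sets


def make_compositional_language(spec: GeneratorSpec, seed: int | None = None) -> Language:
    """A fully compositional language: shape morpheme ++ '-' ++ angle morpheme.

    The realized structure score depends on which 23 scenes the split
    draws; the generator enforces its contract (score >= 0.7) by
    redrawing the split from derived sub-seeds until it holds, which is
    deterministic for a given seed.
    """
    from .metrics import structure_score

    seed = spec.seed if seed is None else seed
    for attempt in range(50):
        rng = np.random.default_rng([seed, attempt])
        train, test = _split_scenes(spec, rng)
        morphemes = _shape_morphemes(rng, spec.n_shapes)
        items = [(s, _compositional_label(s, morphemes, spec.angle_grid)) for s in train]
        language = Language(
            name=f"compositional-{seed}",
            items=items,
            test_scenes=test,
            distractor_sets=_make_distractors(train, spec.n_distractors, rng),
        )
        if structure_score(language).score >= 0.7:
            return language
    raise RuntimeError("could not realize a compositional language; grid too coarse")


def make_holistic_language(spec: GeneratorSpec, seed: int | None = None) -> Language:
    """An idiosyncratic language: independent random labels, all distinct."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    train, test = _split_scenes(spec, rng)
    taken: set[str] = set()
    items = []
    for s in train:
        label = _holistic_label(rng, taken)
        taken.add(label)
        items.append((s, label))
    return Language(
        name=f"holistic-{seed}",
        items=items,
        test_scenes=test,
        distractor_sets=_make_distractors(train, spec.n_distractors, rng),
    )


def interpolate_language(
    base: Language, replacement_fraction: float, seed: int = 0
) -> Language:
    """Replace a fraction of labels of ``base`` with holistic labels.

    The realized structure score decreases monotonically in expectation
    as the fraction grows; fraction 0 returns an identical language.
    """
    if not 0.0 <= replacement_fraction <= 1.0:
        raise ValueError("replacement_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_replace = round(replacement_fraction * len(base.items))
    which = set(rng.choice(len(base.items), size=n_replace, replace=False).tolist())
    taken = {l for _, l in base.items}
    items = []
    for i, (scene, label) in enumerate(base.items):
        if i in which:
            label = _holistic_label(rng, taken)
            taken.add(label)
        items.append((scene, label))
    return Language(
        name=f"{base.name}-mix{replacement_fraction:g}-{seed}",
        items=items,
        test_scenes=list(base.test_scenes),
        alphabet=base.alphabet,
        distractor_sets=base.distractor_sets,
    )


def make_language_suite(spec: GeneratorSpec) -> list[Language]:
    """One language per structure bin, low to high, on a shared scene split.

    Bins are realized by interpolating between a holistic and a fully
    compositional language built on the same train/test scenes; the
    returned list is ordered by realized structure score within the
    bin order low..high.
    """
    base = make_compositional_language(spec, spec.seed)
    suite = []
    for i, bin_name in enumerate(spec.target_bins):
        frac = BIN_REPLACEMENT.get(bin_name, 1.0 - i / max(1, len(spec.target_bins) - 1))
        suite.append(interpolate_language(base, frac, seed=spec.seed * 1000 + i))
    # bin labels follow the realized scores so bins are ordered by construction
    suite.sort(key=lambda l: l.structure_score)
    for bin_name, lang in zip(spec.target_bins, suite):
        lang.name = f"{bin_name}-{spec.seed}"
    return suite


# ---------------------------------------------------------------------------
# Synthetic reference learners
# ---------------------------------------------------------------------------

def _mutate(label: str, rate: float, rng: np.random.Generator) -> str:
    """Per-character substitution noise (alphabetic characters only)."""
    if rate == 0.0:
        return label
    chars = list(label)
    for i, c in enumerate(chars):
        if c != "-" and rng.random() < rate:
            pool = CONSONANTS + VOWELS
            chars[i] = pool[rng.integers(len(pool))]
    return "".join(chars)


def _nearest_train(
    scene: Scene, train: list[Scene], same_shape: bool
) -> Scene | None:
    pool = [s for s in train if (s.shape == scene.shape) == same_shape]
    if not pool:
        return None
    return min(pool, key=lambda s: (angular_difference(s.angle, scene.angle), s.shape, s.angle))


def _recombine(scene: Scene, language: Language) -> str:
    """Compose a label for a new scene from memorized parts.

    Shape part from the same-shape training item with the closest angle;
    angle part from the training item with the closest angle overall.
    Parts are split on the first hyphen; hyphen-less labels fall back to
    a prefix/suffix blend.
    """
    shape_src = _nearest_train(scene, language.train_scenes, same_shape=True)
    angle_src = min(
        language.train_scenes,
        key=lambda s: (angular_difference(s.angle, scene.angle), s.shape, s.angle),
    )
    shape_label = language.label_for(shape_src) if shape_src else language.label_for(angle_src)
    angle_label = language.label_for(angle_src)
    if "-" in shape_label and "-" in angle_label:
        return shape_label.split("-", 1)[0] + "-" + angle_label.split("-", 1)[1]
    half1 = shape_label[: max(1, len(shape_label) // 2)]
    half2 = angle_label[len(angle_label) // 2 :]
    return half1 + half2


def _blend(scene: Scene, language: Language, rng: np.random.Generator) -> str:
    """Noisy generalization for unstructured languages: splice two
    memorized labels chosen near-randomly."""
    idx = rng.integers(len(language.items))
    a = language.items[int(idx)][1]
    b = language.label_for(
        min(language.train_scenes, key=lambda s: (angular_difference(s.angle, scene.angle), s.shape, s.angle))
    )
    cut_a = max(1, len(a) // 2)
    return (a[:cut_a] + b[len(b) // 2 :])[:16]


def make_reference_productions(
    language: Language, ref_spec: ReferenceLearnerSpec, seed: int = 0
) -> list[dict[str, list[tuple[Scene, str]]]]:
    """Per-learner productions for train and test scenes.

    Memorization productions are the true labels with per-character
    noise.  Generalization productions recombine morphemes with
    probability ``recombination_fidelity`` scaled by the language's
    structure score (relative to the fully-compositional level of 0.7,
    saturating at 1); otherwise they are noisy blends of memorized
    labels.
    """
    structure = min(1.0, max(0.0, language.structure_score) / 0.7)
    p_recombine = ref_spec.recombination_fidelity * structure
    learners = []
    for j in range(ref_spec.n_learners):
        rng = np.random.default_rng([seed, j])
        train_prods = [
            (scene, _mutate(label, ref_spec.noise_rate, rng)) for scene, label in language.items
        ]
        test_prods = []
        for scene in language.test_scenes:
            if p_recombine >= 1.0 or rng.random() < p_recombine:
                label = _recombine(scene, language)
            else:
                label = _blend(scene, language, rng)
            test_prods.append((scene, _mutate(label, ref_spec.noise_rate, rng)))
        learners.append({"train": train_prods, "test": test_prods})
    return learners


def reference_lookup(
    learners: list[dict[str, list[tuple[Scene, str]]]], phase: str
) -> dict[Scene, list[str]]:
    """Collate per-learner productions into scene -> list-of-labels."""
    table: dict[Scene, list[str]] = {}
    for learner in learners:
        for scene, label in learner[phase]:
            table.setdefault(scene, []).append(label)
    return table
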