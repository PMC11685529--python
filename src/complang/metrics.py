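"""Measures of compositional structure, generalization and convergence.

All scores reduce to two primitive quantities:

* **form distance** — length-normalized Levenshtein edit distance between
  two labels, ``lev(a, b) / max(|a|, |b|)`` in [0, 1]; *production
  similarity* is one minus this distance;
* **semantic difference** — a shape-mismatch indicator (0/1) plus the
  angular difference divided by 180, in [0, 2].

The *structure score* (topographic similarity) of a language is the
Pearson correlation between pairwise semantic differences and pairwise
form distances over all unordered item pairs; the *generalization score*
is the same correlation over the cross pairs between one learner's
productions for trained items and for held-out items; the *convergence
score* averages per-scene production similarity across learners of the
same language.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import edlib
import numpy as np

from .corpus import Language, Scene


@dataclass(frozen=True)
class ScoreReport:
    """A score plus how many pairs produced it.

    ``degenerate`` marks zero-variance correlations; the score is then
    reported as 0.0 so that downstream aggregation stays total, with the
    flag preserving auditability.
    """

    score: float
    n_pairs: int
    degenerate: bool = False

    def __float__(self) -> float:
        return float(self.score)


def levenshtein(a: str, b: str) -> int:
    """Plain Levenshtein distance (unit insert/delete/substitute costs)."""
    if a == b:
        return 0
    if len(a) == 0:
        return len(b)
    if len(b) == 0:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def normalized_edit_distance(a: str, b: str) -> float:
    """Levenshtein distance divided by the longer label's length, in [0, 1]."""
    a, b = str(a), str(b)
    if a == b:
        return 0.0
    return levenshtein(a, b) / max(len(a), len(b))


def production_similarity(a: str, b: str) -> float:
    """One minus length-normalized edit distance."""
    return 1.0 - normalized_edit_distance(a, b)


def angular_difference(a1: float, a2: float, circular: bool = True) -> float:
    """Difference between two angles in degrees.

    With ``circular=True`` (the default) the wrap-around is respected:
    min(|d|, 360 - |d|), bounded by 180.  With ``circular=False`` the raw
    absolute difference is returned.
    """
    d = abs(float(a1) - float(a2))
    if circular:
        d = min(d, 360.0 - d)
    return d


def semantic_difference(s1: Scene, s2: Scene, circular: bool = True) -> float:
    """Shape mismatch (0/1) plus angular difference over 180, in [0, 2]."""
    shape_term = 0.0 if s1.shape == s2.shape else 1.0
    return shape_term + angular_difference(s1.angle, s2.angle, circular) / 180.0


def _pearson(x: np.ndarray, y: np.ndarray) -> ScoreReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if x.std() == 0.0 or y.std() == 0.0:
        return ScoreReport(score=0.0, n_pairs=n, degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    return ScoreReport(score=r, n_pairs=n)


def structure_score(language: Language, circular: bool = True) -> ScoreReport:
    """Topographic similarity of a language's training items.

    Pearson r between pairwise semantic differences and pairwise
    normalized edit distances over all unordered item pairs (253 pairs
    for a standard 23-item language).
    """
    if len(language.items) < 3:
        raise ValueError("structure score needs at least 3 items")
    sem, form = [], []
    for (sc1, l1), (sc2, l2) in combinations(language.items, 2):
        sem.append(semantic_difference(sc1, sc2, circular))
        form.append(normalized_edit_distance(l1, l2))
    return _pearson(np.array(sem), np.array(form))


def generalization_score(
    train_prods: Sequence[tuple[Scene, str]],
    test_prods: Sequence[tuple[Scene, str]],
    circular: bool = True,
) -> ScoreReport:
    """Systematicity of one learner's generalizations.

    Pearson r between semantic differences and form distances over all
    |train| x |test| cross pairs of that learner's productions.
    """
    if not train_prods or not test_prods:
        raise ValueError("both production lists must be non-empty")
    sem, form = [], []
    for sc1, l1 in train_prods:
        for sc2, l2 in test_prods:
            sem.append(semantic_difference(sc1, sc2, circular))
            form.append(normalized_edit_distance(str(l1), str(l2)))
    return _pearson(np.array(sem), np.array(form))


def convergence_score(prods_by_agent: Sequence[Sequence[str]]) -> ScoreReport:
    """Agreement between learners of the same language.

    One minus the mean normalized edit distance over all scene-wise
    unordered agent pairs: with n scenes and k agents, n*k*(k-1)/2
    distances.  All-identical productions give 1; per-scene equal-length
    labels over mutually disjoint alphabets give 0.
    """
    k = len(prods_by_agent)
    if k < 2:
        raise ValueError("convergence needs at least 2 agents")
    n = len(prods_by_agent[0])
    if any(len(p) != n for p in prods_by_agent):
        raise ValueError("all agents must cover the same ordered scene set")
    dists = [
        normalized_edit_distance(str(pa[i]), str(pb[i]))
        for pa, pb in combinations(prods_by_agent, 2)
        for i in range(n)
    ]
    return ScoreReport(score=1.0 - float(np.mean(dists)), n_pairs=len(dists))


def similarity_to_reference(
    prods: Sequence[tuple[Scene, str]],
    reference: dict[Scene, Sequence[str]],
) -> ScoreReport:
    """Mean production similarity to reference labels, scene by scene.

    For each produced (scene, label), the similarity is averaged over all
    reference labels for that scene (e.g. several human learners); the
    result is the mean over scenes.
    """
    sims = []
    n_pairs = 0
    for scene, label in prods:
        if scene not in reference or len(reference[scene]) == 0:
            raise ValueError(f"no reference labels for scene {scene}")
        refs = reference[scene]
        sims.append(float(np.mean([production_similarity(str(label), str(r)) for r in refs])))
        n_pairs += len(refs)
    return ScoreReport(score=float(np.mean(sims)), n_pairs=n_pairs)


def mantel_permutation_p(
    x: Sequence[float], y: Sequence[float], n_permutations: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for a pairwise-vector correlation.

    Provided for auditing; headline scores are plain Pearson correlations.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(np.corrcoef(x, y)[0, 1])
    count = 1
    for _ in range(n_permutations):
        r = abs(np.corrcoef(rng.permutation(x), y)[0, 1])
        if r >= obs:
            count += 1
    return count / (n_permutations + 1)
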