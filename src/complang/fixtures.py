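"""Deterministic fixtures and independent oracles for the test suite.

Contains a brute-force dynamic-programming edit distance (the oracle the
fast library-backed metric is checked against), tiny hand-built
languages, and the published worked examples of generalization labels
produced by human, recurrent-network and GPT-3.5 learners for the same
scenes across differently structured input languages.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import Language, Scene


def oracle_edit_distance(a: str, b: str) -> int:
    """Classic quadratic dynamic program for Levenshtein distance.

    Test-only reference implementation; intentionally simple.
    """
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


@dataclass(frozen=True)
class WorkedExample:
    """One published generalization example: three learners, one scene."""

    structure_bin: str
    shape: int
    angle: float
    human: str
    rnn: str
    gpt: str

    @property
    def scene(self) -> Scene:
        return Scene(self.shape, self.angle)


def table2_pairs() -> list[WorkedExample]:
    """The published worked examples of generalization productions.

    Exact transcription of labels generated for unseen scenes by human
    learners, recurrent networks, and GPT-3.5, across input languages
    from low to high structure.
    """
    rows = [
        ("low", 2, 360, "koko", "kesee", "fetik-tik"),
        ("low", 4, 45, "woti", "kite", "hihi"),
        ("low", 3, 150, "ptiumi", "mihi", "himi"),
        ("mid-low", 3, 225, "wangsuus", "wangsoe", "wangsuus"),
        ("mid-low", 4, 225, "gntsoe", "gntuu", "gntsii"),
        ("mid-low", 1, 135, "sketsi", "gesh", "geshts"),
        ("mid", 3, 60, "powi", "powu-u-u", "powee"),
        ("mid", 4, 330, "fuottoa", "fuotio", "fuottu-u-u"),
        ("mid", 1, 30, "fewo-o-o-o", "fewen", "fewee"),
        ("mid-high", 1, 30, "fas-a", "fas-a", "fas-a"),
        ("mid-high", 3, 360, "muif-i", "muif-a", "muif-i"),
        ("mid-high", 1, 225, "fas-huif", "fas-huif", "fas-huif"),
        ("high", 4, 60, "smut-tkk", "smut-tk", "smut-ttk"),
        ("high", 2, 360, "nif-k", "nif-kks", "nif-k"),
        ("high", 1, 315, "wef-ks", "wef-kks", "wef-kks"),
    ]
    return [WorkedExample(*r) for r in rows]


def tiny_language(n_items: int = 4, compositional: bool = True) -> Language:
    """A hand-built miniature language for fast unit tests."""
    if compositional:
        items = [
            (Scene(1, 90), "fas-a"),
            (Scene(1, 180), "fas-e"),
            (Scene(2, 90), "nif-a"),
            (Scene(2, 180), "nif-e"),
            (Scene(3, 90), "muif-a"),
            (Scene(3, 180), "muif-e"),
        ][:n_items]
    else:
        items = [
            (Scene(1, 90), "koko"),
            (Scene(1, 180), "wangsus"),
            (Scene(2, 90), "ptiumi"),
            (Scene(2, 180), "gempt"),
            (Scene(3, 90), "sketsi"),
            (Scene(3, 180), "fuottoa"),
        ][:n_items]
    scenes = [s for s, _ in items]
    test = [Scene(4, 90), Scene(4, 180), Scene(1, 270)]
    distractors = [[s for s in scenes][:5] for _ in items]
    for i, (target, _) in enumerate(items):
        if target not in distractors[i]:
            distractors[i][0] = target
    return Language(
        name="tiny-compositional" if compositional else "tiny-holistic",
        items=items,
        test_scenes=test,
        distractor_sets=distractors,
    )
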