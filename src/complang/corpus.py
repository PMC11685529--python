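"""Data model for scenes, labels and artificial languages.

A *scene* is a meaning: one of four shapes moving at an angle in
(0, 360] degrees.  A *language* maps scenes to character-string labels;
it carries a train/test split of the scene inventory plus, per training
item, a distractor set used in the guessing task.

Scenes are presented to the learning agent as a 6-dimensional vector:
a one-hot encoding of the shape concatenated with the sine and cosine of
the angle, so that nearby directions receive nearby encodings while every
distinct angle remains distinguishable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

N_SHAPES = 4
DEFAULT_ALPHABET = "abcdefghijklmnopqrstuvwxyz-"
PAD_ID = 0
EOS_ID = 1
MAX_LABEL_LENGTH = 16


class DomainError(ValueError):
    """Raised when a scene, label or language violates its invariants."""


@dataclass(frozen=True, order=True)
class Scene:
    """One meaning: a shape category and a motion angle in degrees.

    Angle 0 is normalized to 360 so every direction has a single
    canonical representation ("north" is 360, not 0).
    """

    shape: int
    angle: float

    def __post_init__(self):
        if not isinstance(self.shape, (int, np.integer)) or not 1 <= self.shape <= N_SHAPES:
            raise DomainError(f"shape must be an integer in 1..{N_SHAPES}, got {self.shape!r}")
        angle = float(self.angle)
        if angle == 0.0:
            angle = 360.0
        if not 0.0 < angle <= 360.0:
            raise DomainError(f"angle must lie in (0, 360] degrees, got {self.angle!r}")
        object.__setattr__(self, "shape", int(self.shape))
        object.__setattr__(self, "angle", angle)


def encode_scene(scene: Scene) -> np.ndarray:
    """Encode a scene as one-hot(shape) ++ (sin(angle), cos(angle)).

    The angle is converted from degrees to radians before the transform.
    E.g. shape 2 at 90 degrees encodes to (0, 1, 0, 0, 1, 0).
    """
    if not isinstance(scene, Scene):
        scene = Scene(*scene)
    vec = np.zeros(6)
    vec[scene.shape - 1] = 1.0
    rad = math.radians(scene.angle)
    vec[4] = math.sin(rad)
    vec[5] = math.cos(rad)
    return vec


def encode_scenes(scenes: Sequence[Scene]) -> np.ndarray:
    """Stack scene encodings into an (n, 6) array."""
    return np.stack([encode_scene(s) for s in scenes])


@dataclass(frozen=True)
class Label:
    """A non-empty character string over a declared alphabet."""

    text: str
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self):
        if len(self.text) == 0:
            raise DomainError("label must be non-empty")
        bad = sorted(set(self.text) - set(self.alphabet))
        if bad:
            raise DomainError(f"label {self.text!r} contains characters outside alphabet: {bad}")

    def __str__(self) -> str:
        return self.text

    def __len__(self) -> int:
        return len(self.text)


class Vocabulary:
    """Character-level vocabulary: PAD=0, EOS=1, then alphabet characters."""

    def __init__(self, alphabet: str = DEFAULT_ALPHABET):
        self.alphabet = alphabet
        self.char_to_id = {c: i + 2 for i, c in enumerate(alphabet)}
        self.id_to_char = {i: c for c, i in self.char_to_id.items()}

    def __len__(self) -> int:
        return len(self.alphabet) + 2

    def tokenize(self, label: str | Label) -> list[int]:
        """Map a label to token ids terminated by EOS."""
        text = str(label)
        if len(text) == 0:
            raise DomainError("cannot tokenize an empty label")
        try:
            ids = [self.char_to_id[c] for c in text]
        except KeyError as e:
            raise DomainError(f"character {e.args[0]!r} not in vocabulary") from None
        return ids + [EOS_ID]

    def detokenize(self, ids: Iterable[int]) -> str:
        """Invert tokenize; PAD and everything from EOS onward are dropped."""
        chars = []
        for i in ids:
            if i == EOS_ID:
                break
            if i == PAD_ID:
                continue
            chars.append(self.id_to_char[int(i)])
        return "".join(chars)


def tokenize_label(label: str | Label, vocabulary: Vocabulary) -> list[int]:
    return vocabulary.tokenize(label)


def detokenize(ids: Iterable[int], vocabulary: Vocabulary) -> str:
    return vocabulary.detokenize(ids)


@dataclass
class Language:
    """A named set of scene-to-label mappings with a train/test split.

    ``items`` is the training set of (Scene, label) pairs; ``test_scenes``
    are held-out meanings with no ground-truth label.  ``distractor_sets``
    holds, per training item, the candidate scenes shown in the guessing
    task (always including the target).
    """

    name: str
    items: list[tuple[Scene, str]]
    test_scenes: list[Scene]
    alphabet: str = DEFAULT_ALPHABET
    distractor_sets: list[list[Scene]] | None = None
    _structure_score: float | None = field(default=None, repr=False)

    def __post_init__(self):
        train_scenes = [s for s, _ in self.items]
        if len(set(train_scenes)) != len(train_scenes):
            dupes = sorted({s for s in train_scenes if train_scenes.count(s) > 1})
            raise DomainError(f"duplicate training scenes: {dupes}")
        overlap = set(train_scenes) & set(self.test_scenes)
        if overlap:
            raise DomainError(f"test scenes overlap training scenes: {sorted(overlap)}")
        for _, label in self.items:
            Label(label, self.alphabet)  # validates
        if self.distractor_sets is not None:
            if len(self.distractor_sets) != len(self.items):
                raise DomainError("need one distractor set per training item")
            for (scene, _), cands in zip(self.items, self.distractor_sets):
                if scene not in cands:
                    raise DomainError(f"distractor set for {scene} does not contain the target")

    @property
    def train_scenes(self) -> list[Scene]:
        return [s for s, _ in self.items]

    @property
    def labels(self) -> list[str]:
        return [l for _, l in self.items]

    def label_for(self, scene: Scene) -> str:
        for s, l in self.items:
            if s == scene:
                return l
        raise KeyError(scene)

    def vocabulary(self) -> Vocabulary:
        return Vocabulary(self.alphabet)

    @property
    def structure_score(self) -> float:
        """Topographic similarity of the training items (computed lazily)."""
        if self._structure_score is None:
            from .metrics import structure_score

            self._structure_score = structure_score(self).score
        return self._structure_score

    def __len__(self) -> int:
        return len(self.items)


# ---------------------------------------------------------------------------
# Serialization: one directory per language with train.csv, test.csv and
# distractors.json.  CSV columns: shape,angle,label (train) / shape,angle
# (test).  Angles are written as shortest-round-trip floats; angle 0 is
# normalized to 360 on load.
# ---------------------------------------------------------------------------

def _fmt_angle(angle: float) -> str:
    return f"{angle:g}"


def write_language(language: Language, path: str | Path) -> None:
    """Write a language to ``path`` (a directory, created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = ["shape,angle,label"]
    for scene, label in language.items:
        lines.append(f"{scene.shape},{_fmt_angle(scene.angle)},{label}")
    (path / "train.csv").write_text("\n".join(lines) + "\n")
    lines = ["shape,angle"]
    for scene in language.test_scenes:
        lines.append(f"{scene.shape},{_fmt_angle(scene.angle)}")
    (path / "test.csv").write_text("\n".join(lines) + "\n")
    meta = {"name": language.name, "alphabet": language.alphabet}
    if language.distractor_sets is not None:
        meta["distractors"] = [
            [[s.shape, s.angle] for s in cands] for cands in language.distractor_sets
        ]
    (path / "distractors.json").write_text(json.dumps(meta, indent=1) + "\n")


def read_language(path: str | Path) -> Language:
    """Read a language directory written by :func:`write_language`."""
    path = Path(path)
    train_lines = (path / "train.csv").read_text().strip().splitlines()
    header = train_lines[0].strip().lower()
    if header.split(",")[:3] != ["shape", "angle", "label"]:
        raise DomainError(f"unexpected train.csv header: {header!r}")
    items: list[tuple[Scene, str]] = []
    for line in train_lines[1:]:
        shape, angle, label = line.split(",", 2)
        items.append((Scene(int(shape), float(angle)), label.strip()))
    test_lines = (path / "test.csv").read_text().strip().splitlines()
    test_scenes = []
    for line in test_lines[1:]:
        shape, angle = line.split(",")
        test_scenes.append(Scene(int(shape), float(angle)))
    name = path.name
    alphabet = None
    distractors = None
    meta_path = path / "distractors.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        name = meta.get("name", name)
        alphabet = meta.get("alphabet")
        if "distractors" in meta:
            distractors = [
                [Scene(int(sh), float(an)) for sh, an in cands]
                for cands in meta["distractors"]
            ]
    if alphabet is None:
        # infer: default alphabet restricted to observed characters, but keep
        # the full default if all labels fit in it
        observed = set("".join(l for _, l in items))
        if observed <= set(DEFAULT_ALPHABET):
            alphabet = DEFAULT_ALPHABET
        else:
            alphabet = "".join(sorted(observed))
    return Language(
        name=name,
        items=items,
        test_scenes=test_scenes,
        alphabet=alphabet,
        distractor_sets=distractors,
    )
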