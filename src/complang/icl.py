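"""In-context-learning probe for pretrained language models.

Builds a prompt of 23 JSON-lines demonstrations (shape, angle, word)
followed by one query line without a word, sends it to an *injected*
completion function (a plain str -> str callable; no network code
lives here), parses the completion back into a label, and scores the
productions with exactly the same metrics as the recurrent agents.

Deterministic fake completers are provided for testing: a copy
completer (returns the demonstrated word for known scenes) and a
nearest-neighbour completer (returns the word of the semantically
closest demonstrated scene).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

from .corpus import Language, Scene
from .metrics import semantic_difference
from .training import ProductionRecord

CompletionFn = Callable[[str], str]


@dataclass
class PromptSpec:
    """Prompt format: JSON-lines demonstrations, no task description."""

    include_task_description: bool = False
    temperature: float = 0.0
    shape_key: str = "shape"
    angle_key: str = "angle"
    word_key: str = "word"


def _angle_repr(angle: float):
    return int(angle) if float(angle).is_integer() else angle


def build_prompt(language: Language, query: Scene, spec: PromptSpec | None = None) -> str:
    """Demonstrations in item order, then one query line lacking the word.

    A memorization probe (query equal to a training scene) still sees
    that scene labeled earlier in the prompt, so perfect copying is the
    perfect solution.
    """
    spec = spec or PromptSpec()
    if len(language.items) == 0:
        raise ValueError("cannot build a prompt from an empty language")
    lines = []
    if spec.include_task_description:
        lines.append(json.dumps({"task": "produce the word for the last scene"}))
    for scene, label in language.items:
        lines.append(
            json.dumps(
                {
                    spec.shape_key: scene.shape,
                    spec.angle_key: _angle_repr(scene.angle),
                    spec.word_key: label,
                },
                separators=(", ", ": "),
            )
        )
    lines.append(
        json.dumps(
            {spec.shape_key: query.shape, spec.angle_key: _angle_repr(query.angle)},
            separators=(", ", ": "),
        )
    )
    return "\n".join(lines)


def parse_completion(text: str) -> tuple[str, bool]:
    """Extract a single label from a raw completion.

    Strips JSON punctuation, quotes and whitespace, drops a leading
    ``word:`` field name, and truncates multi-word output to the first
    token.  Returns (label, flagged) where the flag marks output that
    needed truncation or contains characters outside the default
    alphabet; flagged output is kept, not rejected.
    """
    flagged = False
    stripped = text.strip().strip("{}[]").strip()
    for prefix in ('"word"', "'word'", "word"):
        if stripped.lower().startswith(prefix):
            rest = stripped[len(prefix):].lstrip()
            if rest[:1] in (":", "="):
                stripped = rest[1:].strip()
    stripped = stripped.strip('{}[],:"\' \t\n')
    tokens = stripped.split()
    if len(tokens) > 1:
        flagged = True
    label = tokens[0].strip('{}[],:"\'') if tokens else ""
    if any(not (c.isalpha() and c.islower()) and c != "-" for c in label):
        flagged = True
    return label, flagged


def copy_completer(language: Language, spec: PromptSpec | None = None) -> CompletionFn:
    """Oracle that copies the demonstrated word for a seen query scene.

    Unseen scenes fall back to the word of the nearest demonstrated
    scene, mimicking a learner that can only retrieve.
    """
    return nearest_neighbor_completer(language, spec, exact_first=True)


def nearest_neighbor_completer(
    language: Language, spec: PromptSpec | None = None, exact_first: bool = True
) -> CompletionFn:
    """Returns the word of the semantically closest demonstrated scene."""
    spec = spec or PromptSpec()

    def complete(prompt: str) -> str:
        lines = [json.loads(l) for l in prompt.strip().splitlines() if l.strip()]
        demos = [l for l in lines if spec.word_key in l]
        query = lines[-1]
        q = Scene(int(query[spec.shape_key]), float(query[spec.angle_key]))
        best, best_d = None, float("inf")
        for d in demos:
            s = Scene(int(d[spec.shape_key]), float(d[spec.angle_key]))
            if exact_first and s == q:
                return f'"{d[spec.word_key]}"'
            dist = semantic_difference(s, q)
            if dist < best_d:
                best, best_d = d[spec.word_key], dist
        return f'"{best}"'

    return complete


def run_icl_probe(
    completion_fn: CompletionFn,
    language: Language,
    spec: PromptSpec | None = None,
    agent_id: int = 0,
    fallback_char: str = "a",
) -> tuple[list[ProductionRecord], list[ProductionRecord]]:
    """Query every train and test scene independently.

    No history accumulates between queries and the probe never feeds its
    own productions back into the prompt.  A completer error or an empty
    parse yields a flagged single-character fallback record so one bad
    item cannot abort the probe.
    """
    spec = spec or PromptSpec()

    def one(scene: Scene, phase: str) -> ProductionRecord:
        prompt = build_prompt(language, scene, spec)
        try:
            label, flagged = parse_completion(completion_fn(prompt))
        except Exception:
            label, flagged = "", True
        if not label:
            label, flagged = fallback_char, True
        return ProductionRecord(
            agent_id=agent_id,
            language_name=language.name,
            round=0,
            scene=scene,
            produced=label,
            phase=phase,
            fallback=flagged,
        )

    memorization = [one(s, "memorization") for s in language.train_scenes]
    generalization = [one(s, "generalization") for s in language.test_scenes]
    return memorization, generalization
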