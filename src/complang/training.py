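"""Round-based training protocol mirroring the human learning experiment.

Each round has three blocks.  *Exposure*: one shuffled pass over the
training items in minibatches of 5, optimizing the generative plus
weighted contrastive loss with in-batch distractors.  *Guessing*: one
step per item at batch size 1, where the contrastive candidates are the
item's stored distractor set (the generative term is kept so the agent
does not forget how to produce); guessing accuracy is measured with
frozen parameters before the block's updates.  *Production*: another
pass over the items optimizing the generative term only.  After the
blocks, the agent greedy-produces labels for all training scenes
(memorization test) and all held-out scenes (generalization test)
without any parameter updates.

`LearningSession` is the model object; its :meth:`~LearningSession.fit`
returns a :class:`LearningResults` carrying the per-round production
records, losses and metric trajectories.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import Agent, AgentConfig, LossBreakdown, init_agent
from .corpus import Language, Scene
from .metrics import (
    generalization_score,
    production_similarity,
    similarity_to_reference,
)


@dataclass
class ProductionRecord:
    """One produced label for one scene by one learner at one round."""

    agent_id: int
    language_name: str
    round: int
    scene: Scene
    produced: str
    phase: str  # "memorization" | "generalization"
    fallback: bool = False


@dataclass
class RoundResult:
    """Outcome of one exposure/guessing/production round plus tests."""

    round: int
    memorization: list[ProductionRecord]
    generalization: list[ProductionRecord]
    guessing_accuracy: float
    losses: dict[str, LossBreakdown]


def _minibatches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def run_exposure_block(
    agent: Agent, language: Language, batch_size: int = 5, rng: np.random.Generator | None = None
) -> LossBreakdown:
    """One shuffled pass; per minibatch one step on L_gen + alpha * L_con."""
    rng = rng or np.random.default_rng(0)
    scenes, labels = language.train_scenes, language.labels
    total = LossBreakdown(0.0, 0.0, agent.config.alpha_con)
    n_batches = 0
    for idx in _minibatches(len(scenes), batch_size, rng):
        bs = [scenes[i] for i in idx]
        bl = [labels[i] for i in idx]
        gen = agent.generative_loss(bs, bl)
        if len(idx) >= 2:
            con = agent.contrastive_loss(bs, bl)
            loss = gen + con * agent.config.alpha_con
            con_val = float(con.data)
        else:  # a singleton cannot form contrastive pairs
            loss, con_val = gen, 0.0
        agent.step(loss)
        total = total + LossBreakdown(float(gen.data), con_val, agent.config.alpha_con)
        n_batches += 1
    return LossBreakdown(
        total.generative / n_batches, total.contrastive / n_batches, agent.config.alpha_con
    )


def measure_guessing_accuracy(agent: Agent, language: Language) -> float:
    """Fraction of items whose stored distractor set is guessed correctly."""
    if language.distractor_sets is None:
        raise ValueError("language has no distractor sets")
    hits = 0
    for (scene, label), cands in zip(language.items, language.distractor_sets):
        target = cands.index(scene)
        if agent.guess(label, cands) == target:
            hits += 1
    return hits / len(language.items)


def run_guessing_block(
    agent: Agent, language: Language, rng: np.random.Generator | None = None
) -> tuple[LossBreakdown, float]:
    """Per item, one step on L_gen + alpha * L_con over its distractor set.

    Accuracy is reported from the parameters as they were *before* the
    block's updates.
    """
    if language.distractor_sets is None:
        raise ValueError("language has no distractor sets")
    rng = rng or np.random.default_rng(0)
    accuracy = measure_guessing_accuracy(agent, language)
    order = rng.permutation(len(language.items))
    gen_sum = con_sum = 0.0
    for i in order:
        scene, label = language.items[i]
        cands = language.distractor_sets[i]
        gen = agent.generative_loss([scene], [label])
        con = agent.guessing_loss(label, cands, cands.index(scene))
        agent.step(gen + con * agent.config.alpha_con)
        gen_sum += float(gen.data)
        con_sum += float(con.data)
    n = len(language.items)
    return LossBreakdown(gen_sum / n, con_sum / n, agent.config.alpha_con), accuracy


def run_production_block(
    agent: Agent, language: Language, batch_size: int = 5, rng: np.random.Generator | None = None
) -> LossBreakdown:
    """One shuffled pass on the generative loss alone (contrastive = 0)."""
    rng = rng or np.random.default_rng(0)
    scenes, labels = language.train_scenes, language.labels
    gen_sum = 0.0
    n_batches = 0
    for idx in _minibatches(len(scenes), batch_size, rng):
        gen = agent.generative_loss([scenes[i] for i in idx], [labels[i] for i in idx])
        agent.step(gen)
        gen_sum += float(gen.data)
        n_batches += 1
    return LossBreakdown(gen_sum / n_batches, 0.0, agent.config.alpha_con)


def run_tests(agent: Agent, language: Language, round_no: int, agent_id: int = 0):
    """Greedy-produce labels for all train and test scenes (no updates)."""
    mem = [
        ProductionRecord(agent_id, language.name, round_no, s, lab, "memorization", fb)
        for s, (lab, fb) in zip(
            language.train_scenes, agent.produce_batch(language.train_scenes)
        )
    ]
    gen = [
        ProductionRecord(agent_id, language.name, round_no, s, lab, "generalization", fb)
        for s, (lab, fb) in zip(language.test_scenes, agent.produce_batch(language.test_scenes))
    ]
    return mem, gen


def run_round(
    agent: Agent,
    language: Language,
    round_no: int,
    rng: np.random.Generator,
    batch_size: int = 5,
    agent_id: int = 0,
) -> RoundResult:
    """Execute exposure, guessing, production, then the two tests."""
    exposure = run_exposure_block(agent, language, batch_size, rng)
    guessing, accuracy = run_guessing_block(agent, language, rng)
    production = run_production_block(agent, language, batch_size, rng)
    mem, gen = run_tests(agent, language, round_no, agent_id)
    return RoundResult(
        round=round_no,
        memorization=mem,
        generalization=gen,
        guessing_accuracy=accuracy,
        losses={"exposure": exposure, "guessing": guessing, "production": production},
    )


class LearningSession:
    """One agent learning one language; the model object.

    Parameters
    ----------
    language : Language
        The input language (must carry distractor sets for guessing).
    config : AgentConfig, optional
        Agent hyperparameters; the config seed controls initialization
        and all block shuffling.
    """

    def __init__(self, language: Language, config: AgentConfig | None = None):
        self.language = language
        self.config = config or AgentConfig(alphabet=language.alphabet)
        self.agent = init_agent(self.config)

    def fit(self, n_rounds: int = 100, batch_size: int = 5) -> "LearningResults":
        """Train for ``n_rounds`` rounds and collect per-round results."""
        rounds: list[RoundResult] = []
        t0 = time.perf_counter()
        for r in range(1, n_rounds + 1):
            # reseed shuffling per round from the agent seed, reproducibly
            rng = np.random.default_rng([self.config.seed, r])
            rounds.append(
                run_round(self.agent, self.language, r, rng, batch_size, self.config.seed)
            )
        wall_time = time.perf_counter() - t0
        return LearningResults(self.language, self.config, rounds, wall_time)


@dataclass
class LearningResults:
    """Trajectory of one agent: production records and metrics per round."""

    language: Language
    config: AgentConfig
    rounds: list[RoundResult]
    wall_time: float = 0.0

    def true_label_similarity(self, round_result: RoundResult) -> float:
        """Mean production similarity to the input language (memorization)."""
        return float(
            np.mean(
                [
                    production_similarity(rec.produced, self.language.label_for(rec.scene))
                    for rec in round_result.memorization
                ]
            )
        )

    def generalization(self, round_result: RoundResult):
        return generalization_score(
            [(r.scene, r.produced) for r in round_result.memorization],
            [(r.scene, r.produced) for r in round_result.generalization],
        )

    def reference_similarity(self, round_result: RoundResult, reference, phase: str):
        records = (
            round_result.memorization if phase == "memorization" else round_result.generalization
        )
        return similarity_to_reference([(r.scene, r.produced) for r in records], reference)

    def trajectory(self) -> pd.DataFrame:
        """Per-round summary metrics as a tidy DataFrame."""
        rows = []
        for rr in self.rounds:
            rows.append(
                {
                    "round": rr.round,
                    "true_label_similarity": self.true_label_similarity(rr),
                    "generalization_score": self.generalization(rr).score,
                    "guessing_accuracy": rr.guessing_accuracy,
                    "loss_exposure": rr.losses["exposure"].total,
                    "loss_production": rr.losses["production"].total,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the learning trajectory."""
        df = self.trajectory()
        last = df.iloc[-1] if len(df) else None
        lines = [
            "Learning session summary",
            "========================",
            f"language:            {self.language.name}",
            f"structure score:     {self.language.structure_score:.3f}",
            f"items (train/test):  {len(self.language.items)}/{len(self.language.test_scenes)}",
            f"rounds trained:      {len(self.rounds)}",
            f"agent seed:          {self.config.seed}",
        ]
        if last is not None:
            lines += [
                f"final true-label similarity:  {last['true_label_similarity']:.3f}",
                f"final generalization score:   {last['generalization_score']:.3f}",
                f"final guessing accuracy:      {last['guessing_accuracy']:.3f}",
            ]
        return "\n".join(lines)

    def plot_trajectory(self, ax=None):
        """Plot metric trajectories over rounds (matplotlib axes)."""
        import matplotlib.pyplot as plt

        df = self.trajectory()
        if ax is None:
            _, ax = plt.subplots()
        for col in ("true_label_similarity", "generalization_score", "guessing_accuracy"):
            ax.plot(df["round"], df[col], label=col.replace("_", " "))
        ax.set_xlabel("round")
        ax.set_ylabel("score")
        ax.set_ylim(-0.05, 1.05)
        ax.legend()
        return ax


def train_agent(
    agent: Agent, language: Language, n_rounds: int = 100, batch_size: int = 5
) -> list[RoundResult]:
    """Functional entry point: train an existing agent for n rounds."""
    rounds = []
    for r in range(1, n_rounds + 1):
        rng = np.random.default_rng([agent.config.seed, r])
        rounds.append(run_round(agent, language, r, rng, batch_size, agent.config.seed))
    return rounds
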