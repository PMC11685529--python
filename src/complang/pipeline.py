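"""Orchestration of the full grid: languages x seeds x rounds.

Runs independent learning sessions, collects per-round production
records and measures into a long-format results table, bins languages by
structure score, and performs the memorization-error analysis (how
similar are imperfectly memorized labels to the truth).

Scene-level measures (true/reference label similarity) produce one row
per (language, seed, round, scene); agent-level measures (generalization
score, guessing accuracy) and the per-language convergence score use an
empty scene_id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import AgentConfig
from .corpus import Language, Scene
from .metrics import (
    convergence_score,
    generalization_score,
    production_similarity,
)
from .training import LearningSession

MEASURES = (
    "true_label_similarity",
    "reference_label_similarity",
    "generalization_score",
    "convergence_score",
    "guessing_accuracy",
)


@dataclass
class DesignManifest:
    """Bookkeeping for an experimental grid."""

    n_seeds_per_language: int
    n_languages: int
    n_rounds: int
    n_memorization_items: int = 23
    n_generalization_items: int = 13


def enumerate_design(manifest: DesignManifest) -> tuple[int, int]:
    """Total memorization and generalization evaluations in a grid.

    The reference design (100 seeds x 10 languages x 100 rounds with
    23 + 13 test items) yields 2.3M and 1.3M evaluations.
    """
    base = manifest.n_seeds_per_language * manifest.n_languages * manifest.n_rounds
    return (
        base * manifest.n_memorization_items,
        base * manifest.n_generalization_items,
    )


def design_summary(manifest: DesignManifest) -> str:
    """Human-readable totals, reported in millions where large."""
    mem, gen = enumerate_design(manifest)

    def fmt(n: int) -> str:
        return f"{n / 1e6:g}M" if n >= 100_000 else str(n)

    return f"{fmt(mem)} memorization / {fmt(gen)} generalization evaluations"


def _scene_id(scene: Scene) -> str:
    return f"s{scene.shape}a{scene.angle:g}"


@dataclass
class ResultsTable:
    """Long-format experiment output.

    ``productions`` has one row per produced label; ``measures`` has one
    row per (language, seed, round, scene, measure) for scene-level
    measures and scene_id "" for agent- or language-level ones.
    """

    productions: pd.DataFrame
    measures: pd.DataFrame

    def final_round(self) -> int:
        return int(self.productions["round"].max())


def run_experiment(
    languages: list[Language],
    n_seeds: int = 10,
    n_rounds: int = 40,
    config: AgentConfig | None = None,
    reference_productions: dict[str, list] | None = None,
    base_seed: int = 0,
    progress: bool = False,
) -> ResultsTable:
    """Train ``n_seeds`` agents per language and collect all measures.

    Per agent and round: true-label similarity, reference-label
    similarity (if reference productions are supplied), generalization
    score, guessing accuracy; per language and round: convergence score
    over that language's agents.  Deterministic given the seeds: agents
    are independent jobs and results are merged in (language, seed)
    order regardless of execution order.
    """
    from .synthetic import reference_lookup

    prod_rows = []
    measure_rows = []
    for language in sorted(languages, key=lambda l: l.name):
        structure = language.structure_score
        refs = None
        if reference_productions and language.name in reference_productions:
            learners = reference_productions[language.name]
            refs = {
                "memorization": reference_lookup(learners, "train"),
                "generalization": reference_lookup(learners, "test"),
            }
        # per (round, scene): productions of every agent, for convergence
        by_round_gen: dict[int, list[list[str]]] = {}
        for seed in range(n_seeds):
            agent_seed = base_seed * 10_000 + seed
            cfg = config or AgentConfig(alphabet=language.alphabet)
            cfg = AgentConfig(**{**cfg.__dict__, "seed": agent_seed, "alphabet": language.alphabet})
            session = LearningSession(language, cfg)
            results = session.fit(n_rounds=n_rounds)
            if progress:
                print(f"  {language.name} seed {seed}: done in {results.wall_time:.1f}s")
            for rr in results.rounds:
                mem = [(r.scene, r.produced) for r in rr.memorization]
                gen = [(r.scene, r.produced) for r in rr.generalization]
                for rec in rr.memorization + rr.generalization:
                    prod_rows.append(
                        {
                            "language": language.name,
                            "structure_score": structure,
                            "agent_seed": seed,
                            "round": rr.round,
                            "scene_id": _scene_id(rec.scene),
                            "shape": rec.scene.shape,
                            "angle": rec.scene.angle,
                            "phase": rec.phase,
                            "produced": rec.produced,
                        }
                    )
                for scene, label in mem:
                    measure_rows.append(
                        {
                            "language": language.name,
                            "structure_score": structure,
                            "agent_seed": seed,
                            "round": rr.round,
                            "scene_id": _scene_id(scene),
                            "phase": "memorization",
                            "measure": "true_label_similarity",
                            "value": production_similarity(label, language.label_for(scene)),
                        }
                    )
                if refs is not None:
                    for phase, prods in (("memorization", mem), ("generalization", gen)):
                        for scene, label in prods:
                            measure_rows.append(
                                {
                                    "language": language.name,
                                    "structure_score": structure,
                                    "agent_seed": seed,
                                    "round": rr.round,
                                    "scene_id": _scene_id(scene),
                                    "phase": phase,
                                    "measure": "reference_label_similarity",
                                    "value": float(
                                        np.mean(
                                            [
                                                production_similarity(label, r)
                                                for r in refs[phase][scene]
                                            ]
                                        )
                                    ),
                                }
                            )
                measure_rows.append(
                    {
                        "language": language.name,
                        "structure_score": structure,
                        "agent_seed": seed,
                        "round": rr.round,
                        "scene_id": "",
                        "phase": "generalization",
                        "measure": "generalization_score",
                        "value": generalization_score(mem, gen).score,
                    }
                )
                measure_rows.append(
                    {
                        "language": language.name,
                        "structure_score": structure,
                        "agent_seed": seed,
                        "round": rr.round,
                        "scene_id": "",
                        "phase": "guessing",
                        "measure": "guessing_accuracy",
                        "value": rr.guessing_accuracy,
                    }
                )
                by_round_gen.setdefault(rr.round, []).append([l for _, l in gen])
        for rnd, per_agent in sorted(by_round_gen.items()):
            if len(per_agent) >= 2:
                measure_rows.append(
                    {
                        "language": language.name,
                        "structure_score": structure,
                        "agent_seed": -1,
                        "round": rnd,
                        "scene_id": "",
                        "phase": "generalization",
                        "measure": "convergence_score",
                        "value": convergence_score(per_agent).score,
                    }
                )
    return ResultsTable(pd.DataFrame(prod_rows), pd.DataFrame(measure_rows))


def memorization_error_analysis(
    table: ResultsTable, languages: list[Language], final_round: int | None = None
) -> pd.DataFrame:
    """Error rate and similarity-to-truth of erroneous memorizations.

    An error is a final-round memorization production that differs from
    the ground-truth label in any character; the similarity column is
    computed over errors only (NaN, flagged, when a language has none).
    """
    truth = {l.name: {_scene_id(s): lab for s, lab in l.items} for l in languages}
    prods = table.productions
    if final_round is None:
        final_round = table.final_round()
    sel = prods[(prods["round"] == final_round) & (prods["phase"] == "memorization")]
    rows = []
    for name, group in sel.groupby("language", sort=True):
        t = truth[name]
        correct = group.apply(lambda r: r["produced"] == t[r["scene_id"]], axis=1)
        errors = group[~correct]
        sims = [
            production_similarity(r["produced"], t[r["scene_id"]]) for _, r in errors.iterrows()
        ]
        rows.append(
            {
                "language": name,
                "structure_score": group["structure_score"].iloc[0],
                "n_productions": len(group),
                "error_rate": 1.0 - float(correct.mean()),
                "error_similarity": float(np.mean(sims)) if sims else float("nan"),
                "no_errors": len(sims) == 0,
            }
        )
    return pd.DataFrame(rows)


def bin_by_structure(table: ResultsTable, n_bins: int = 5) -> pd.DataFrame:
    """Group languages into equal-membership bins by structure-score rank.

    When counts do not divide evenly the extra languages go to the
    lowest bins.  Returns per-bin per-round mean measure values with
    language and observation counts.
    """
    langs = (
        table.measures[["language", "structure_score"]]
        .drop_duplicates()
        .sort_values(["structure_score", "language"])
        .reset_index(drop=True)
    )
    n = len(langs)
    if n_bins > n:
        n_bins = n
    sizes = [n // n_bins + (1 if i < n % n_bins else 0) for i in range(n_bins)]
    assignment = {}
    start = 0
    for b, size in enumerate(sizes):
        for i in range(start, start + size):
            assignment[langs.loc[i, "language"]] = b
        start += size
    m = table.measures.copy()
    m["structure_bin"] = m["language"].map(assignment)
    out = (
        m.groupby(["structure_bin", "round", "measure"])
        .agg(value=("value", "mean"), n=("value", "size"), n_languages=("language", "nunique"))
        .reset_index()
    )
    return out
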