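"""Linear mixed-effects analysis of the learning measures.

Each measure is regressed on the language's structure score and the
natural-log round number (both centered and scaled by default) with an
optional interaction, plus crossed random intercepts for the agent seed
and the specific scene.  The solver is statsmodels' MixedLM; this
module's own content is the design construction, the predictor
transforms, and recovery diagnostics.

The fitting surface follows the statsmodels idiom:
``StructureEffectModel(table, spec).fit()`` returns a results object
with per-term estimates and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf


@dataclass
class ModelSpec:
    """What to regress and how to transform the predictors.

    ``scale_log_round=False`` reproduces the center-only variant used
    when scaling the log-round predictor hinders convergence.
    """

    response: str = "value"
    include_interaction: bool = True
    scale_structure: bool = True
    scale_log_round: bool = True
    random_seed_intercept: bool = True
    random_scene_intercept: bool = True


@dataclass
class EffectEstimate:
    """One fixed-effect estimate: beta, its SE, z = beta/se, and p."""

    term: str
    beta: float
    se: float

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def p(self) -> float:
        return 2.0 * float(sps.norm.sf(abs(self.z)))


def _standardize(x: np.ndarray, scale: bool) -> np.ndarray:
    x = x - x.mean()
    if scale:
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot scale a zero-variance predictor; use center-only")
        x = x / sd
    return x


def build_long_table(measures: pd.DataFrame, measure: str, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Model-ready table for one measure.

    One row per observation with columns value, structure_z (centered/
    scaled structure score), log_round_z (centered/scaled ln round),
    seed and scene grouping labels.  Rows with missing values are
    rejected rather than silently dropped.
    """
    spec = spec or ModelSpec()
    sel = measures[measures["measure"] == measure]
    if len(sel) == 0:
        raise ValueError(f"no rows for measure {measure!r}")
    if sel["value"].isna().any():
        raise ValueError("missing values in response")
    out = pd.DataFrame(
        {
            "value": sel["value"].to_numpy(dtype=float),
            "structure_z": _standardize(
                sel["structure_score"].to_numpy(dtype=float), spec.scale_structure
            ),
            "log_round_z": _standardize(
                np.log(sel["round"].to_numpy(dtype=float)), spec.scale_log_round
            ),
            "seed": sel["language"].astype(str) + "/" + sel["agent_seed"].astype(str),
            "scene": sel["scene_id"].astype(str),
        }
    )
    return out.reset_index(drop=True)


class StructureEffectModel:
    """Mixed model of one measure on structure score and log round."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        required = {"value", "structure_z", "log_round_z", "seed"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table lacks columns: {sorted(missing)}")
        self.table = table

    def fit(self) -> "StructureEffectResults":
        spec = self.spec
        fixed = "value ~ structure_z + log_round_z"
        if spec.include_interaction:
            fixed += " + structure_z:log_round_z"
        vc = {}
        if spec.random_seed_intercept and self.table["seed"].nunique() > 1:
            vc["seed"] = "0 + C(seed)"
        has_scene = (
            spec.random_scene_intercept
            and "scene" in self.table.columns
            and self.table["scene"].mask(self.table["scene"] == "").nunique(dropna=True) > 1
        )
        if has_scene:
            vc["scene"] = "0 + C(scene)"
        df = self.table.copy()
        df["_group"] = 1  # crossed random intercepts via variance components
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(fixed, df, groups="_group", vc_formula=vc if vc else None)
            fitted = model.fit(reml=True, method="lbfgs", maxiter=200)
        estimates = []
        for term in fitted.fe_params.index:
            estimates.append(
                EffectEstimate(
                    term=term,
                    beta=float(fitted.fe_params[term]),
                    se=float(fitted.bse_fe[term]),
                )
            )
        return StructureEffectResults(
            estimates=estimates,
            converged=bool(fitted.converged),
            resid=np.asarray(fitted.resid, dtype=float),
            n_obs=len(df),
            spec=spec,
        )


@dataclass
class StructureEffectResults:
    """Fixed-effect estimates plus convergence and residual diagnostics."""

    estimates: list[EffectEstimate]
    converged: bool
    resid: np.ndarray
    n_obs: int
    spec: ModelSpec = field(default_factory=ModelSpec)

    def __getitem__(self, term: str) -> EffectEstimate:
        for e in self.estimates:
            if e.term == term:
                return e
        raise KeyError(term)

    @property
    def structure(self) -> EffectEstimate:
        return self["structure_z"]

    @property
    def log_round(self) -> EffectEstimate:
        return self["log_round_z"]

    def qq_data(self) -> tuple[np.ndarray, np.ndarray]:
        """Theoretical and sample quantiles of the residuals (QQ plot)."""
        osm, osr = sps.probplot(self.resid, dist="norm", fit=False)
        return np.asarray(osm), np.asarray(osr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": e.term, "beta": e.beta, "se": e.se, "z": e.z, "p": e.p,
                 "converged": self.converged}
                for e in self.estimates
            ]
        )

    def summary(self) -> str:
        lines = [
            "Mixed-effects fit (crossed random intercepts: seed, scene)",
            f"observations: {self.n_obs}   converged: {self.converged}",
            f"{'term':<28}{'beta':>10}{'SE':>9}{'z':>10}{'p':>10}",
        ]
        for e in self.estimates:
            p = f"{e.p:.3g}" if e.p >= 1e-3 else "<0.001"
            lines.append(f"{e.term:<28}{e.beta:>10.4f}{e.se:>9.4f}{e.z:>10.2f}{p:>10}")
        return "\n".join(lines)


def fit_structure_effect(
    measures: pd.DataFrame, measure: str, spec: ModelSpec | None = None
) -> StructureEffectResults:
    """Convenience wrapper: build the long table and fit in one call."""
    table = build_long_table(measures, measure, spec)
    return StructureEffectModel(table, spec).fit()
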