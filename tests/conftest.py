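"""Shared fixtures.

The `experiment_grid` fixture runs the scaled-down study once per
session -- a 5-language synthetic suite spanning low to high structure,
10 agent seeds per language, 60 training rounds -- and is shared by the
trend, trajectory and error-analysis acceptance tests.
"""

import pytest

from complang.agent import AgentConfig
from complang.pipeline import run_experiment
from complang.synthetic import (
    GeneratorSpec,
    ReferenceLearnerSpec,
    make_language_suite,
    make_reference_productions,
)

SUITE_SEED = 1
GRID_SEEDS = 10
GRID_ROUNDS = 60


@pytest.fixture(scope="session")
def language_suite():
    return make_language_suite(GeneratorSpec(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def experiment_grid(language_suite):
    references = {
        lang.name: make_reference_productions(lang, ReferenceLearnerSpec(), seed=SUITE_SEED)
        for lang in language_suite
    }
    return run_experiment(
        language_suite,
        n_seeds=GRID_SEEDS,
        n_rounds=GRID_ROUNDS,
        reference_productions=references,
        base_seed=0,
    )
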