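import warnings

import numpy as np
import pandas as pd
import pytest

from updatebias.cohort import CohortConfig, simulate_cohort
from updatebias.model import MCMCSettings, ModelSpec, fit_model

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects x 40 items of VAS-gridded ratings; quick for module tests."""
    return simulate_cohort(CohortConfig(n_subjects=6, discretize=True), seed=101)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    return fit_model(
        small_cohort.ratings,
        ModelSpec(),
        MCMCSettings(chains=2, warmup=200, iterations=300, seed=11),
        check=False,
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Full study-sized cohort: 50 subjects x 40 items with known bias spread."""
    return simulate_cohort(CohortConfig(), seed=0)


@pytest.fixture(scope="session")
def study_fit(study_cohort):
    return fit_model(
        study_cohort.ratings,
        ModelSpec(),
        MCMCSettings.profile("ci", seed=0),
        check=False,
    )


def make_schedule(n_items: int, seed: int) -> "pd.DataFrame":
    """Large schedule built directly from the proportional score inventory.

    The task's null-PE cap is a 40-item design constant, so oversized
    schedules used in large-n consistency tests are assembled directly.
    """
    from updatebias.task_design import FeedbackSchedule, _reduced_inventory

    rng = np.random.default_rng(seed)
    inv = _reduced_inventory(n_items)
    scores = np.repeat(list(inv.keys()), list(inv.values()))
    rng.shuffle(scores)
    expected = np.clip(rng.normal(5.0, 1.5, size=n_items), 0, 10)
    table = pd.DataFrame(
        {
            "item_id": np.arange(1, n_items + 1),
            "expected": expected,
            "score": scores,
            "condition": np.where(scores >= 7, "positive", "neutral"),
            "pe": scores - np.rint(expected),
        }
    )
    return FeedbackSchedule(table)
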