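"""Shared fixtures.

The heavy Monte-Carlo studies are session-scoped so the calibration, power,
coverage and robustness checks all read from the same simulation runs.
Replicate counts follow the scaled-down study sizes documented in
docs/methods.md; seeds are fixed constants.
"""

import numpy as np
import pytest

from conmixmr import SimScenario, SummarySet, run_study


@pytest.fixture(scope="session")
def scenario1_null_study():
    """Scenario 1 (all instruments valid), null effect, 1000 replicates."""
    return run_study(
        SimScenario.standard(1, theta=0.0),
        methods=("ivw_random", "conmix"),
        n_reps=1000,
        base_seed=911,
        psi=1.0,
    )


@pytest.fixture(scope="session")
def scenario1_pos_study():
    """Scenario 1, positive effect theta=+0.1, 1000 replicates."""
    return run_study(
        SimScenario.standard(1, theta=0.1),
        methods=("ivw_random", "conmix"),
        n_reps=1000,
        base_seed=912,
        psi=1.0,
    )


@pytest.fixture(scope="session")
def scenario3_study():
    """Scenario 3 (directional pleiotropy, 20/100 invalid), null effect, 500 reps."""
    return run_study(
        SimScenario.standard(3, theta=0.0, n_invalid=20),
        methods=("ivw_random", "conmix"),
        n_reps=500,
        base_seed=913,
        psi=1.0,
    )


@pytest.fixture(scope="session")
def scenario4_study():
    """Scenario 4 (pleiotropy via confounder, 20/100 invalid), null, 500 reps."""
    return run_study(
        SimScenario.standard(4, theta=0.0, n_invalid=20),
        methods=("ivw_random", "conmix"),
        n_reps=500,
        base_seed=914,
        psi=1.0,
    )


def two_cluster_summary(n_a: int = 12, n_b: int = 11, seed: int = 42) -> SummarySet:
    """Two groups of variants supporting causal effects ~0.67 and ~0.93.

    Exposure associations are unit with tight SEs so the ratio estimates sit
    directly at the outcome associations; sizes are chosen so the two
    likelihood peaks have comparable height.
    """
    rng = np.random.default_rng(seed)
    beta_y = np.concatenate(
        [0.67 + rng.normal(0.0, 0.005, n_a), 0.93 + rng.normal(0.0, 0.005, n_b)]
    )
    j = n_a + n_b
    return SummarySet(
        variant_ids=tuple(f"s{i}" for i in range(j)),
        beta_x=np.ones(j),
        se_x=np.full(j, 0.01),
        beta_y=beta_y,
        se_y=np.full(j, 0.02),
    )


def one_cluster_summary(j: int = 23, center: float = 0.7, seed: int = 43) -> SummarySet:
    """A single consensus group of variants around one causal effect."""
    rng = np.random.default_rng(seed)
    return SummarySet(
        variant_ids=tuple(f"s{i}" for i in range(j)),
        beta_x=np.ones(j),
        se_x=np.full(j, 0.01),
        beta_y=center + rng.normal(0.0, 0.005, j),
        se_y=np.full(j, 0.02),
    )


@pytest.fixture
def bimodal_data() -> SummarySet:
    return two_cluster_summary()


@pytest.fixture
def unimodal_data() -> SummarySet:
    return one_cluster_summary()


def random_summary_set(rng: np.random.Generator, j: int | None = None) -> SummarySet:
    """A generic random summary dataset (not tied to any scenario)."""
    if j is None:
        j = int(rng.integers(5, 40))
    beta_x = rng.uniform(0.05, 0.3, j) * rng.choice([-1.0, 1.0], j)
    se_x = rng.uniform(0.005, 0.02, j)
    se_y = rng.uniform(0.01, 0.05, j)
    beta_y = rng.normal(0.1 * beta_x, se_y)
    return SummarySet(
        variant_ids=tuple(f"r{i}" for i in range(j)),
        beta_x=beta_x,
        se_x=se_x,
        beta_y=beta_y,
        se_y=se_y,
    )
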