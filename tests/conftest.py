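import math

import numpy as np
import pytest

from ffvpsim.cohort import AgentRecord, AlphaSpec, CohortConfig, generate_cohort
from ffvpsim.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pattern_cohort(pattern, desert, n, alpha=0.005, start_id=0):
    """n identical agents with a fixed exposure pattern and desert history."""
    return [AgentRecord(start_id + i, pattern, desert, alpha) for i in range(n)]


def make_mixed_desert_cohort(pattern, n, seed, alpha=0.005):
    """Agents sharing one exposure pattern under the default desert mix
    (70.7% ever-desert, generator flip chain)."""
    n_nd = round(n * 0.293)
    cfg = CohortConfig(
        n_agents=n,
        cell_counts={
            (False, False): 0,
            (False, True): n_nd,
            (True, False): 0,
            (True, True): n - n_nd,
        },
        pattern_weights={pattern: 1.0},
        alpha_spec=AlphaSpec(value=alpha),
        seed=seed,
    )
    return generate_cohort(cfg)


def brute_force_poisson_quantile(u, lam):
    """Independent oracle: accumulate the Poisson pmf term by term."""
    k, cum = 0, 0.0
    while True:
        cum += math.exp(-lam) * lam**k / math.factorial(k)
        if cum >= u:
            return k
        k += 1


@pytest.fixture
def fast_cfg():
    """Short schedule for cheap smoke-level simulations."""
    return SimulationConfig(days_per_year=20, n_years=7, record_every=5, seed=7)
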