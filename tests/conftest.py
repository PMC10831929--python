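import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import boolpop as bp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_node_chain():
    """A -> B relay: A switches on, B copies A with its own rates."""
    net, params = bp.network_from_rules(
        {"A": ("TRUE", 0.9, 1.0), "B": ("A", 1.3, 0.4)}
    )
    cfg = bp.SimulationConfig(
        parameters=params, n_trajectories=20_000, t_max=10.0, window_dt=1.0, seed=11
    )
    return net, cfg


@pytest.fixture(scope="session")
def toy_model():
    """Small multiscale disease model with feedback, shared across tests."""
    return bp.make_toy_multiscale(n_cells=2, n_ligand_chains=1, feedback=True, seed=5)


def binom_3se(p, n):
    """Three binomial standard errors for a probability estimate."""
    return 3.0 * np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / n)


def binom_joint_3se(p, n, k):
    """Per-cell bound keeping a K-comparison family at the 3-sigma level.

    Bonferroni on the two-sided 3-sigma tail probability: each of the ``k``
    cells is tested at level 0.0027/k, so the whole-timecourse check has
    the same false-alarm rate as a single 3 SE comparison.
    """
    from scipy.stats import norm

    z = norm.isf(0.00135 / k)
    return z * np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / n)
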