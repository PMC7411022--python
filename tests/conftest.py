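"""Shared fixtures: rendered score pools and small reusable inputs.

Image rendering dominates test cost, so pools of scored synthetic cells are
session-scoped and shared across tests that only need score samples.
"""

import numpy as np
import pytest

from ephascore import synthetic


@pytest.fixture(scope="session")
def scattered_profile():
    return synthetic.CellSynthParams(aggregation=0.1)


@pytest.fixture(scope="session")
def aggregated_profile():
    return synthetic.CellSynthParams(aggregation=0.9)


@pytest.fixture(scope="session")
def scattered_pool(scattered_profile):
    """Raw entropy scores of 50 rendered scattered-phenotype cells."""
    return synthetic.simulate_score_pool(scattered_profile, 50, seed=101)


@pytest.fixture(scope="session")
def aggregated_pool(aggregated_profile):
    """Raw entropy scores of 50 rendered aggregated-phenotype cells."""
    return synthetic.simulate_score_pool(aggregated_profile, 50, seed=202)


@pytest.fixture(scope="session")
def baseline_scores():
    """An unsorted-population score distribution for colony/bootstrap tests."""
    rng = np.random.default_rng(7)
    return np.clip(rng.normal(0.5, 0.2, 400), 0.01, None)
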