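"""Shared fixtures: one moderately sized synthetic dataset reused across tests."""

import numpy as np
import pytest

from ancestra import admixture, synthgen


@pytest.fixture(scope="session")
def small_truth():
    """K=3, m=400, n=60: quick dataset with clear structure."""
    model = synthgen.simulate_frequency_tree(3, 400, drift=0.12, seed=7)
    samples = [(f"S{k + 1}", 20, np.eye(3)[k] * 5 + 0.2) for k in range(3)]
    G, truth = synthgen.simulate_admixed_genotypes(model, samples, missing_rate=0.01, seed=8)
    return G, truth


@pytest.fixture(scope="session")
def small_fit(small_truth):
    G, truth = small_truth
    return admixture.fit_admixture(G, 3, seed=9)


@pytest.fixture(scope="session")
def small_ensemble(small_truth, small_fit):
    G, _ = small_truth
    return admixture.bootstrap_fit(G, 3, B=30, seed=10, reference=small_fit)
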