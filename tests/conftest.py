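"""Shared fixtures: simulated datasets and fitted chains.

The scaled dataset (20,000 SNPs) realizes the reference six-phenotype
scenario; the three session-scoped fits on it (with annotations, without,
and with row-shuffled annotations) back the end-to-end recovery, graph and
robustness checks.  Seeds are fixed so every run of the suite sees the same
chains.
"""

import dataclasses

import numpy as np
import pytest

from pleiograph.sampler import MCMCConfig, run_mcmc
from pleiograph.simulate import default_scenario, simulate, shuffle_annotations

DATA_SEED = 20


@pytest.fixture(scope="session")
def scaled_scenario():
    return dataclasses.replace(default_scenario(), T=20_000)


@pytest.fixture(scope="session")
def scaled_truth(scaled_scenario):
    return simulate(scaled_scenario, seed=DATA_SEED)


@pytest.fixture(scope="session")
def annotated_fit(scaled_truth):
    cfg = MCMCConfig(n_iter=10_000, n_burnin=5_000, thin=5, seed=11)
    return run_mcmc(scaled_truth.y, scaled_truth.annotations, config=cfg)


@pytest.fixture(scope="session")
def plain_fit(scaled_truth):
    cfg = MCMCConfig(n_iter=6_000, n_burnin=3_000, thin=5, seed=12)
    return run_mcmc(scaled_truth.y, None, config=cfg)


@pytest.fixture(scope="session")
def shuffled_fit(scaled_truth):
    shuffled = shuffle_annotations(scaled_truth.annotations,
                                   np.random.default_rng(21))
    cfg = MCMCConfig(n_iter=6_000, n_burnin=3_000, thin=5, seed=13)
    return run_mcmc(scaled_truth.y, shuffled, config=cfg)


@pytest.fixture(scope="session")
def small_truth():
    sc = dataclasses.replace(default_scenario(), T=3_000, gibbs_iters=300)
    return simulate(sc, seed=5)


@pytest.fixture(scope="session")
def small_fit(small_truth):
    cfg = MCMCConfig(n_iter=1_500, n_burnin=750, thin=5, seed=6)
    return run_mcmc(small_truth.y, small_truth.annotations, config=cfg)
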