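"""Shared fixtures: small synthetic experiments and a cached model fit."""

import numpy as np
import pandas as pd
import pytest

import assemblage as A
from assemblage.model import (MCMCConfig, ModelSpec, fit_distributional_model,
                              prepare_model_data, simulate_similarity_records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced 4-regime experiment: 60 taxa, 5 sampling days, 2 replicates."""
    spec = A.DesignSpec(
        regimes=("UDH", "UDL", "DUH", "DUL"), replicates_per_regime=2,
        sampling_days=(2, 8, 14, 20, 28), inoculum_samples=1,
        reads_per_sample=A.ReadDepthModel(mean=20000, sd=5000, minimum=12000),
    )
    taxa = A.neutral_community(n_taxa=60, total_abundance=2e4, seed=5)
    schedules = A.default_schedules(k_low=2e4, k_high=1e5)
    table, metadata = A.simulate_experiment(spec, taxa, schedules, seed=5)
    return table, metadata


@pytest.fixture(scope="session")
def recovery_records():
    """Similarity records simulated from the distributional model itself with
    known slopes (beta_t = 0.01 on the mean, gamma_t = -0.05 on log sigma)."""
    return simulate_similarity_records(
        beta={"Intercept": 0.6, "centered_day": 0.01, "disturbance": 0.05,
              "centered_day:disturbance": -0.002},
        gamma={"Intercept": np.log(0.05), "centered_day": -0.05},
        tau=0.02, n_pairs=3, days=np.arange(2, 30, 2), seed=314,
    )


@pytest.fixture(scope="session")
def recovery_spec():
    return ModelSpec(
        mean_terms=("centered_day", "disturbance", "centered_day:disturbance"),
        sigma_terms=("centered_day",),
    )


@pytest.fixture(scope="session")
def default_fit(recovery_records, recovery_spec):
    """One fit at the full default MCMC settings (4 x 4000, 2000 warm-up)."""
    data = prepare_model_data(recovery_records, period=1, spec=recovery_spec)
    return fit_distributional_model(data, config=MCMCConfig(seed=9))


@pytest.fixture(scope="session")
def quick_config():
    return MCMCConfig(chains=2, iterations_per_chain=900, warmup=300, seed=17)
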