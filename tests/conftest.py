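"""Shared fixtures: small simulated datasets and full-scale pipeline runs."""

import numpy as np
import pandas as pd
import pytest

from dnet import PipelineConfig, SimulationConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def small_config():
    """A fast two-module dataset used by most unit tests."""
    return SimulationConfig(
        n_genes=200,
        n_timepoints=24,
        n_modules=2,
        module_sizes=[12, 12],
        activation_times=[5, 17],
        noise_sd=0.4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_runs(tmp_path_factory):
    """Full pipeline on the default planted-module config over 10 seeds.

    Session-scoped because both community recovery and temporal ordering are
    scored on the same runs.
    """
    root = tmp_path_factory.mktemp("runs")
    results = []
    for seed in range(10):
        cfg = PipelineConfig(
            outdir=root / f"seed{seed}",
            simulation=SimulationConfig(seed=seed),
            seed=seed,
        )
        results.append(run_pipeline(cfg))
    return results


def random_expression(rng, n_genes=30, n_timepoints=12, missing=0.0):
    """Random positive expression matrix, optionally with missing entries."""
    m = rng.gamma(shape=2.0, scale=5.0, size=(n_genes, n_timepoints))
    if missing:
        m[rng.random(m.shape) < missing] = np.nan
    return pd.DataFrame(
        m,
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"t{j}" for j in range(n_timepoints)],
    )
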