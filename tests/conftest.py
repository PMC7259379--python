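import numpy as np
import pytest

from omicreg.fitting import fit_all, make_split
from omicreg.io import RunConfig
from omicreg.simulate import SimulationConfig, simulate_dataset


def tiny_sim_config(**overrides) -> SimulationConfig:
    """Small three-phenotype scenario that fits in a couple of seconds."""
    defaults = dict(
        n_samples={"A": 60, "B": 45, "Normal": 40},
        m_cpg=100,
        m_tx=90,
        m_mirna=60,
        n_target_genes=3,
        k_planted=2,
        block_size=2,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def fast_run_config(**overrides) -> RunConfig:
    defaults = dict(cv_repeats=3, lambda_grid_size=20, seed=7, normal_phenotype="Normal")
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_world():
    """Dataset, ground truth, split and fitted models for unit tests."""
    sim = tiny_sim_config()
    dataset, truth = simulate_dataset(sim)
    config = fast_run_config()
    split = make_split(dataset, config)
    models = fit_all(dataset, split, config)
    return {
        "sim": sim,
        "dataset": dataset,
        "truth": truth,
        "config": config,
        "split": split,
        "models": models,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
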