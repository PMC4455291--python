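import numpy as np
import pytest

from glomnose.experiments import ExperimentConfig, make_benchmark
from glomnose.glomerular import init_network
from glomnose.sensor_sim import (
    ResponseMatrix,
    default_model,
    make_testing_schedule,
    make_training_schedule,
    simulate_responses,
)


@pytest.fixture(scope="session")
def small_benchmark():
    """Default benchmark at seed 0: 150 training + 706 testing samples."""
    cfg = ExperimentConfig(master_seed=0, n_trials=2)
    train, test = make_benchmark(cfg)
    return cfg, train, test


@pytest.fixture()
def random_network():
    return init_network(L=4, N=16, f_density=0.5, seed=42)


@pytest.fixture()
def tiny_responses():
    """Noise-free 40-sample response table on the default model."""
    model = default_model(replica_gain_sd=0, replica_selectivity_sd=0,
                          drift_step_sd=0, jump_sd=0, noise_sd=0)
    sched = make_training_schedule([8, 8, 8, 8, 8], seed=5)
    return simulate_responses(model, sched, seed=5)


def make_uniform_responses(n_samples: int, n_channels: int = 16, seed: int = 0,
                           lo: float = 0.0, hi: float = 1.0) -> ResponseMatrix:
    """Helper: i.i.d. uniform response table with dummy labels."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(lo, hi, size=(n_samples, n_channels))
    return ResponseMatrix(values, np.ones(n_samples, dtype=int),
                          np.zeros(n_samples, dtype=int),
                          np.repeat(np.arange(1, 5), n_channels // 4),
                          np.arange(n_samples))
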