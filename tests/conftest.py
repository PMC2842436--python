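import numpy as np
import pytest

from mixedclr import ExpressionDataset, TimeSeriesExperiment, generate_network, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_dataset():
    """Hand-sized 3-gene dataset: one time course plus WT/KO/KD blocks."""
    ts = TimeSeriesExperiment(
        times=np.array([0.0, 20.0, 40.0]),
        values=np.array(
            [
                [0.20, 0.50, 0.30],
                [0.40, 0.50, 0.25],
                [0.50, 0.50, 0.20],
            ]
        ),
    )
    return ExpressionDataset(
        genes=["G1", "G2", "G3"],
        time_series=[ts],
        wildtype=np.array([0.40, 0.50, 0.30]),
        knockout=np.array(
            [
                [0.00, 0.48, 0.10],
                [0.41, 0.00, 0.29],
                [0.39, 0.52, 0.00],
            ]
        ),
        knockdown=np.array(
            [
                [0.20, 0.49, 0.20],
                [0.40, 0.25, 0.30],
                [0.40, 0.50, 0.15],
            ]
        ),
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """A modest synthetic benchmark shared across tests (20 genes, low noise)."""
    network = generate_network(20, density=2.0, seed=11)
    dataset = simulate_dataset(network, noise_sd=0.01, n_ts=8, n_times=11, seed=12)
    return network, dataset, network.gold_standard()


@pytest.fixture(scope="session")
def noisefree_benchmark():
    network = generate_network(15, density=1.5, seed=21)
    dataset = simulate_dataset(network, noise_sd=0.0, n_ts=5, n_times=9, seed=22)
    return network, dataset, network.gold_standard()
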