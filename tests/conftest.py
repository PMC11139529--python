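import numpy as np
import pytest

from herbqc import chemometrics as cm
from herbqc import datasets, simulate
from herbqc.qams import SamplePrep


@pytest.fixture(scope="session")
def calibration_curves():
    return datasets.load_calibration_curves()


@pytest.fixture(scope="session")
def sample_prep():
    return datasets.load_sample_prep()


@pytest.fixture(scope="session")
def contents_table():
    return datasets.load_batch_contents()


@pytest.fixture
def default_sim_config():
    return simulate.default_config(seed=11, noise_cv=0.01)


def two_group_config(seed, separation_sd=3.0, n_informative=4, noise_cv=0.01):
    """14-batch config with two planted groups separated on selected analytes."""
    base = {"GA": 3.0, "TEGG": 4.5, "EA": 0.6, "PEGG": 2.4}
    sd = {"GA": 0.25, "TEGG": 0.45, "EA": 0.05, "PEGG": 0.15}
    shifted = dict(base)
    for name in ["GA", "PEGG", "TEGG", "EA"][:n_informative]:
        shifted[name] = base[name] + separation_sd * sd[name]
    return simulate.SimulationConfig(
        seed=seed,
        analytes=simulate.default_config().analytes,
        noise_cv=noise_cv,
        batches=14,
        group_means=[base, shifted],
        group_sd=sd,
        group_sizes=[7, 7],
        n_outliers=0,
    )


@pytest.fixture
def planted_matrix():
    """Autoscaled 14x4 matrix with two planted groups and the true labels."""
    config = two_group_config(seed=5)
    peaks, truth = simulate.gen_batches(config)
    wide = peaks.pivot(index="batch_id", columns="analyte", values="area")
    groups = truth.drop_duplicates("batch_id").set_index("batch_id")["group"]
    matrix = cm.DataMatrix.from_frame(wide)
    labels = np.array([groups[s] for s in matrix.sample_ids])
    return cm.autoscale(matrix), labels
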