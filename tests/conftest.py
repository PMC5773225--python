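import numpy as np
import pandas as pd
import pytest

from isocell import (
    LabelCalibration,
    LabelingExperiment,
    NaturalAbundance,
    calibrate,
)
from isocell.simulate import PopulationSpec, simulate_experiment


@pytest.fixture(scope="session")
def experiment():
    return LabelingExperiment()


@pytest.fixture(scope="session")
def natural():
    return NaturalAbundance()


@pytest.fixture(scope="session")
def calibration(experiment, natural):
    return calibrate(LabelCalibration(), experiment, natural)


@pytest.fixture(scope="session")
def small_sim():
    """A 250-cell synthetic experiment at default population parameters."""
    spec = PopulationSpec(n_cells=250)
    return spec, simulate_experiment(spec, seed=20260926)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_counts():
    """Hand-built two-field counts + filter tables with exactly known fractions."""
    counts = pd.DataFrame(
        {
            "replicate_id": ["R1"] * 4,
            "field_id": ["F1", "F1", "F2", "F2"],
            "roi_id": ["a", "b", "c", "d"],
            "c1H": [999736, 900000, 999736, 500000],
            "c2H": [264, 100000, 264, 500],
            "c12C": [990072, 900000, 990072, 900000],
            "c13C": [9928, 100000, 9928, 100000],
        }
    )
    filters = pd.DataFrame(
        {
            "field_id": ["F1", "F2", "ref"],
            "x13C_filter": [0.012, 0.010, 0.010],
            "x2H_filter": [0.0004, 0.0003, 0.0003],
            "is_reference": [0, 0, 1],
        }
    )
    return counts, filters
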