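import warnings

import numpy as np
import pandas as pd
import pytest

from vinoflux.datamodel import FermentationDataset
from vinoflux.synthetic import SimulationSpec, simulate_fermentation

warnings.filterwarnings("ignore", category=UserWarning)


def make_dataset(series: dict[str, tuple[list[float], list[float], str]],
                 strain: str = "S1", replicate: int = 1) -> FermentationDataset:
    """Build a one-strain dataset from {analyte: (times, values, unit)}."""
    rows = []
    for analyte, (times, values, unit) in series.items():
        for t, v in zip(times, values):
            rows.append((strain, replicate, t, analyte, v, unit))
    df = pd.DataFrame(
        rows, columns=["strain", "replicate", "time_h", "analyte", "value", "unit"]
    )
    return FermentationDataset(df)


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic fermentation (noisy), shared across tests."""
    return simulate_fermentation(SimulationSpec(seed=12345))


@pytest.fixture(scope="session")
def sim_noise_free():
    spec = SimulationSpec(
        seed=12345,
        noise_cv={k: 0.0 for k in ("biomass", "sugar", "nitrogen", "voc", "metabolite")},
    )
    return simulate_fermentation(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
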