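import numpy as np
import pytest

from thyromet.preprocess import preprocess
from thyromet.simulate import SimulationConfig, generate_spectra


@pytest.fixture(scope="session")
def extract_dataset():
    """Small extract-mode cohort with default planted effects (well-resolved
    signals, no lipid envelope) used across supervised-analysis tests."""
    cfg = SimulationConfig(group_sizes=(15, 8, 7), seed=11, tissue_mode="extract")
    spectra, truth = generate_spectra(cfg)
    table = preprocess(spectra)
    y = (table.groups != "healthy").astype(int)
    return table, y, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
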