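"""Shared fixtures: default geometry, noise model, shapes and populations."""

import numpy as np
import pytest

import itdcode as it


@pytest.fixture(scope="session")
def geom():
    return it.HeadGeometry()


@pytest.fixture(scope="session")
def model():
    return it.RateNoiseModel()


@pytest.fixture(scope="session")
def band_shape():
    """Band-average tuning shape used for landscape-style analyses."""
    return it.CyclicGaussianParams(baseline=10.0, amplitude=50.0, width=0.125,
                                   best_ipd=0.0)


@pytest.fixture(scope="session")
def band_freqs():
    return np.linspace(800.0, 1000.0, 5)


@pytest.fixture(scope="session")
def small_population():
    """20 virtual cells from the default generator conditions."""
    return it.generate_population(it.PopulationGeneratorConfig(n_cells=20, seed=5))


@pytest.fixture(scope="session")
def ridge_cell(band_shape):
    """A cell sitting on the high-MI constant-best-phase ridge."""
    return it.CellCharacteristics("ridge", bf=900.0, cp=0.2, cd=0.0,
                                  shape=band_shape)
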