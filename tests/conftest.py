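"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from adaptntcp import CohortConfig, generate_fraction_series, generate_phantom
from adaptntcp.pipeline import build_plans


def tiny_cohort_config(**overrides) -> CohortConfig:
    """A desk-scale cohort: 32x32x16 grid at 2 mm with a reduced larynx
    amplitude (organs shrink with the grid, drift amplitudes are in mm)."""
    kwargs = dict(
        n_patients=2,
        grid_shape=(32, 32, 16),
        n_fractions_range=(4, 5),
        larynx_amplitude_mm=2.0,
        random_seed=7,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_cohort_config()


@pytest.fixture(scope="session")
def tiny_patient(tiny_config):
    return generate_phantom(tiny_config, 0)


@pytest.fixture(scope="session")
def tiny_series(tiny_config, tiny_patient):
    phantom, structures = tiny_patient
    return generate_fraction_series(phantom, structures, tiny_config, 0)


@pytest.fixture(scope="session")
def tiny_plans(tiny_patient):
    """(plans dict, nominal influence, spots) on the tiny phantom."""
    phantom, structures = tiny_patient
    return build_plans(phantom, structures)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
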