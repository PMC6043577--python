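"""Shared fixtures: small seeded synthetic systems reused across tests."""

import numpy as np
import pytest

from nmrdyn.dispersion import DispersionDataset, r2eff_from_intensities
from nmrdyn.synthetic import (
    generate_dispersion_intensities,
    generate_two_state_system,
)

NU_SMALL = (66.7, 133.3, 200.0, 333.3, 600.0, 1000.0)


@pytest.fixture(scope="session")
def noiseless_truth():
    return generate_two_state_system(n_residues=6, noise_fraction=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_truth):
    table = generate_dispersion_intensities(noiseless_truth, NU_SMALL, seed=7)
    return DispersionDataset(r2eff_from_intensities(table))


@pytest.fixture(scope="session")
def small_noisy_dataset():
    truth = generate_two_state_system(n_residues=6, noise_fraction=0.03, seed=11)
    table = generate_dispersion_intensities(truth, NU_SMALL, seed=11)
    curves = r2eff_from_intensities(table, noise_sd=0.03 * 100.0)
    return truth, DispersionDataset(curves)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
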