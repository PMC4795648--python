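"""Shared fixtures.

Heavy objects (template banks, experiment results at the study's stimulus
counts) are session-scoped so the expensive S1/C1/C2 pipeline runs once.
"""

import numpy as np
import pytest

import holoface as hf


@pytest.fixture(scope="session")
def stim_config():
    return hf.StimulusConfig()


@pytest.fixture(scope="session")
def model_config():
    return hf.ModelConfig()


@pytest.fixture(scope="session")
def train_images():
    """Ten odd-numbered training identities, rendered."""
    return [hf.render(hf.generate_identity(2 * i + 1, 1)) for i in range(10)]


@pytest.fixture(scope="session")
def small_banks(train_images):
    """Compact three-size bank trio (10 images x 10 patches) for unit tests."""
    return hf.learn_bank(train_images, per_image=10, seed=2)


@pytest.fixture(scope="session")
def full_banks():
    """The study-sized banks: 20 patches from each of 50 training faces."""
    train = [hf.render(hf.generate_identity(2 * i + 1, 1)) for i in range(50)]
    return hf.learn_bank(train, per_image=20, seed=2)


@pytest.fixture(scope="session")
def test_faces20():
    """Twenty even-numbered (held-out) identities."""
    return [hf.generate_identity(2 * i, 1) for i in range(20)]


@pytest.fixture(scope="session")
def cfe_result(full_banks, test_faces20):
    banks = {sc: full_banks[sc] for sc in ("large", "small")}
    return hf.run_cfe(banks, test_faces20, seed=3, n_resamples=200, per_neuron=True)


@pytest.fixture(scope="session")
def fie_behavioral_result(full_banks, test_faces20):
    return hf.run_fie_behavioral(full_banks, test_faces20, seed=3, n_resamples=200)


@pytest.fixture(scope="session")
def fie_neural_result(full_banks, test_faces20):
    return hf.run_fie_neural(full_banks, test_faces20, band=None, seed=3)


@pytest.fixture(scope="session")
def wpe_result(full_banks):
    """Whole-part run at a reduced identity count (12 of the 20)."""
    faces = [hf.generate_identity(2 * i, 1) for i in range(12)]
    banks = {sc: full_banks[sc] for sc in ("large", "small")}
    return hf.run_wpe(banks, faces, seed=3, n_resamples=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
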