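import numpy as np
import pytest

import anisofit as af


@pytest.fixture(scope="session")
def toy_ensemble():
    """Three-conformer toy hydrocarbon (29 atoms), chain-A rotamers."""
    return af.make_toy_ensemble(3, seed=1)


@pytest.fixture(scope="session")
def uniform_pops(toy_ensemble):
    return af.PopulationSet.uniform(toy_ensemble.conformer_ids)


@pytest.fixture(scope="session")
def true_tensor():
    return af.make_true_tensor(5.0e-4, 0.3, orientation_seed=7)


@pytest.fixture(scope="session")
def clean_data(toy_ensemble, uniform_pops, true_tensor):
    """Noise-free synthetic dataset generated from the fixture truth."""
    truth = af.SyntheticTruth(
        true_tensor=true_tensor,
        true_populations=uniform_pops,
        noise=af.NoiseModel.noiseless(),
        seed=11,
    )
    return af.simulate_dataset(toy_ensemble, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
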