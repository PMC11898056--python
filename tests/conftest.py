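import numpy as np
import pytest

from thermograph.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def cls2_container(tmp_path_factory):
    """Small high-SNR binary classification container (quick tests)."""
    path = tmp_path_factory.mktemp("data") / "cls2.h5"
    spec = SyntheticSpec(
        n_proteins=40, length_range=(10, 20), F=16, task="classification",
        n_classes=2, effect_size=3.0, noise_sd=0.5, seed=11,
    )
    generate_dataset(spec, path)
    return path


@pytest.fixture(scope="session")
def reg_container(tmp_path_factory):
    """Small regression container spanning the five temperature bands."""
    path = tmp_path_factory.mktemp("data") / "reg.h5"
    spec = SyntheticSpec(
        n_proteins=40, length_range=(10, 20), F=16, task="regression",
        effect_size=3.0, noise_sd=0.5, seed=12,
    )
    generate_dataset(spec, path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
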