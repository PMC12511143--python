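import numpy as np
import pytest

from giwtnet.synth_data import SceneSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small materialised dataset (train 6 / val 2 / test 2) shared by
    metrics, training and CLI tests."""
    root = tmp_path_factory.mktemp("data") / "tiny"
    template = SceneSpec(image_size=(128, 128), n_objects=4)
    index = make_dataset(root, 6, 2, 2, template, seed=11)
    return root, index
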