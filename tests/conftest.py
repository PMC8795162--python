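import numpy as np
import pytest

from splitsite.models import ModelSpec, SplitModel
from splitsite.nn import LayerDef


def tiny_split_model(input_side: int = 8, filters: int = 2, hidden: int = 5) -> SplitModel:
    """A small conv split model for protocol-level tests (fits 8x8 inputs)."""
    spec = ModelSpec(
        task="classification",
        architecture="custom_cnn",
        epochs=5,
        global_batch_size=48,
        loss_name="binary_crossentropy",
        activation_name="sigmoid",
        input_shape=(input_side, input_side, 1),
        n_server_layers=4,
    )
    client = [
        LayerDef("conv2d", kernel_size=3, filters=filters),
        LayerDef("activation", activation="relu"),
        LayerDef("maxpool2d"),
    ]
    server = [
        LayerDef("flatten"),
        LayerDef("dense", units=hidden),
        LayerDef("activation", activation="relu"),
        LayerDef("dense", units=1),
        LayerDef("activation", activation="sigmoid"),
    ]
    return SplitModel(spec, client, server)


@pytest.fixture(scope="session")
def tiny_model() -> SplitModel:
    return tiny_split_model()


@pytest.fixture(scope="session")
def small_image_set():
    from splitsite.synthetic import make_image_set

    return make_image_set(120, 16, lesion_contrast=0.5, noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def cholesterol_set():
    from splitsite.synthetic import make_cholesterol_set

    return make_cholesterol_set(800, noise_sd=5.0, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
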