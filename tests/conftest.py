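import numpy as np
import pytest

from spikecam import ToyDetectorSpec, build_toy_detector


def tiny_two_layer_spec(weight_seed: int = 0) -> ToyDetectorSpec:
    """A 2-conv detector on 8x8 inputs, small enough for finite differences."""
    return ToyDetectorSpec(
        input_size=(8, 8),
        layer_specs=((3, 2, 3, 4), (3, 2, 4, 4)),
        detection_layers=(("small", 0), ("medium", 1)),
        weight_seed=weight_seed,
        y_layers=("small", "medium"),
    )


@pytest.fixture(scope="session")
def default_detector():
    return build_toy_detector(ToyDetectorSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
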