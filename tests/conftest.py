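import numpy as np
import pytest

from protodbt.protopnet.model import ProtoPNet, TrainSchedule
from protodbt.synthetic import generate_crop_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_crops():
    """Tiny balanced 2-class crop set shared across classifier tests."""
    return generate_crop_dataset(n_train=60, n_test=16, size=64, seed=7)


@pytest.fixture(scope="session")
def fitted_model(small_crops):
    """A briefly trained, projected model (shared; treat as read-only)."""
    Xtr, ytr, _, _ = small_crops
    model = ProtoPNet(in_size=64, seed=0)
    model.fit(Xtr, ytr, TrainSchedule(n_warmup_epochs=1, n_joint_epochs=2,
                                      n_lastlayer_epochs=2, seed=0))
    return model


@pytest.fixture
def gray_image(rng):
    return rng.integers(0, 256, size=(96, 80), dtype=np.uint8)
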