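import numpy as np
import pytest

from sswan.network import NetworkConfig, SSWAN
from sswan.phantoms import PhantomConfig, generate_dataset
from sswan.train import TrainConfig, train

# The fixed desk-scale overfit protocol: 16 noisy 64x64 two-class phantoms,
# a 2-block width-16 network, 200 epochs of Adam at 1e-3 on the joint
# Dice + reconstruction objective. Session-scoped so the trained models are
# shared between the functional tests that probe different aspects of the
# same run.

OVERFIT_EPOCHS = 200


@pytest.fixture(scope="session")
def overfit_phantoms():
    cfg = PhantomConfig(size=(64, 64), num_classes=2, noise_sigma=0.05, seed=0)
    return generate_dataset(16, cfg, base_seed=0)


def _run_overfit(samples, width):
    model = SSWAN(NetworkConfig(num_blocks=2, width=width, reduction=4,
                                num_classes=2, seed=0))
    history = train(model, samples, TrainConfig(epochs=OVERFIT_EPOCHS))
    return model, history


@pytest.fixture(scope="session")
def overfit_w16(overfit_phantoms):
    return _run_overfit(overfit_phantoms, width=16)


@pytest.fixture(scope="session")
def overfit_w8(overfit_phantoms):
    return _run_overfit(overfit_phantoms, width=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
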