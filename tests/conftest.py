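import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cxrtransfer import make_blob_task, preprocess_batch, synthetic
from cxrtransfer.synthetic import BLOB_INTENSITY_RANGE

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blob_net():
    """A fixture CNN trained on the disc-localization task, with a fresh
    held-out draw for evaluation. Trained once per session."""
    images, y, _ = make_blob_task(n=400, side=64, seed=0)
    X = preprocess_batch(images, side=64, intensity_range=BLOB_INTENSITY_RANGE)
    net = synthetic.build_fixture_cnn(1, seed=0, widths=(8, 16))
    net.fit(X, y, epochs=5, lr=3e-3, batch_size=16, seed=1)

    test_images, test_y, test_masks = make_blob_task(n=200, side=64, seed=123)
    TX = preprocess_batch(test_images, side=64,
                          intensity_range=BLOB_INTENSITY_RANGE)
    return {"net": net, "X": X, "y": y,
            "test_X": TX, "test_y": test_y, "test_masks": test_masks}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
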