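import numpy as np
import pytest

from neurointent.preproc import EpochSet
from neurointent.scenefeat import Detection, DetectionSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_epochs(rng):
    """20 trials (5 per class) x 4 channels x 128 samples of seeded noise."""
    data = rng.standard_normal((20, 4, 128))
    labels = np.repeat(np.arange(4), 5)
    return EpochSet(data, labels, ["C3", "Cz", "C4", "CP1"], fs=128.0)


def random_detection_set(rng, n=6, n_categories=80, size=(640.0, 480.0)):
    w, h = size
    dets = []
    for _ in range(n):
        bw, bh = rng.uniform(20, 200), rng.uniform(20, 200)
        x = rng.uniform(0, w - bw)
        y = rng.uniform(0, h - bh)
        dets.append(Detection(int(rng.integers(0, n_categories)),
                              (x, y, bw, bh), float(rng.uniform(0.3, 1.0))))
    return DetectionSet("img", size, dets)


@pytest.fixture
def detection_set(rng):
    return random_detection_set(rng)
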