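import numpy as np
import pytest

from ssveptag.containers import Recording
from ssveptag.design import ExperimentDesign
from ssveptag.montage import Montage, gsn128
from ssveptag.spectral import default_roi_set
from ssveptag.synth import (CategoryTruth, GroundTruthSpec, VisualTruth,
                            make_topography)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def montage():
    return gsn128()


@pytest.fixture(scope="session")
def roi_set():
    return default_roi_set()


@pytest.fixture(scope="session")
def mini_montage():
    """Eight channels on a ring: cheap stand-in geometry for generator tests
    that do not depend on the real net layout."""
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pos = np.column_stack([np.cos(ang), np.sin(ang)])
    return Montage([f"m{i}" for i in range(1, 9)], pos, n_neighbors=2)


def make_mini_spec(mini_montage, age_days=200.0, seed=0, **overrides):
    """GroundTruthSpec on the 8-channel ring; visual focus m1/m2, category
    focus m5/m6."""
    fields = dict(
        age_days=age_days,
        categories={
            "faces": CategoryTruth(1.0, (500.0, 900.0), (1.0, -1.0), amp_slope=0.9),
            "limbs": CategoryTruth(0.8, (500.0,), (-1.0,)),
            "corridors": CategoryTruth(0.8, (520.0,), (-1.0,)),
            "characters": CategoryTruth(0.7, (480.0,), (-1.0,)),
            "cars": CategoryTruth(0.6, (1000.0,), (1.0,)),
        },
        visual=VisualTruth(),
        visual_topography=make_topography(mini_montage, ["m1", "m2"], 0.4),
        category_topography=make_topography(mini_montage, ["m5", "m6"], 0.4),
        noise_scale=0.0,
        artifact_rate=0.0,
        rng_seed=seed,
    )
    fields.update(overrides)
    return GroundTruthSpec(**fields)


@pytest.fixture
def mini_spec(mini_montage):
    return make_mini_spec(mini_montage)


def sinusoid_recording(freq, amp=1.0, fs=500.0, duration=70.0, n_channels=4,
                       events=None):
    t = np.arange(int(duration * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_channels, 1))
    return Recording(data, fs, [f"c{i}" for i in range(n_channels)],
                     events or [], {})
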