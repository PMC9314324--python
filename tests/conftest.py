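import numpy as np
import pytest

from qrskit import synthesis
from qrskit.records_io import BeatClass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_sinus_config():
    """30 s, 200 Hz, 60 bpm, no ectopy, no noise."""
    return synthesis.SynthesisConfig(
        duration_s=30.0, fs=200.0, heart_rate_bpm=60.0, rhythm="sinus",
        pac_fraction=0.0, pvc_fraction=0.0, noise_level=0.0,
        artifact_burst_rate=0.0, seed=7,
    )


@pytest.fixture
def mixed_record():
    """45 s / 200 Hz record with all three beat classes and mild noise."""
    config = synthesis.SynthesisConfig(
        duration_s=45.0, fs=200.0, heart_rate_bpm=75.0,
        pac_fraction=0.15, pvc_fraction=0.15, noise_level=0.1,
        artifact_burst_rate=0.0, seed=99,
    )
    return synthesis.simulate_record(config)


def random_annotation_times(rng, n, min_gap_s, duration_s=30.0):
    """Random beat times at least min_gap_s apart inside [0, duration)."""
    times = np.sort(rng.uniform(0.5, duration_s - 0.5, size=n))
    keep = [times[0]] if n else []
    for t in times[1:]:
        if t - keep[-1] >= min_gap_s:
            keep.append(t)
    return np.array(keep)


def random_classes(rng, n):
    return [
        [BeatClass.N, BeatClass.PVC, BeatClass.PAC][i]
        for i in rng.integers(0, 3, size=n)
    ]
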