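import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ftcdlat as fl

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_table() -> fl.LITable:
    """Study-scale LI table: 31 left- and 43 right-handers from the default
    latent two-factor configuration."""
    return fl.generate_li_table(fl.default_study_config(seed=7))


@pytest.fixture(scope="session")
def clean_recording() -> fl.CBFVRecording:
    """Noise-free recording with injected LI = 2.0, no artifacts."""
    return fl.generate_recording(2.0, fl.RecordingConfig(seed=5, noise_sd=0.0))


@pytest.fixture(scope="session")
def clean_epochs(clean_recording) -> fl.EpochSet:
    return fl.preprocess_recording(clean_recording)


def make_epochs(
    left: np.ndarray,
    right: np.ndarray,
    fs: float = 25.0,
    t_start: float = -7.0,
    normalized: bool = True,
) -> fl.EpochSet:
    """Hand-built EpochSet for unit tests (values already on the requested
    scale; recording-wide stats derived from the supplied matrices)."""
    left = np.atleast_2d(np.asarray(left, float))
    right = np.atleast_2d(np.asarray(right, float))
    n, k = left.shape
    times = t_start + np.arange(k) / fs
    scale = "norm" if normalized else "raw"
    stats = {}
    for name, arr in (("left", left), ("right", right)):
        stats[f"{scale}_mean_{name}"] = float(arr.mean())
        stats[f"{scale}_sd_{name}"] = float(arr.std())
        if normalized:
            stats[f"raw_mean_{name}"] = float(arr.mean())
            stats[f"raw_sd_{name}"] = float(arr.std())
    return fl.EpochSet(
        times=times,
        fs=fs,
        left=left,
        right=right,
        onsets=np.arange(n) * 33.0 + 10.0,
        usable=np.ones(n, bool),
        reasons=[None] * n,
        channel_stats=stats,
        normalized=normalized,
    )


@pytest.fixture
def meta_10() -> pd.DataFrame:
    subjects = [f"P{i:02d}" for i in range(10)]
    return pd.DataFrame(
        {"group": ["left"] * 5 + ["right"] * 5, "site": ["sim"] * 10}, index=subjects
    )
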