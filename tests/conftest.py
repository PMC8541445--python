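import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oddballeeg import build_wavelets
from oddballeeg.preprocess import TrialSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 256.0


@pytest.fixture(scope="session")
def default_bank():
    return build_wavelets(FS)


def make_trialset(
    data: np.ndarray,
    fs: float = FS,
    pre_samples: int = 77,
    channel_labels=None,
) -> TrialSet:
    """Wrap a (trials, channels, time) array as a TrialSet with t=0 at
    sample index pre_samples."""
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_t = data.shape
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(n_ch))
    time_ms = (np.arange(n_t) - pre_samples) / fs * 1000.0
    return TrialSet(
        data=data,
        time_ms=time_ms,
        fs=fs,
        channel_labels=channel_labels,
        kept_mask=np.ones(n_tr, dtype=bool),
        rejection_reasons=[[] for _ in range(n_tr)],
    )


@pytest.fixture
def trialset_factory():
    return make_trialset
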