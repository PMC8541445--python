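"""Complex Morlet time-frequency decomposition and percent-change power.

Per channel and frequency the single-trial power is the squared magnitude
of the convolution with a unit-energy complex Morlet wavelet; the activity
A(f, t) is the average of that power over kept trials; the baseline R(f)
is the time-average of A over the pre-stimulus baseline window; and the
reported quantity is the percent change 100*(A - R)/R.  Values above 0 are
event-related synchronization (ERS), below 0 desynchronization (ERD).

The frequency grid runs 0.5..40 Hz in 0.75 Hz steps (53 frequencies) and
the number of wavelet cycles grows linearly from 2 at the low end to 10 at
40 Hz, trading temporal for spectral precision as frequency rises.
Convolution is done in the frequency domain with reflection padding of one
epoch length on each side, which keeps edge artifacts inside the padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .montage import BAND_ORDER, BANDS, band_of
from .preprocess import TrialSet

__all__ = [
    "WaveletBank",
    "TFDecomposition",
    "BandPowerMap",
    "PeakFeature",
    "build_wavelets",
    "tf_percent_change",
    "band_average",
    "extract_peak",
    "peak_features_all",
]


@dataclass
class WaveletBank:
    freqs: np.ndarray        # Hz, strictly increasing
    cycles: np.ndarray       # per frequency
    fs: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.cycles = np.asarray(self.cycles, dtype=np.float64)
        if self.freqs.size < 2:
            raise ValueError("frequency grid needs at least 2 frequencies")
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(np.diff(self.cycles) < -1e-12):
            raise ValueError("cycles must be non-decreasing in frequency")

    @property
    def n_freqs(self) -> int:
        return self.freqs.size

    def wavelet(self, k: int) -> np.ndarray:
        """Unit-energy complex Morlet for grid index k (time domain)."""
        f = self.freqs[k]
        sigma_t = self.cycles[k] / (2 * np.pi * f)
        half = int(round(3.0 * sigma_t * self.fs))
        t = np.arange(-half, half + 1) / self.fs
        w = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
        return w / np.sqrt(np.sum(np.abs(w) ** 2))


def build_wavelets(
    fs: float,
    f_min: float = 0.5,
    f_max: float = 40.0,
    step: float = 0.75,
    c_min: float = 2.0,
    c_max: float = 10.0,
) -> WaveletBank:
    """Build the wavelet bank: grid f_min + k*step up to f_max, cycles
    interpolated linearly from c_min at f_min to c_max at f_max."""
    if f_min >= f_max:
        raise ValueError("f_min must be below f_max")
    if step <= 0:
        raise ValueError("step must be positive")
    freqs = f_min + step * np.arange(int(np.floor((f_max - f_min) / step + 1e-9)) + 1)
    cycles = c_min + (c_max - c_min) * (freqs - f_min) / (f_max - f_min)
    return WaveletBank(freqs=freqs, cycles=cycles, fs=fs)


@dataclass
class TFDecomposition:
    """channels x frequencies x time percent-change power (unitless %)."""

    values: np.ndarray
    freqs: np.ndarray
    time_ms: np.ndarray
    channel_labels: tuple[str, ...]
    baseline_ms: tuple[float, float]

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)

    def channel(self, label: str) -> np.ndarray:
        """frequency x time map for one channel."""
        return self.values[self.channel_labels.index(label)]


@dataclass
class BandPowerMap:
    """band -> channels x time percent-change traces."""

    bands: dict[str, np.ndarray]
    time_ms: np.ndarray
    channel_labels: tuple[str, ...]
    band_defs: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)

    def trace(self, channel: str, band: str) -> np.ndarray:
        return self.bands[band][self.channel_labels.index(channel)]


@dataclass
class PeakFeature:
    channel: str
    band: str
    peak_power: float     # % change
    latency_ms: float


def tf_percent_change(
    trials: TrialSet,
    bank: WaveletBank,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    channels: tuple[str, ...] | None = None,
) -> TFDecomposition:
    """Decompose kept trials and normalize to baseline percent change.

    ``channels`` restricts the decomposition to a subset of labels (the
    full montage by default).
    """
    if trials.n_kept < 1:
        raise ValueError("no kept trials to decompose")
    base_sel = trials.time_window(*baseline_ms)
    if not base_sel.any():
        raise ValueError("baseline window lies outside the epoch")

    if channels is None:
        channels = trials.channel_labels
        data = trials.kept_data
    else:
        idx = [trials.channel_labels.index(c) for c in channels]
        data = trials.kept_data[:, idx, :]
    n_tr, n_ch, n_t = data.shape

    # reflection padding of one epoch length (n_t - 1 samples) per side
    pad = n_t - 1
    padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    n_sig = padded.shape[-1]

    wavelets = [bank.wavelet(k) for k in range(bank.n_freqs)]
    n_fft = sfft.next_fast_len(n_sig + max(w.size for w in wavelets) - 1)

    spec = sfft.fft(padded.reshape(n_tr * n_ch, n_sig).astype(np.float32),
                    n=n_fft, axis=-1)
    A = np.empty((n_ch, bank.n_freqs, n_t), dtype=np.float64)
    for k, w in enumerate(wavelets):
        wf = sfft.fft(w.astype(np.complex64), n=n_fft)
        conv = sfft.ifft(spec * wf, axis=-1)
        start = (w.size - 1) // 2 + pad   # 'same' alignment, drop padding
        seg = conv[:, start:start + n_t]
        power = (seg.real.astype(np.float64) ** 2
                 + seg.imag.astype(np.float64) ** 2)
        A[:, k, :] = power.reshape(n_tr, n_ch, n_t).mean(axis=0)

    R = A[:, :, base_sel].mean(axis=2)              # (n_ch, n_freqs)
    if np.any(R <= 0):
        raise ValueError("degenerate input: zero baseline power at some frequency")
    pct = (A - R[:, :, None]) / R[:, :, None] * 100.0
    return TFDecomposition(
        values=pct,
        freqs=bank.freqs.copy(),
        time_ms=trials.time_ms.copy(),
        channel_labels=channels,
        baseline_ms=baseline_ms,
    )


def band_average(
    tf: TFDecomposition, band_defs: dict[str, tuple[float, float]] | None = None
) -> BandPowerMap:
    """Unweighted mean of percent change over the grid frequencies of each band."""
    if band_defs is None:
        band_defs = BANDS
    bands: dict[str, np.ndarray] = {}
    for name in band_defs:
        if band_defs is BANDS:
            sel = np.array([band_of(f) == name for f in tf.freqs])
        else:
            lo, hi = band_defs[name]
            sel = (tf.freqs >= lo - 1e-9) & (tf.freqs <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"band {name!r} contains no grid frequency")
        bands[name] = tf.values[:, sel, :].mean(axis=1)
    return BandPowerMap(
        bands=bands,
        time_ms=tf.time_ms.copy(),
        channel_labels=tf.channel_labels,
        band_defs=dict(band_defs),
    )


def extract_peak(
    bandmap: BandPowerMap,
    channel: str,
    band: str,
    window_ms: tuple[float, float] = (200.0, 650.0),
) -> PeakFeature:
    """Maximum percent change of the band trace in the window and its latency.

    Ties take the earliest time point.
    """
    trace = bandmap.trace(channel, band)
    sel = (bandmap.time_ms >= window_ms[0] - 1e-9) & \
          (bandmap.time_ms <= window_ms[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"window {window_ms} ms lies outside the epoch")
    times = bandmap.time_ms[sel]
    values = trace[sel]
    i = int(np.argmax(values))
    return PeakFeature(channel=channel, band=band,
                       peak_power=float(values[i]), latency_ms=float(times[i]))


def peak_features_all(
    bandmap: BandPowerMap, window_ms: tuple[float, float] = (200.0, 650.0)
) -> list[PeakFeature]:
    """Peak features for every channel x band, in montage-then-band order."""
    out = []
    for ch in bandmap.channel_labels:
        for band in BAND_ORDER:
            if band in bandmap.bands:
                out.append(extract_peak(bandmap, ch, band, window_ms))
    return out
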