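"""Epoching, DC baseline correction and automatic trial rejection.

Continuous recordings are cut into epochs of -300..+700 ms around each
*target* stimulus (the oddball events that elicit a P300).  Each epoch is
baseline-corrected by subtracting the mean of the 200 ms pre-stimulus
window, and then screened by three per-channel rules: post-stimulus
peak-to-peak amplitude, post-stimulus standard deviation, and a
noise-to-signal ratio (NSR).  A trial is dropped if any rule fires on any
channel.

NSR is defined here as SD(baseline window) / SD(post-stimulus window): a
high value means the evoked activity does not rise above the pre-stimulus
background.  The printed direction of the SD rule in the source protocol
("< 50" rejects) would discard clean low-amplitude trials, so the default
is the physically sensible direction (reject when post-stimulus SD exceeds
the threshold); the literal direction is retained as ``sd_mode="literal_below"``
for fidelity experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import check_montage

__all__ = [
    "EEGSession",
    "TrialSet",
    "RejectionConfig",
    "extract_trials",
    "baseline_correct",
    "reject_trials",
]


@dataclass
class EEGSession:
    """A continuous multichannel EEG recording with stimulus markers.

    signal is channels x samples in microvolts; events are
    (sample_index, is_target) pairs.
    """

    subject_id: str
    group_label: str
    fs: float
    channel_labels: tuple[str, ...]
    signal: np.ndarray
    events: list[tuple[int, bool]]
    session_label: str | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        check_montage(self.channel_labels)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"signal must be (n_channels={len(self.channel_labels)}, n_samples), "
                f"got {self.signal.shape}"
            )
        n = self.signal.shape[1]
        for idx, _ in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample {idx} outside recording of {n} samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def target_events(self) -> list[int]:
        return [idx for idx, is_target in self.events if is_target]


@dataclass
class TrialSet:
    """Epoched trials (trials x channels x time, microvolts).

    ``data`` holds one row per original target event, including rejected
    ones; ``kept_mask`` marks survivors and ``rejection_reasons`` records,
    per original trial, which rules fired (empty list = kept).
    """

    data: np.ndarray
    time_ms: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    kept_mask: np.ndarray
    rejection_reasons: list[list[str]]
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def kept_data(self) -> np.ndarray:
        return self.data[self.kept_mask]

    def time_window(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Boolean mask over the time axis for lo_ms <= t <= hi_ms."""
        return (self.time_ms >= lo_ms - 1e-9) & (self.time_ms <= hi_ms + 1e-9)


@dataclass
class RejectionConfig:
    """Thresholds of the three rejection rules (microvolts / unitless).

    ``np.inf`` disables the peak-to-peak and NSR rules; sd_mode="above"
    with an infinite threshold disables the SD rule.
    """

    p2p_threshold: float = 200.0
    sd_threshold: float = 50.0
    sd_mode: str = "above"  # or "literal_below"
    nsr_threshold: float = 0.7
    baseline_ms: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self) -> None:
        if self.p2p_threshold <= 0 or self.sd_threshold <= 0 or self.nsr_threshold <= 0:
            raise ValueError("rejection thresholds must be positive")
        if self.sd_mode not in ("above", "literal_below"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert a duration in ms to samples, rounding half away from zero."""
    x = ms * fs / 1000.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def extract_trials(
    session: EEGSession, pre_ms: float = 300.0, post_ms: float = 700.0
) -> TrialSet:
    """Epoch the session around every target event.

    The epoch spans ``round(pre_ms*fs/1000)`` samples before the stimulus
    to ``round(post_ms*fs/1000)`` samples after it, endpoints inclusive
    (257 samples at 256 Hz for the default window).  Only target events
    are epoched.  Events too close to a recording edge yield an all-zero
    row that is flagged rejected with reason ``"edge"``.
    """
    n_pre = ms_to_samples(pre_ms, session.fs)
    n_post = ms_to_samples(post_ms, session.fs)
    n_time = n_pre + n_post + 1
    targets = session.target_events()
    n_ch = len(session.channel_labels)

    data = np.zeros((len(targets), n_ch, n_time), dtype=np.float64)
    kept = np.ones(len(targets), dtype=bool)
    reasons: list[list[str]] = [[] for _ in targets]
    for i, idx in enumerate(targets):
        if idx - n_pre < 0 or idx + n_post >= session.n_samples:
            kept[i] = False
            reasons[i].append("edge")
            continue
        data[i] = session.signal[:, idx - n_pre : idx + n_post + 1]

    time_ms = (np.arange(-n_pre, n_post + 1) / session.fs) * 1000.0
    return TrialSet(
        data=data,
        time_ms=time_ms,
        fs=session.fs,
        channel_labels=session.channel_labels,
        kept_mask=kept,
        rejection_reasons=reasons,
        subject_id=session.subject_id,
        group_label=session.group_label,
    )


def baseline_correct(
    trials: TrialSet, baseline_ms: tuple[float, float] = (-200.0, 0.0)
) -> TrialSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    sel = trials.time_window(*baseline_ms)
    if not sel.any():
        raise ValueError(f"baseline window {baseline_ms} ms is empty")
    mean = trials.data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(trials, data=trials.data - mean,
                   rejection_reasons=[list(r) for r in trials.rejection_reasons])


def reject_trials(trials: TrialSet, cfg: RejectionConfig | None = None) -> TrialSet:
    """Apply the three rejection rules; any rule on any channel rejects.

    Rules are evaluated on the post-stimulus window (t >= 0):
    (a) peak-to-peak > p2p_threshold;
    (b) SD above threshold (default) or below it (literal mode);
    (c) NSR = SD(baseline)/SD(post-stimulus) > nsr_threshold.
    Kept trials are returned bit-identical; the mask and reasons are updated.
    """
    if cfg is None:
        cfg = RejectionConfig()
    post = trials.time_ms >= -1e-9
    if not post.any():
        raise ValueError("post-stimulus window is empty")
    base = trials.time_window(*cfg.baseline_ms)

    seg = trials.data[:, :, post]
    p2p = seg.max(axis=2) - seg.min(axis=2)          # (trials, channels)
    sd_post = seg.std(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        nsr = np.where(sd_post > 0,
                       trials.data[:, :, base].std(axis=2) / sd_post, np.inf)

    fire_p2p = (p2p > cfg.p2p_threshold).any(axis=1)
    if cfg.sd_mode == "above":
        fire_sd = (sd_post > cfg.sd_threshold).any(axis=1)
    else:
        fire_sd = (sd_post < cfg.sd_threshold).any(axis=1)
    fire_nsr = (nsr > cfg.nsr_threshold).any(axis=1)

    kept = trials.kept_mask.copy()
    reasons = [list(r) for r in trials.rejection_reasons]
    for i in range(trials.n_trials):
        if not trials.kept_mask[i]:
            continue
        if fire_p2p[i]:
            reasons[i].append("p2p")
        if fire_sd[i]:
            reasons[i].append("sd")
        if fire_nsr[i]:
            reasons[i].append("nsr")
        if reasons[i]:
            kept[i] = False
    return replace(trials, data=trials.data.copy(), kept_mask=kept,
                   rejection_reasons=reasons)
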