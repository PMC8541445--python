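"""Synthetic P300 oddball EEG cohorts with controllable group effects.

Each session is a continuous 16-channel recording at 256 Hz containing
``n_target_trials`` target stimuli (plus non-target markers for
bookkeeping).  The signal is a sum of

* 1/f background noise (frequency-domain amplitude shaping of white noise,
  flat below 0.5 Hz so baselines do not drift),
* ongoing band-limited oscillations at the four band carriers
  (1.5 / 6 / 10 / 20 Hz) whose phase is redrawn every inter-stimulus
  segment.  Channel pairs designated in ``coupling`` share a common
  oscillator phase plus independent von Mises jitter with concentration
  kappa, which gives the closed-form expected inter-site phase clustering
  ISPC = I1(kappa)/I0(kappa) used by the parameter-recovery tests,
* one Gabor atom per band after every target stimulus (the evoked
  response; the Beta atom stands in for the P300-band peak the classifier
  uses).  Gabor carrier phase is randomized per channel and trial so the
  evoked response does not masquerade as phase coupling,
* optional single-sample +/-250 uV artifact spikes on random trials,
  which deterministically trigger the peak-to-peak rejection rule.

The "als-like" group applies three effect directions observed in ALS
patients relative to controls: reduced Beta evoked power
(``beta_power_factor_als``), delayed Delta/Alpha evoked latency
(``latency_shift_als_ms``), and reduced Alpha-band coupling on the
designated PO7<->central pairs (``coupling_kappa_als_delta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0, i1

from .montage import BAND_CARRIER_HZ, BAND_ORDER, CHANNELS
from .preprocess import EEGSession, ms_to_samples

__all__ = ["SynthConfig", "GroundTruth", "generate_session", "generate_cohort",
           "expected_ispc"]

GROUP_CONTROL = "control"
GROUP_ALS = "als-like"

#: Alpha-band hub-partner pairs carrying the connectivity effect: PO7
#: against the electrodes above the motor cortex.
DEFAULT_COUPLED_PAIRS: tuple[tuple[str, str], ...] = (
    ("PO7", "CZ"), ("PO7", "C1"), ("PO7", "C2"),
    ("PO7", "C3"), ("PO7", "C4"), ("PO7", "CP4"),
)


def _default_coupling() -> dict[str, dict[tuple[str, str], float]]:
    return {"alpha": {pair: 4.0 for pair in DEFAULT_COUPLED_PAIRS}}


def expected_ispc(kappa: float) -> float:
    """Expected ISPC of a pair with von Mises phase jitter of concentration kappa."""
    if np.isinf(kappa):
        return 1.0
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return float(i1(kappa) / i0(kappa))


@dataclass
class SynthConfig:
    """Generator parameters. Defaults emulate the study cohort conditions
    (12 ALS-like vs 16 control subjects, 264 target trials each, 256 Hz,
    16-channel montage)."""

    n_control: int = 16
    n_als_like: int = 12
    n_target_trials: int = 264
    fs: float = 256.0
    channels: tuple[str, ...] = CHANNELS
    # background
    noise_exponent: float = 1.0      # 1/f^a amplitude slope (power ~ f^-a)
    noise_scale: float = 1.0         # uV SD per channel
    osc_amp: dict[str, float] = field(
        default_factory=lambda: {"delta": 1.5, "theta": 1.5,
                                 "alpha": 4.5, "beta": 1.5})
    # evoked response (Gabor atoms), per band
    erp_amp: dict[str, float] = field(
        default_factory=lambda: {"delta": 24.0, "theta": 4.0,
                                 "alpha": 2.2, "beta": 7.0})
    erp_latency_ms: dict[str, float] = field(
        default_factory=lambda: {"delta": 400.0, "theta": 380.0,
                                 "alpha": 430.0, "beta": 450.0})
    erp_width_ms: dict[str, float] = field(
        default_factory=lambda: {"delta": 180.0, "theta": 120.0,
                                 "alpha": 100.0, "beta": 80.0})
    # group effects
    beta_power_factor_als: float = 0.5
    latency_shift_als_ms: float = 60.0
    coupling: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=_default_coupling)
    coupling_kappa_als_delta: float = 3.0
    # artifacts
    artifact_trial_rate: float = 0.05
    artifact_amp_uv: float = 250.0
    # between-subject variability
    subject_amp_sigma: float = 0.15      # lognormal sigma on evoked amplitude
    subject_latency_sd_ms: float = 15.0  # normal jitter on evoked latency
    # timing
    isi_s: float = 1.25
    stim_offset_s: float = 0.35
    lead_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_target_trials < 1:
            raise ValueError("n_target_trials must be >= 1")
        if not 0.0 <= self.artifact_trial_rate < 1.0:
            raise ValueError("artifact_trial_rate must be in [0, 1)")
        if self.isi_s < 1.2:
            raise ValueError("inter-stimulus interval must be >= 1.2 s "
                             "so epochs cannot overlap")
        for band, pairs in self.coupling.items():
            for pair, kappa in pairs.items():
                if not np.isinf(kappa) and kappa < 0:
                    raise ValueError(f"coupling kappa for {band}:{pair} "
                                     "must be non-negative")
        self.channels = tuple(self.channels)


@dataclass
class GroundTruth:
    """Injected per-subject effect values, sufficient to compute the
    expected value of every downstream feature the effects touch."""

    subject_id: str
    group_label: str
    beta_power_multiplier: float
    erp_latency_ms: dict[str, float]          # actual per-subject latencies
    erp_amp_scale: float                      # subject-level amplitude factor
    pair_kappa: dict[tuple[str, str, str], float]  # (band, hub, partner) -> kappa

    def expected_pair_ispc(self, band: str, ch_x: str, ch_y: str) -> float:
        """Expected ISPC for a designated pair in a band (Bessel ratio)."""
        for key in ((band, ch_x, ch_y), (band, ch_y, ch_x)):
            if key in self.pair_kappa:
                return expected_ispc(self.pair_kappa[key])
        raise KeyError(f"no injected coupling for {band}:{ch_x}-{ch_y}")


def _one_over_f_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                      fs: float, exponent: float, scale: float) -> np.ndarray:
    if scale == 0.0:
        return np.zeros((n_ch, n_samp))
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    # flat below 0.5 Hz: EEG is AC-coupled, unbounded 1/f drift is unphysical
    shaped = np.maximum(freqs, 0.5) ** (-exponent / 2.0)
    shaped[0] = 0.0
    spec *= shaped
    noise = np.fft.irfft(spec, n=n_samp, axis=1)
    sd = noise.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd * scale


def _segment_taper(seg_len: int, ramp: int) -> np.ndarray:
    taper = np.ones(seg_len)
    if ramp > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        taper[:ramp] = edge
        taper[-ramp:] = edge[::-1]
    return taper


def generate_session(
    config: SynthConfig, subject_id: str, group_label: str, seed: int
) -> tuple[EEGSession, GroundTruth]:
    """Generate one continuous session plus its injected ground truth."""
    if group_label not in (GROUP_CONTROL, GROUP_ALS):
        raise ValueError(f"group_label must be {GROUP_CONTROL!r} or "
                         f"{GROUP_ALS!r}, got {group_label!r}")
    rng = np.random.default_rng(seed)
    fs = config.fs
    n_ch = len(config.channels)
    ch_index = {c: i for i, c in enumerate(config.channels)}
    n_seg = config.n_target_trials
    seg_len = ms_to_samples(config.isi_s * 1000.0, fs)
    lead = ms_to_samples(config.lead_s * 1000.0, fs)
    stim_off = ms_to_samples(config.stim_offset_s * 1000.0, fs)
    n_samp = 2 * lead + n_seg * seg_len

    signal = _one_over_f_noise(rng, n_ch, n_samp, fs,
                               config.noise_exponent, config.noise_scale)

    # ---- subject-level effect values ------------------------------------
    amp_scale = float(np.exp(rng.normal(0.0, config.subject_amp_sigma)))
    is_als = group_label == GROUP_ALS
    beta_mult = config.beta_power_factor_als if is_als else 1.0
    latencies: dict[str, float] = {}
    for band in BAND_ORDER:
        lat = config.erp_latency_ms[band] + rng.normal(
            0.0, config.subject_latency_sd_ms)
        if is_als and band in ("delta", "alpha"):
            lat += config.latency_shift_als_ms
        latencies[band] = float(lat)
    pair_kappa: dict[tuple[str, str, str], float] = {}
    for band, pairs in config.coupling.items():
        for (hub, partner), kappa in pairs.items():
            k = kappa
            if is_als:
                k = max(0.0, k - config.coupling_kappa_als_delta) \
                    if not np.isinf(k) else k
            pair_kappa[(band, hub, partner)] = float(k)

    # ---- ongoing band oscillations, phase redrawn each segment ----------
    taper = _segment_taper(seg_len, ramp=ms_to_samples(45.0, fs))
    tau = np.arange(seg_len) / fs
    seg_starts = lead + np.arange(n_seg) * seg_len
    for band in BAND_ORDER:
        amp = config.osc_amp.get(band, 0.0)
        if amp == 0.0:
            continue
        f_c = BAND_CARRIER_HZ[band]
        phases = rng.uniform(0.0, 2 * np.pi, size=(n_seg, n_ch))
        for (b, hub, partner), kappa in pair_kappa.items():
            if b != band:
                continue
            jitter = (np.zeros(n_seg) if np.isinf(kappa)
                      else rng.vonmises(0.0, kappa, size=n_seg))
            phases[:, ch_index[partner]] = phases[:, ch_index[hub]] + jitter
        # (n_seg, n_ch, seg_len)
        carrier = amp * np.cos(2 * np.pi * f_c * tau[None, None, :]
                               + phases[:, :, None]) * taper[None, None, :]
        for i, s0 in enumerate(seg_starts):
            signal[:, s0:s0 + seg_len] += carrier[i]

    # ---- evoked Gabor atoms after each target stimulus ------------------
    stim_samples = seg_starts + stim_off
    for band in BAND_ORDER:
        base_amp = config.erp_amp.get(band, 0.0)
        if base_amp == 0.0:
            continue
        if band == "beta":
            base_amp = base_amp * np.sqrt(beta_mult)
        f_c = BAND_CARRIER_HZ[band]
        sigma = config.erp_width_ms[band] / 1000.0  # s
        half = int(round(3.5 * sigma * fs))
        t_rel = np.arange(-half, half + 1) / fs
        envelope = np.exp(-(t_rel ** 2) / (2 * sigma ** 2))
        center_off = ms_to_samples(latencies[band], fs)
        trial_jit = rng.uniform(0.85, 1.15, size=n_seg)
        phase = rng.uniform(0.0, 2 * np.pi, size=(n_seg, n_ch))
        for i, stim in enumerate(stim_samples):
            c0 = stim + center_off
            lo, hi = c0 - half, c0 + half + 1
            if lo < 0 or hi > n_samp:
                continue
            atom = (base_amp * amp_scale * trial_jit[i]) * envelope[None, :] \
                * np.cos(2 * np.pi * f_c * t_rel[None, :] + phase[i][:, None])
            signal[:, lo:hi] += atom

    # ---- artifact trials -------------------------------------------------
    post_len = ms_to_samples(700.0, fs)
    for i, stim in enumerate(stim_samples):
        if rng.uniform() < config.artifact_trial_rate:
            ch = rng.integers(0, n_ch)
            offset = rng.integers(1, post_len + 1)
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            signal[ch, stim + offset] += sign * config.artifact_amp_uv

    # ---- events: targets plus non-target bookkeeping markers ------------
    nontarget_off = ms_to_samples(1100.0, fs)
    events: list[tuple[int, bool]] = []
    for s0, stim in zip(seg_starts, stim_samples):
        events.append((int(stim), True))
        events.append((int(s0 + nontarget_off), False))
    events.sort()

    session = EEGSession(
        subject_id=subject_id,
        group_label=group_label,
        fs=fs,
        channel_labels=config.channels,
        signal=signal,
        events=events,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        group_label=group_label,
        beta_power_multiplier=beta_mult,
        erp_latency_ms=latencies,
        erp_amp_scale=amp_scale,
        pair_kappa=pair_kappa,
    )
    return session, truth


def subject_seeds(config: SynthConfig) -> list[int]:
    """Reproducible, distinct per-subject seeds derived from config.seed."""
    n = config.n_control + config.n_als_like
    ss = np.random.SeedSequence(config.seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n, dtype=np.uint32)]


def generate_cohort(
    config: SynthConfig,
) -> list[tuple[EEGSession, GroundTruth]]:
    """Generate the full two-group cohort (controls first, then als-like)."""
    if config.n_control < 1 or config.n_als_like < 1:
        raise ValueError("need at least one subject per group")
    seeds = subject_seeds(config)
    out: list[tuple[EEGSession, GroundTruth]] = []
    k = 0
    for i in range(config.n_control):
        out.append(generate_session(config, f"ctrl{i + 1:02d}",
                                    GROUP_CONTROL, seeds[k]))
        k += 1
    for i in range(config.n_als_like):
        out.append(generate_session(config, f"als{i + 1:02d}",
                                    GROUP_ALS, seeds[k]))
        k += 1
    return out
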