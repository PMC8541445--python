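"""Wavelet bank construction, percent-change power, band averaging and
peak extraction."""

import numpy as np
import pytest

from oddballeeg import band_average, build_wavelets, extract_peak, \
    tf_percent_change
from oddballeeg.montage import BAND_ORDER, band_of
from oddballeeg.tfpower import BandPowerMap, TFDecomposition

from conftest import FS, make_trialset


def sinusoid_trials(freq, n_trials=12, n_ch=1, amp_post=None, n_pre=77,
                    n_post=179, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(-n_pre, n_post + 1) / FS
    data = []
    for _ in range(n_trials):
        x = np.cos(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        if amp_post is not None:
            x = np.where(t >= 0, amp_post, 1.0) * x
        data.append(np.tile(x, (n_ch, 1)))
    return make_trialset(np.array(data), pre_samples=n_pre)


class TestWaveletBank:
    def test_default_grid_has_53_frequencies(self, default_bank):
        assert default_bank.n_freqs == 53
        assert default_bank.freqs[0] == 0.5
        assert default_bank.freqs[-1] == pytest.approx(39.5)

    def test_cycles_interpolation_endpoints(self, default_bank):
        assert default_bank.cycles[0] == 2.0
        assert default_bank.cycles[-1] <= 10.0
        assert np.all(np.diff(default_bank.cycles) > 0)

    def test_all_wavelets_unit_energy(self, default_bank):
        for k in range(default_bank.n_freqs):
            w = default_bank.wavelet(k)
            assert np.sum(np.abs(w) ** 2) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            build_wavelets(FS, f_min=10, f_max=5)
        with pytest.raises(ValueError):
            build_wavelets(FS, step=-1)
        with pytest.raises(ValueError):
            build_wavelets(FS, f_min=1, f_max=1.5, step=10)  # < 2 freqs

    def test_band_bins_exhaustive_below_30(self, default_bank):
        counts = {b: 0 for b in BAND_ORDER}
        unassigned = 0
        for f in default_bank.freqs:
            b = band_of(f)
            if b is None:
                unassigned += 1
                assert f > 30.0
            else:
                counts[b] += 1
        assert counts == {"delta": 4, "theta": 7, "alpha": 7, "beta": 22}
        assert unassigned == 13


class TestPercentChange:
    def test_stationary_signal_near_zero(self, default_bank):
        ts = sinusoid_trials(10.0)
        tf = tf_percent_change(ts, default_bank)
        mid = (tf.time_ms >= -100) & (tf.time_ms <= 500)
        for f in (9.5, 10.25):
            k = int(np.argmin(np.abs(tf.freqs - f)))
            assert np.max(np.abs(tf.values[0, k, mid])) < 5.0

    def test_amplitude_doubling_recovers_power_ratio(self, default_bank):
        """A 4:1 post/pre power ratio yields +300% when the baseline
        window is clear of the wavelet's temporal support."""
        ts = sinusoid_trials(20.0, amp_post=2.0, n_pre=256)
        tf = tf_percent_change(ts, default_bank, baseline_ms=(-900.0, -400.0))
        k = int(np.argmin(np.abs(tf.freqs - 20.0)))
        sel = (tf.time_ms >= 300) & (tf.time_ms <= 500)
        assert tf.values[0, k, sel].mean() == pytest.approx(300.0, abs=30.0)

    def test_default_baseline_contamination_documented(self, default_bank):
        """With the default [-200, 0] ms baseline abutting the step, the
        wavelet support back-smears post power into R and the measured
        change drops well below the ideal +300%."""
        ts = sinusoid_trials(20.0, amp_post=2.0)
        tf = tf_percent_change(ts, default_bank)
        k = int(np.argmin(np.abs(tf.freqs - 20.0)))
        sel = (tf.time_ms >= 300) & (tf.time_ms <= 500)
        val = tf.values[0, k, sel].mean()
        assert 150.0 < val < 280.0

    def test_zero_signal_raises(self, default_bank):
        ts = make_trialset(np.zeros((3, 1, 257)))
        with pytest.raises(ValueError, match="degenerate"):
            tf_percent_change(ts, default_bank)

    def test_scaling_invariance(self, default_bank):
        ts = sinusoid_trials(10.0, n_trials=4, seed=2)
        tf1 = tf_percent_change(ts, default_bank)
        scaled = make_trialset(ts.data * 3.7)
        tf2 = tf_percent_change(scaled, default_bank)
        # single-precision convolution internals: allow small wiggle
        assert np.allclose(tf1.values, tf2.values, rtol=1e-2, atol=1.0)

    def test_values_bounded_below(self, default_bank):
        ts = sinusoid_trials(6.0, n_trials=4, seed=3)
        tf = tf_percent_change(ts, default_bank)
        assert tf.values.min() >= -100.0


class TestBandAverage:
    def _tf(self, values, freqs, n_t=257):
        return TFDecomposition(
            values=values, freqs=np.asarray(freqs),
            time_ms=(np.arange(n_t) - 77) / FS * 1000.0,
            channel_labels=("CZ",), baseline_ms=(-200.0, 0.0))

    def test_constant_map_preserved(self, default_bank):
        tf = self._tf(np.full((1, 53, 257), 50.0), default_bank.freqs)
        bm = band_average(tf)
        for band in BAND_ORDER:
            assert np.allclose(bm.trace("CZ", band), 50.0)

    def test_two_frequency_band_mean(self):
        values = np.zeros((1, 2, 257))
        values[0, 0] = 10.0
        values[0, 1] = 30.0
        tf = self._tf(values, [20.0, 21.0])
        bm = band_average(tf, band_defs={"custom": (19.0, 22.0)})
        assert np.allclose(bm.trace("CZ", "custom"), 20.0)

    def test_energy_at_20hz_bin_lands_in_beta_only(self, default_bank):
        """A map with percent change only at the 20 Hz bin shows up in the
        Beta trace (diluted by the band width) and nowhere else."""
        values = np.zeros((1, 53, 257))
        k = int(np.argmin(np.abs(default_bank.freqs - 20.0)))
        values[0, k, :] = 110.0
        tf = self._tf(values, default_bank.freqs)
        bm = band_average(tf)
        assert np.allclose(bm.trace("CZ", "beta"), 110.0 / 22)
        for other in ("delta", "theta", "alpha"):
            assert np.allclose(bm.trace("CZ", other), 0.0)

    def test_empty_band_errors(self):
        tf = self._tf(np.zeros((1, 2, 257)), [20.0, 21.0])
        with pytest.raises(ValueError, match="no grid frequency"):
            band_average(tf, band_defs={"empty": (1.0, 2.0)})


class TestExtractPeak:
    def _bandmap(self, trace):
        n_t = trace.size
        return BandPowerMap(
            bands={"beta": trace[None, :]},
            time_ms=(np.arange(n_t) - 77) / FS * 1000.0,
            channel_labels=("CZ",), band_defs={"beta": (13.5, 30.0)})

    def test_gaussian_bump_latency(self):
        t = (np.arange(257) - 77) / FS * 1000.0
        bm = self._bandmap(100.0 * np.exp(-((t - 400.0) ** 2) / (2 * 40 ** 2)))
        pk = extract_peak(bm, "CZ", "beta")
        assert abs(pk.latency_ms - 400.0) <= 1000.0 / FS

    def test_flat_trace_ties_resolve_earliest(self):
        pk = extract_peak(self._bandmap(np.full(257, 5.0)), "CZ", "beta")
        assert pk.peak_power == 5.0
        assert pk.latency_ms == pytest.approx(200.0, abs=1000.0 / FS)

    def test_out_of_window_bump_clipped(self):
        t = (np.arange(257) - 77) / FS * 1000.0
        trace = 100.0 * np.exp(-((t - 100.0) ** 2) / (2 * 30 ** 2))
        pk = extract_peak(self._bandmap(trace), "CZ", "beta")
        assert pk.latency_ms >= 200.0

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            extract_peak(self._bandmap(np.zeros(257)), "CZ", "beta",
                         window_ms=(900.0, 950.0))


def test_injected_gabor_latency_recovery(default_bank):
    """A 20 Hz Gabor at 450 ms is recovered in the Beta trace within the
    wavelet's temporal sigma at 20 Hz."""
    rng = np.random.default_rng(11)
    t = (np.arange(257) - 77) / FS
    data = []
    for _ in range(40):
        x = rng.standard_normal(257) * 0.5
        x += 3.0 * np.exp(-((t - 0.45) ** 2) / (2 * 0.05 ** 2)) * np.cos(
            2 * np.pi * 20.0 * t + rng.uniform(0, 2 * np.pi))
        data.append(x[None, :])
    ts = make_trialset(np.array(data))
    bm = band_average(tf_percent_change(ts, default_bank))
    pk = extract_peak(bm, "ch0", "beta")
    k = int(np.argmin(np.abs(default_bank.freqs - 20.0)))
    sigma_t_ms = default_bank.cycles[k] / (2 * np.pi * 20.0) * 1000.0
    assert abs(pk.latency_ms - 450.0) <= sigma_t_ms
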