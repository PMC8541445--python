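"""Variable selection, LOOCV SVM metrics, KDE, and longitudinal tracking."""

import numpy as np
import pandas as pd
import pytest

from oddballeeg import (
    SynthConfig,
    generate_session,
    kde_density,
    loocv_svm,
    select_variables,
    track_longitudinal,
)
from oddballeeg.groupstats import VariableTable
from oddballeeg.montage import BAND_ORDER
from oddballeeg.synthgen import GROUP_ALS, GROUP_CONTROL


def make_table(n_ctrl=16, n_als=12, n_noise=40, effect=0.0, seed=0):
    """Noise table with one optionally shifted variable ('signal')."""
    rng = np.random.default_rng(seed)
    n = n_ctrl + n_als
    cols = {"signal": rng.normal(size=n)}
    cols["signal"][n_ctrl:] += effect
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.normal(size=n)
    frame = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    frame.insert(0, "group", [GROUP_CONTROL] * n_ctrl + [GROUP_ALS] * n_als)
    return VariableTable(frame, ("CZ",), BAND_ORDER)


class TestSelection:
    def test_deterministic_under_seed(self):
        table = make_table(effect=2.0, seed=1)
        r1 = select_variables(table, reps=5, seed=42)
        r2 = select_variables(table, reps=5, seed=42)
        assert r1.counts.equals(r2.counts)
        assert r1.chosen == r2.chosen

    def test_strong_variable_always_chosen(self):
        table = make_table(effect=3.0, seed=2)
        hits = sum(
            select_variables(table, reps=5, seed=s).chosen == ["signal"]
            for s in range(10))
        assert hits >= 9

    def test_all_noise_table_flagged_unstable(self):
        table = make_table(effect=0.0, seed=3)
        report = select_variables(table, reps=5, seed=0)
        assert not report.stable

    def test_groups_too_small_rejected(self):
        table = make_table(n_ctrl=3, n_als=3)
        with pytest.raises(ValueError, match="too small"):
            select_variables(table)


class TestLoocv:
    def test_disjoint_ranges_perfect_metrics(self):
        table = make_table(effect=10.0, seed=4)
        rep = loocv_svm(table, ["signal"])
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0
        assert rep.accuracy == 1.0

    def test_confusion_matrix_matches_hand_count(self):
        """Feature equals the class indicator except for two flipped
        subjects, whose LOOCV predictions must land on the wrong side."""
        n_ctrl, n_als = 8, 8
        x = np.array([0.0] * n_ctrl + [1.0] * n_als)
        x[0], x[n_ctrl] = 1.0, 0.0  # one flipped subject per group
        frame = pd.DataFrame({"f": x}, index=[f"s{i}" for i in range(16)])
        frame.insert(0, "group",
                     [GROUP_CONTROL] * n_ctrl + [GROUP_ALS] * n_als)
        rep = loocv_svm(VariableTable(frame, ("CZ",), BAND_ORDER), ["f"])
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (7, 7, 1, 1)
        assert rep.sensitivity == pytest.approx(7 / 8)
        assert rep.specificity == pytest.approx(7 / 8)
        assert rep.accuracy == pytest.approx(14 / 16)

    def test_permuted_labels_accuracy_near_chance(self):
        rng = np.random.default_rng(5)
        table = make_table(effect=3.0, seed=6, n_noise=0)
        accs = []
        for _ in range(100):
            frame = table.frame.copy()
            frame["group"] = rng.permutation(frame["group"].to_numpy())
            rep = loocv_svm(VariableTable(frame, ("CZ",), BAND_ORDER),
                            ["signal"])
            accs.append(rep.accuracy)
        band = 1.96 * np.sqrt(0.25 / 28)
        assert abs(np.mean(accs) - 0.5) < band

    def test_duplicating_rows_leaves_predictions_unchanged(self):
        table = make_table(effect=10.0, seed=7, n_noise=2)
        rep1 = loocv_svm(table, ["signal"])
        doubled = pd.concat([table.frame, table.frame.set_index(
            table.frame.index + "_copy")])
        rep2 = loocv_svm(VariableTable(doubled, ("CZ",), BAND_ORDER),
                         ["signal"])
        for idx in table.frame.index:
            assert rep2.predictions[idx] == rep1.predictions[idx]

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            loocv_svm(make_table(), ["nope"])


class TestKde:
    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(8)
        grid, dens = kde_density({"g": rng.normal(size=1000)})
        at0 = dens["g"][np.argmin(np.abs(grid))]
        assert at0 == pytest.approx(0.3989, abs=0.05)

    def test_nonnegative_unit_integral(self):
        rng = np.random.default_rng(9)
        grid, dens = kde_density({
            "a": rng.normal(size=50), "b": rng.normal(3.0, 0.5, size=30)})
        for d in dens.values():
            assert d.min() >= 0.0
            assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_mixture_two_modes(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([rng.normal(-3, 0.5, 400),
                               rng.normal(3, 0.5, 400)])
        grid, dens = kde_density({"g": vals})
        d = dens["g"]
        interior = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
        modes = grid[1:-1][interior & (d[1:-1] > 0.05)]
        assert len(modes) == 2

    def test_zero_variance_fallback(self):
        grid, dens = kde_density({"g": np.array([2.0, 2.0, 2.0])})
        assert np.all(np.isfinite(dens["g"]))
        assert np.trapezoid(dens["g"], grid) == pytest.approx(1.0, abs=1e-3)


class TestLongitudinal:
    def _session(self, kappa, seed):
        cfg = SynthConfig(
            n_target_trials=60,
            coupling={"alpha": {("PO7", "CZ"): kappa}},
            artifact_trial_rate=0.0,
        )
        return generate_session(cfg, "px", "control", seed)[0]

    def test_declining_coupling_gives_declining_series(self):
        sessions = [self._session(k, seed=20 + i)
                    for i, k in enumerate((6.0, 2.0, 0.5))]
        series = track_longitudinal(sessions, "ispc_PO7_CZ_alpha")
        assert list(series.index) == ["session1", "session2", "session3"]
        assert series.iloc[0] > series.iloc[1] > series.iloc[2]

    def test_single_session_rejected(self):
        with pytest.raises(ValueError, match="2 sessions"):
            track_longitudinal([self._session(2.0, 0)], "ispc_PO7_CZ_alpha")

    def test_unknown_variable_rejected(self):
        sessions = [self._session(2.0, 0), self._session(2.0, 1)]
        with pytest.raises(KeyError):
            track_longitudinal(sessions, "bogus_variable")
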