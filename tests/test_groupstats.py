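"""Variable-table structure, rank-sum screening, FDR, and permutation maps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oddballeeg import (
    build_variable_table,
    extreme_point_correction,
    fdr_adjust,
    pointwise_permutation,
    ranksum_p,
    ranksum_screen,
)
from oddballeeg.connectivity import ISPCTable
from oddballeeg.groupstats import SubjectFeatures, VariableTable
from oddballeeg.montage import BAND_ORDER, CHANNELS
from oddballeeg.tfpower import PeakFeature


def synth_features(subject_id, group, channels=CHANNELS, bands=BAND_ORDER,
                   seed=0):
    rng = np.random.default_rng(seed)
    peaks = [
        PeakFeature(ch, band, float(rng.uniform(0, 100)),
                    float(rng.uniform(200, 650)))
        for ch in channels for band in bands
    ]
    tables = {}
    for band in bands:
        m = rng.uniform(0, 1, size=(len(channels), len(channels)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        tables[band] = m
    ispc = ISPCTable(tables=tables, channel_labels=tuple(channels),
                     window_ms=(-250.0, 650.0))
    return SubjectFeatures(subject_id, group, peaks, ispc)


class TestVariableTable:
    def test_full_montage_counts(self):
        subs = [synth_features(f"s{i}", "control" if i < 2 else "als-like",
                               seed=i) for i in range(4)]
        table = build_variable_table(subs)
        assert table.n_power == 128
        assert table.n_connectivity == 960
        assert len(table.feature_columns) == 1088

    def test_toy_montage_counts(self):
        chans, bands = ("A", "B", "C"), ("delta", "beta")
        subs = [synth_features(f"s{i}", "control", chans, bands, seed=i)
                for i in range(3)]
        table = build_variable_table(subs, bands=bands)
        assert table.n_power == 3 * 2 * 2
        assert table.n_connectivity == 3 * 2 * 2

    def test_symmetric_orientations_equal_and_dedup(self):
        subs = [synth_features(f"s{i}", "control", seed=i) for i in range(2)]
        table = build_variable_table(subs)
        f = table.frame
        assert np.allclose(f["ispc_CZ_PZ_alpha"], f["ispc_PZ_CZ_alpha"])
        dedup = table.deduplicated()
        assert dedup.n_connectivity == 480

    def test_montage_mismatch_rejected(self):
        a = synth_features("a", "control")
        b = synth_features("b", "als-like", channels=tuple(reversed(CHANNELS)))
        with pytest.raises(ValueError, match="montage"):
            build_variable_table([a, b])


def enum_ranksum_p(x, y):
    """Independent oracle: exact two-sided rank-sum p by enumerating every
    assignment of the pooled ranks to the first group."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    w_obs = ranks[: len(x)].sum()
    ws = [sum(combo) for combo in
          itertools.combinations(ranks, len(x))]
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


class TestRankSum:
    def test_identical_groups_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert ranksum_p(vals, vals) == pytest.approx(1.0)

    def test_fully_separated_3v3_exact(self):
        assert ranksum_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)
        assert enum_ranksum_p(np.array([1., 2, 3]),
                              np.array([10., 11, 12])) == pytest.approx(0.1)

    @pytest.mark.parametrize("m,n", [(m, n) for m in range(2, 7)
                                     for n in range(2, 7)])
    def test_matches_enumeration_small_samples(self, m, n):
        rng = np.random.default_rng(100 * m + n)
        for _ in range(3):
            x = rng.normal(size=m)
            y = rng.normal(0.5, size=n)
            assert ranksum_p(x, y) == pytest.approx(
                enum_ranksum_p(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_p([], [1.0])


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_uniform_ladder_collapses_to_max(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            ours = fdr_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(ours - ref)) < 1e-12

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_bounds_and_monotonicity(self, pvals):
        p = np.array(pvals)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.5])


def _screen_table(xa, xb):
    cols = [f"v{j}" for j in range(xa.shape[1])]
    frame = pd.DataFrame(np.vstack([xa, xb]), columns=cols)
    frame.insert(0, "group", ["a"] * len(xa) + ["b"] * len(xb))
    return VariableTable(frame, ("CZ",), BAND_ORDER)


class TestScreen:
    def test_flags_shifted_variable_only(self):
        rng = np.random.default_rng(2)
        xa = rng.normal(size=(10, 5))
        xb = rng.normal(size=(12, 5))
        xb[:, 2] += 5.0
        res = ranksum_screen(_screen_table(xa, xb))
        assert "v2" in res.significant_variables()
        assert res.table["raw_p"].idxmin() == "v2"
        assert res.table.loc["v2", "raw_p"] < 1e-3
        assert np.all(res.table["adj_p"] >= res.table["raw_p"] - 1e-15)

    def test_needs_two_per_group(self):
        xa = np.zeros((1, 3))
        xb = np.ones((4, 3))
        with pytest.raises(ValueError):
            ranksum_screen(_screen_table(xa, xb))


class TestPermutationMaps:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(size=(6, 8, 9))
        pm = pointwise_permutation(maps, maps, n_perm=200, seed=0)
        assert np.allclose(pm.observed, 0.0)
        assert not pm.mask.any()
        assert np.allclose(pm.p_map, 1.0)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 6, 6))
        b = rng.normal(size=(10, 6, 6))
        p1 = pointwise_permutation(a, b, n_perm=300, seed=7)
        p2 = pointwise_permutation(a, b, n_perm=300, seed=7)
        assert np.array_equal(p1.p_map, p2.p_map)

    def test_injected_rectangle_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.5, size=(12, 10, 12))
        b = rng.normal(0, 0.5, size=(16, 10, 12))
        a[:, 3:6, 4:8] += 1.0
        pm = pointwise_permutation(a, b, n_perm=1000, seed=0)
        assert pm.mask[3:6, 4:8].mean() > 0.9
        assert pm.mask[~np.zeros((10, 12), bool)].mean() < 0.5

    def test_extreme_mask_subset_of_pixelwise(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.5, size=(12, 10, 12))
        b = rng.normal(0, 0.5, size=(16, 10, 12))
        a[:, 2:5, 2:5] += 0.8
        pm = pointwise_permutation(a, b, n_perm=500, seed=3)
        extreme = extreme_point_correction(a, b, n_perm=500, seed=3)
        assert extreme[2:5, 2:5].any()
        assert np.all(pm.mask[extreme])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            pointwise_permutation(np.zeros((3, 4, 4)), np.zeros((3, 5, 5)),
                                  n_perm=10)
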