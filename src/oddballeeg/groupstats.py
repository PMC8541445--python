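"""Group statistics: the 1088-variable table, rank-sum screening, FDR
step-up adjustment, and permutation maps with extreme-point correction.

For the 16-channel, 4-band configuration the variable table has 128 power
columns (peak percent-change power and its latency per electrode x band)
and 960 connectivity columns (ISPC for every ordered electrode pair x
band; symmetric pairs are present in both orientations with equal values,
honoring the study's printed 960 count — a de-duplicated view is
available for analyses where the duplication would inflate test counts).

The rank-sum screen is the two-sided Wilcoxon rank-sum / Mann-Whitney
test: exact when both groups have at most six subjects and no ties,
otherwise the normal approximation with midranks and continuity
correction.  FDR adjustment is the classical step-up rule: with p-values
sorted ascending and ranked r = 1..n, the top rank is kept and each next
adjusted value is min(previous adjusted, p(r) * n / r).

The point-wise permutation analysis shuffles subjects between groups
(preserving group sizes), rebuilds the group-mean difference map each
time, and compares each pixel's observed difference against its null
distribution (two-sided).  The extreme-point correction controls the
family-wise error by recording each shuffled map's minimum and maximum
and flagging observed pixels beyond the 2.5th percentile of the minima or
the 97.5th percentile of the maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .montage import BAND_ORDER
from .connectivity import ISPCTable
from .tfpower import PeakFeature

__all__ = [
    "SubjectFeatures",
    "VariableTable",
    "ScreenResult",
    "PermMap",
    "build_variable_table",
    "ranksum_p",
    "ranksum_screen",
    "fdr_adjust",
    "pointwise_permutation",
    "extreme_point_correction",
    "power_column",
    "ispc_column",
]

GROUP_COL = "group"


def power_column(channel: str, band: str, condition: str) -> str:
    """Column name of a power variable; condition is 'power' or 'latency'."""
    return f"pow_{channel}_{band}_{condition}"


def ispc_column(ch_x: str, ch_y: str, band: str) -> str:
    return f"ispc_{ch_x}_{ch_y}_{band}"


@dataclass
class SubjectFeatures:
    """Extracted features of one subject, input to the variable table."""

    subject_id: str
    group_label: str
    peaks: list[PeakFeature]
    ispc: ISPCTable


class VariableTable:
    """Subjects x variables DataFrame with a 'group' label column.

    Column order is deterministic: power variables electrode-major,
    band-minor, condition last; then connectivity variables as ordered
    pairs (electrode-major), band last.
    """

    def __init__(self, frame: pd.DataFrame, channel_labels: tuple[str, ...],
                 bands: tuple[str, ...]):
        self.frame = frame
        self.channel_labels = tuple(channel_labels)
        self.bands = tuple(bands)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != GROUP_COL]

    @property
    def n_power(self) -> int:
        return sum(c.startswith("pow_") for c in self.feature_columns)

    @property
    def n_connectivity(self) -> int:
        return sum(c.startswith("ispc_") for c in self.feature_columns)

    def groups(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(X_a, X_b, columns): feature matrices of the two groups in label
        sort order (first label alphabetically = group a)."""
        labels = sorted(self.frame[GROUP_COL].unique())
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, got {labels}")
        cols = self.feature_columns
        xa = self.frame.loc[self.frame[GROUP_COL] == labels[0], cols].to_numpy(float)
        xb = self.frame.loc[self.frame[GROUP_COL] == labels[1], cols].to_numpy(float)
        return xa, xb, cols

    def deduplicated(self) -> "VariableTable":
        """Drop the redundant orientation of each symmetric ISPC pair."""
        keep = []
        for c in self.frame.columns:
            if c.startswith("ispc_"):
                _, x, y, band = c.split("_")
                if self.channel_labels.index(x) > self.channel_labels.index(y):
                    continue
            keep.append(c)
        return VariableTable(self.frame[keep].copy(), self.channel_labels,
                             self.bands)


def build_variable_table(
    subjects: list[SubjectFeatures],
    bands: tuple[str, ...] = BAND_ORDER,
) -> VariableTable:
    """Assemble the per-subject features into the screening table."""
    if not subjects:
        raise ValueError("no subjects")
    montage = subjects[0].ispc.channel_labels
    for s in subjects:
        if s.ispc.channel_labels != montage:
            raise ValueError(f"montage mismatch for subject {s.subject_id}")

    columns: list[str] = []
    for ch in montage:
        for band in bands:
            for cond in ("power", "latency"):
                columns.append(power_column(ch, band, cond))
    for ch_x in montage:
        for ch_y in montage:
            if ch_y == ch_x:
                continue
            for band in bands:
                columns.append(ispc_column(ch_x, ch_y, band))

    rows = []
    index = []
    group = []
    for s in subjects:
        peak_map = {(p.channel, p.band): p for p in s.peaks}
        row = {}
        for ch in montage:
            for band in bands:
                p = peak_map.get((ch, band))
                if p is None:
                    raise ValueError(
                        f"subject {s.subject_id} missing peak for {ch}/{band}")
                row[power_column(ch, band, "power")] = p.peak_power
                row[power_column(ch, band, "latency")] = p.latency_ms
        for ch_x in montage:
            for ch_y in montage:
                if ch_y == ch_x:
                    continue
                for band in bands:
                    row[ispc_column(ch_x, ch_y, band)] = s.ispc.value(
                        band, ch_x, ch_y)
        rows.append(row)
        index.append(s.subject_id)
        group.append(s.group_label)

    frame = pd.DataFrame(rows, index=index, columns=columns)
    frame.insert(0, GROUP_COL, group)
    return VariableTable(frame, montage, bands)


# --------------------------------------------------------------------------
# rank-sum screening


def ranksum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact (full enumeration of rank assignments) when both samples have at
    most 6 observations and there are no ties; otherwise the normal
    approximation with midranks and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and x.size <= 6 and y.size <= 6:
        method = "exact"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method=method, use_continuity=True).pvalue)


def ranksum_p_columns(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Vectorized column-wise rank-sum p (normal approximation path)."""
    res = mannwhitneyu(xa, xb, alternative="two-sided", axis=0,
                       method="asymptotic", use_continuity=True)
    return np.asarray(res.pvalue, dtype=float)


@dataclass
class ScreenResult:
    """Per-variable screening outcome."""

    table: pd.DataFrame   # columns: raw_p, adj_p, significant, median_a, median_b

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_variables(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def ranksum_screen(table: VariableTable, alpha: float = 0.05) -> ScreenResult:
    """Screen every variable by the two-sided rank-sum test at level alpha.

    The significance flag uses the raw p-value (< alpha); the FDR-adjusted
    p-value is reported alongside.
    """
    xa, xb, cols = table.groups()
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    raw = np.array([ranksum_p(xa[:, j], xb[:, j]) for j in range(len(cols))])
    adj = fdr_adjust(raw)
    out = pd.DataFrame(
        {
            "raw_p": raw,
            "adj_p": adj,
            "significant": raw < alpha,
            "median_a": np.median(xa, axis=0),
            "median_b": np.median(xb, axis=0),
        },
        index=pd.Index(cols, name="variable"),
    )
    return ScreenResult(out)


def fdr_adjust(pvalues) -> np.ndarray:
    """Step-up false-discovery-rate adjustment (Benjamini-Hochberg form).

    Sorted ascending with ranks r = 1..n, the largest p is kept and each
    next value is min(previous adjusted, p(r) * n / r); the result is
    returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(n)
    out[order] = adj_sorted
    return out


# --------------------------------------------------------------------------
# point-wise permutation maps


@dataclass
class PermMap:
    """Observed group-difference map with permutation statistics."""

    observed: np.ndarray     # mean(A) - mean(B), original map shape
    p_map: np.ndarray        # two-sided pixel-wise p in [0, 1]
    mask: np.ndarray         # p < alpha
    extreme_mask: np.ndarray | None
    n_perm: int
    seed: int


def _stack(maps) -> np.ndarray:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim < 2:
        raise ValueError("maps must be (n_subjects, ...) with a map shape")
    return arr


def _null_differences(
    x: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null group-mean differences under label shuffling, (n_perm, n_pixels)."""
    n = x.shape[0]
    flat = x.reshape(n, -1)
    n_b = n - n_a
    w = np.empty((n_perm, n))
    base = np.full(n, -1.0 / n_b)
    for i in range(n_perm):
        perm = rng.permutation(n)
        row = base.copy()
        row[perm[:n_a]] = 1.0 / n_a
        w[i] = row
    return w @ flat


def pointwise_permutation(
    maps_a, maps_b, n_perm: int = 1000, seed: int = 0, alpha: float = 0.05
) -> PermMap:
    """Pixel-wise two-sided permutation test of the group-mean difference.

    p per pixel is the fraction of |null differences| >= |observed|.
    """
    a = _stack(maps_a)
    b = _stack(maps_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError(f"map shape mismatch: {a.shape[1:]} vs {b.shape[1:]}")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    shape = a.shape[1:]
    observed = a.mean(axis=0) - b.mean(axis=0)
    rng = np.random.default_rng(seed)
    null = _null_differences(np.concatenate([a, b]), a.shape[0], n_perm, rng)
    obs_flat = observed.reshape(-1)
    p = (np.abs(null) >= np.abs(obs_flat)[None, :] - 1e-12).mean(axis=0)
    p_map = p.reshape(shape)
    return PermMap(observed=observed, p_map=p_map, mask=p_map < alpha,
                   extreme_mask=None, n_perm=n_perm, seed=seed)


def extreme_point_correction(
    maps_a, maps_b, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Family-wise significance mask from the shuffled maps' extrema.

    Each permutation contributes the minimum and maximum of its shuffled
    difference map; observed pixels below the 2.5th percentile of the
    minima or above the 97.5th percentile of the maxima are significant.
    Under the same seed the permutation stream matches
    ``pointwise_permutation``, so the mask is a subset of its p < 0.05 set.
    """
    a = _stack(maps_a)
    b = _stack(maps_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError(f"map shape mismatch: {a.shape[1:]} vs {b.shape[1:]}")
    observed = a.mean(axis=0) - b.mean(axis=0)
    rng = np.random.default_rng(seed)
    null = _null_differences(np.concatenate([a, b]), a.shape[0], n_perm, rng)
    minima = null.min(axis=1)
    maxima = null.max(axis=1)
    lo = np.percentile(minima, 2.5)
    hi = np.percentile(maxima, 97.5)
    return (observed < lo) | (observed > hi)
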