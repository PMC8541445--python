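"""Nested-fold variable selection, linear SVM with leave-one-out
evaluation, kernel-density views, and longitudinal tracking.

Selection mirrors the study protocol: an outer stratified 4-fold holds out
25% of each group; on the remaining 75% an inner stratified 3-fold is run
and, in each inner fold, every variable significantly different between
groups (rank-sum p < alpha) on the inner-training subjects gets a tally.
The whole loop repeats 25 times with reshuffled folds, and the most-tallied
variables are the selected biomarkers.  Held-out outer subjects never
influence selection.

The classifier is a deliberately simple linear SVM (C = 1, features
z-scored on the training fold only), evaluated by leave-one-out
cross-validation; the als-like group is the positive class, so specificity
is the fraction of controls classified correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .groupstats import GROUP_COL, VariableTable, ranksum_p_columns
from .synthgen import GROUP_ALS

__all__ = [
    "SelectionReport",
    "ClassifierReport",
    "select_variables",
    "loocv_svm",
    "kde_density",
    "track_longitudinal",
]


@dataclass
class SelectionReport:
    """Tally of how often each variable was significant across inner folds."""

    counts: pd.Series            # per variable, descending
    chosen: list[str]            # top-k variables
    total_folds: int             # outer_k * inner_k * reps
    stable: bool                 # top variable significant in >= 90% of folds
    seed: int = 0


@dataclass
class ClassifierReport:
    """Leave-one-out confusion matrix and derived metrics (positive = als-like)."""

    tp: int
    tn: int
    fp: int
    fn: int
    predictions: pd.Series = field(repr=False)
    variables: list[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


def _group_mask(table: VariableTable) -> np.ndarray:
    return (table.frame[GROUP_COL] == GROUP_ALS).to_numpy()


def select_variables(
    table: VariableTable,
    outer_k: int = 4,
    inner_k: int = 3,
    reps: int = 25,
    alpha: float = 0.05,
    seed: int = 0,
    top_k: int = 1,
) -> SelectionReport:
    """Tally rank-sum-significant variables over nested stratified folds."""
    cols = table.feature_columns
    x = table.frame[cols].to_numpy(float)
    y = _group_mask(table)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < outer_k:
        raise ValueError(
            f"group sizes ({n_neg}, {n_pos}) too small for stratified "
            f"{outer_k}-fold selection")

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(cols), dtype=int)
    total = 0
    for _ in range(reps):
        outer = StratifiedKFold(outer_k, shuffle=True,
                                random_state=int(rng.integers(2 ** 31)))
        for train_idx, _test_idx in outer.split(x, y):
            inner = StratifiedKFold(inner_k, shuffle=True,
                                    random_state=int(rng.integers(2 ** 31)))
            for fit_idx, _val_idx in inner.split(x[train_idx], y[train_idx]):
                sub = train_idx[fit_idx]
                pos = x[sub][y[sub]]
                neg = x[sub][~y[sub]]
                p = ranksum_p_columns(pos, neg)
                counts += p < alpha
                total += 1

    series = pd.Series(counts, index=cols).sort_values(
        ascending=False, kind="stable")
    chosen = list(series.index[:top_k]) if series.iloc[0] > 0 else []
    # fold tallies are correlated (folds share subjects), so a lucky noise
    # variable can clear half the folds; a real effect saturates the tally
    stable = bool(series.iloc[0] >= 0.9 * total)
    return SelectionReport(counts=series, chosen=chosen, total_folds=total,
                           stable=stable, seed=seed)


def loocv_svm(
    table: VariableTable, variables: list[str], seed: int = 0
) -> ClassifierReport:
    """Leave-one-out evaluation of a linear SVM on the chosen variables."""
    missing = [v for v in variables if v not in table.frame.columns]
    if missing:
        raise KeyError(f"unknown variables: {missing}")
    x = table.frame[variables].to_numpy(float)
    y = _group_mask(table)
    if y.all() or not y.any():
        raise ValueError("both groups must be present")

    preds = np.zeros(len(y), dtype=bool)
    for train_idx, test_idx in LeaveOneOut().split(x):
        if y[train_idx].all() or not y[train_idx].any():
            raise ValueError("a training fold contains a single class")
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel="linear", C=1.0, random_state=seed),
        )
        model.fit(x[train_idx], y[train_idx])
        preds[test_idx] = model.predict(x[test_idx])

    tp = int(np.sum(preds & y))
    tn = int(np.sum(~preds & ~y))
    fp = int(np.sum(preds & ~y))
    fn = int(np.sum(~preds & y))
    pred_series = pd.Series(
        np.where(preds, GROUP_ALS, "control"), index=table.frame.index)
    return ClassifierReport(tp=tp, tn=tn, fp=fp, fn=fn,
                            predictions=pred_series, variables=list(variables))


def kde_density(
    values_by_group: dict[str, np.ndarray],
    grid_size: int = 512,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Gaussian kernel density per group on a shared grid (Silverman rule).

    A zero-variance group falls back to a narrow fixed bandwidth of 1e-3
    times max(1, |mean|) so the density remains well defined.
    """
    bandwidths = {}
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
        values_by_group[name] = vals
        if np.std(vals) == 0:
            bandwidths[name] = 1e-3 * max(1.0, abs(float(np.mean(vals))))
        else:
            n = vals.size
            bandwidths[name] = np.std(vals, ddof=1) * (4.0 / (3.0 * n)) ** 0.2

    lo = min(v.min() - 5 * bandwidths[k] for k, v in values_by_group.items())
    hi = max(v.max() + 5 * bandwidths[k] for k, v in values_by_group.items())
    grid = np.linspace(lo, hi, grid_size)

    densities = {}
    for name, vals in values_by_group.items():
        if np.std(vals) == 0:
            bw = bandwidths[name]
            z = (grid[:, None] - vals[None, :]) / bw
            dens = np.exp(-0.5 * z ** 2).sum(axis=1) / (
                vals.size * bw * np.sqrt(2 * np.pi))
        else:
            dens = gaussian_kde(vals, bw_method="silverman")(grid)
        densities[name] = dens
    return grid, densities


def track_longitudinal(sessions, variable: str,
                       rejection_cfg=None) -> pd.Series:
    """Recompute one named variable through the full pipeline per session.

    ``sessions`` is an ordered sequence of EEGSession for one subject
    (e.g. recordings months apart); the result is the variable's value per
    session, indexed by session label (or position).
    """
    from .preprocess import baseline_correct, extract_trials, reject_trials
    from .tfpower import band_average, build_wavelets, extract_peak, \
        tf_percent_change
    from .connectivity import analytic_phase, ispc_pair

    sessions = list(sessions)
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions to track a variable")

    parts = variable.split("_")
    if parts[0] == "pow" and len(parts) == 4:
        kind, ch, band, cond = "pow", parts[1], parts[2], parts[3]
        if cond not in ("power", "latency"):
            raise KeyError(f"unknown variable {variable!r}")
    elif parts[0] == "ispc" and len(parts) == 4:
        kind, ch, ch_y, band = "ispc", parts[1], parts[2], parts[3]
    else:
        raise KeyError(f"unknown variable {variable!r}")

    values = []
    labels = []
    for i, session in enumerate(sessions):
        trials = reject_trials(baseline_correct(extract_trials(session)),
                               rejection_cfg)
        if kind == "pow":
            bank = build_wavelets(session.fs)
            tf = tf_percent_change(trials, bank, channels=(ch,))
            peak = extract_peak(band_average(tf), ch, band)
            values.append(peak.peak_power if cond == "power"
                          else peak.latency_ms)
        else:
            phases = analytic_phase(trials, bands=(band,))
            values.append(ispc_pair(phases, band, ch, ch_y))
        labels.append(session.session_label or f"session{i + 1}")
    return pd.Series(values, index=labels, name=variable)
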