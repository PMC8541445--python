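"""Single-config orchestration of the full analysis pipeline.

Stages: simulate (optional) -> preprocess -> tf -> connectivity -> stats
-> classify.  Every stage logs its counts and wall time into a run
manifest (JSON), and the tabular artifacts (variable table, screening
results, selection and classifier reports) are written to the output
directory.  Re-running with the same config reproduces the same counts
bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import loocv_svm, select_variables
from .connectivity import analytic_phase, ispc_all
from .groupstats import (
    SubjectFeatures,
    build_variable_table,
    extreme_point_correction,
    pointwise_permutation,
    ranksum_screen,
)
from .io import read_session, write_session
from .preprocess import RejectionConfig, baseline_correct, extract_trials, \
    reject_trials
from .synthgen import GROUP_ALS, GROUP_CONTROL, SynthConfig, generate_cohort
from .tfpower import band_average, build_wavelets, peak_features_all, \
    tf_percent_change

__all__ = ["PipelineConfig", "run_pipeline", "variable_table_from_sessions"]


def variable_table_from_sessions(sessions, rejection: RejectionConfig | None = None,
                                 peak_window_ms=(200.0, 650.0)):
    """Preprocess, decompose and assemble the variable table for a list of
    :class:`~oddballeeg.preprocess.EEGSession` (the in-memory equivalent of
    the preprocess -> tf -> connectivity -> stats chain)."""
    feats = []
    bank = build_wavelets(sessions[0].fs)
    for session in sessions:
        ts = reject_trials(baseline_correct(extract_trials(session)), rejection)
        tf = tf_percent_change(ts, bank)
        peaks = peak_features_all(band_average(tf), peak_window_ms)
        ispc = ispc_all(analytic_phase(ts))
        feats.append(SubjectFeatures(session.subject_id, session.group_label,
                                     peaks, ispc))
    return build_variable_table(feats)

log = logging.getLogger("oddballeeg")

STAGES = ("simulate", "preprocess", "tf", "connectivity", "stats", "classify")


@dataclass
class PipelineConfig:
    """Everything one run needs: input source, stage toggles, parameters."""

    out_dir: Path = Path("oddballeeg_run")
    synth: SynthConfig | None = None      # generate a cohort ...
    input_dir: Path | None = None         # ... or read EDF + sidecars
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    rejection: RejectionConfig = field(default_factory=RejectionConfig)
    pre_ms: float = 300.0
    post_ms: float = 700.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    peak_window_ms: tuple[float, float] = (200.0, 650.0)
    perm_channel: str = "CZ"
    n_perm: int = 1000
    alpha: float = 0.05
    outer_k: int = 4
    inner_k: int = 3
    selection_reps: int = 25
    top_k: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for s in STAGES:
            self.stages.setdefault(s, True)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.synth is None and self.input_dir is None:
            raise ValueError("config needs either a synth block or an input_dir")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synth") is not None:
            synth = dict(d["synth"])
            if "channels" in synth:
                synth["channels"] = tuple(synth["channels"])
            d["synth"] = SynthConfig(**synth)
        if d.get("rejection") is not None:
            d["rejection"] = RejectionConfig(**d["rejection"])
        if "input_dir" in d and d["input_dir"] is not None:
            d["input_dir"] = Path(d["input_dir"])
        if "baseline_ms" in d:
            d["baseline_ms"] = tuple(d["baseline_ms"])
        if "peak_window_ms" in d:
            d["peak_window_ms"] = tuple(d["peak_window_ms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _load_sessions(cfg: PipelineConfig, manifest: dict):
    """Yield (session, truth) pairs from the configured source."""
    if cfg.stages["simulate"] and cfg.synth is not None:
        t0 = time.perf_counter()
        cohort = generate_cohort(cfg.synth)
        sess_dir = cfg.out_dir / "sessions"
        for session, truth in cohort:
            write_session(session, sess_dir, truth)
        manifest["stages"]["simulate"] = {
            "status": "done",
            "n_sessions": len(cohort),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        manifest["outputs"].append(str(sess_dir))
        return cohort
    manifest["stages"]["simulate"] = {"status": "skipped"}
    if cfg.input_dir is None:
        raise ValueError("simulate disabled and no input_dir configured")
    sessions = []
    for edf in sorted(Path(cfg.input_dir).glob("*.edf")):
        sessions.append(read_session(edf))
    if not sessions:
        raise FileNotFoundError(f"no EDF files under {cfg.input_dir}")
    return sessions


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": {},
        "outputs": [],
        "counts": {},
    }

    cohort = _load_sessions(cfg, manifest)

    if not cfg.stages["preprocess"]:
        manifest["stages"]["preprocess"] = {"status": "skipped"}
        _finish(cfg, manifest)
        return manifest

    t0 = time.perf_counter()
    trials_by_subject = []
    kept = rejected = 0
    for session, _truth in cohort:
        ts = extract_trials(session, cfg.pre_ms, cfg.post_ms)
        ts = baseline_correct(ts, cfg.baseline_ms)
        ts = reject_trials(ts, cfg.rejection)
        trials_by_subject.append(ts)
        kept += ts.n_kept
        rejected += ts.n_trials - ts.n_kept
    manifest["stages"]["preprocess"] = {
        "status": "done",
        "trials_kept": kept,
        "trials_rejected": rejected,
        "seconds": round(time.perf_counter() - t0, 3),
    }
    log.info("preprocess: kept %d, rejected %d trials", kept, rejected)

    peaks_by_subject = {}
    perm_maps = {GROUP_CONTROL: [], GROUP_ALS: []}
    if cfg.stages["tf"]:
        t0 = time.perf_counter()
        bank = build_wavelets(cohort[0][0].fs)
        for ts in trials_by_subject:
            tf = tf_percent_change(ts, bank, cfg.baseline_ms)
            bandmap = band_average(tf)
            peaks_by_subject[ts.subject_id] = peak_features_all(
                bandmap, cfg.peak_window_ms)
            if cfg.perm_channel in tf.channel_labels:
                perm_maps[ts.group_label].append(
                    tf.channel(cfg.perm_channel).copy())
        manifest["stages"]["tf"] = {
            "status": "done",
            "n_frequencies": bank.n_freqs,
            "n_subjects": len(peaks_by_subject),
            "seconds": round(time.perf_counter() - t0, 3),
        }
    else:
        manifest["stages"]["tf"] = {"status": "skipped"}

    ispc_by_subject = {}
    if cfg.stages["connectivity"]:
        t0 = time.perf_counter()
        for ts in trials_by_subject:
            phases = analytic_phase(ts)
            ispc_by_subject[ts.subject_id] = ispc_all(phases)
        manifest["stages"]["connectivity"] = {
            "status": "done",
            "n_subjects": len(ispc_by_subject),
            "seconds": round(time.perf_counter() - t0, 3),
        }
    else:
        manifest["stages"]["connectivity"] = {"status": "skipped"}

    table = None
    if cfg.stages["stats"] and peaks_by_subject and ispc_by_subject:
        t0 = time.perf_counter()
        feats = [
            SubjectFeatures(ts.subject_id, ts.group_label,
                            peaks_by_subject[ts.subject_id],
                            ispc_by_subject[ts.subject_id])
            for ts in trials_by_subject
        ]
        table = build_variable_table(feats)
        table_path = cfg.out_dir / "variable_table.tsv"
        table.frame.to_csv(table_path, sep="\t")
        manifest["outputs"].append(str(table_path))

        screen = ranksum_screen(table, cfg.alpha)
        screen_path = cfg.out_dir / "screening.tsv"
        screen.table.to_csv(screen_path, sep="\t")
        manifest["outputs"].append(str(screen_path))

        stats_info = {
            "status": "done",
            "n_variables": len(table.feature_columns),
            "n_power_variables": table.n_power,
            "n_connectivity_variables": table.n_connectivity,
            "n_significant_raw": screen.n_significant,
            "min_adj_p": float(screen.table["adj_p"].min()),
        }
        if perm_maps[GROUP_CONTROL] and perm_maps[GROUP_ALS]:
            pm = pointwise_permutation(
                perm_maps[GROUP_ALS], perm_maps[GROUP_CONTROL],
                n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha)
            extreme = extreme_point_correction(
                perm_maps[GROUP_ALS], perm_maps[GROUP_CONTROL],
                n_perm=cfg.n_perm, seed=cfg.seed)
            perm_path = cfg.out_dir / f"permmap_{cfg.perm_channel}.npz"
            np.savez_compressed(perm_path, observed=pm.observed,
                                p_map=pm.p_map, mask=pm.mask,
                                extreme_mask=extreme)
            manifest["outputs"].append(str(perm_path))
            stats_info["perm_channel"] = cfg.perm_channel
            stats_info["n_pixels_significant"] = int(pm.mask.sum())
            stats_info["n_pixels_extreme"] = int(extreme.sum())
        stats_info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"]["stats"] = stats_info
    else:
        manifest["stages"]["stats"] = {"status": "skipped"}

    if cfg.stages["classify"] and table is not None:
        t0 = time.perf_counter()
        report = select_variables(
            table, outer_k=cfg.outer_k, inner_k=cfg.inner_k,
            reps=cfg.selection_reps, alpha=cfg.alpha, seed=cfg.seed,
            top_k=cfg.top_k)
        clf = loocv_svm(table, report.chosen, seed=cfg.seed) \
            if report.chosen else None
        payload = {
            "chosen_variables": report.chosen,
            "selection_stable": report.stable,
            "total_inner_folds": report.total_folds,
            "top_counts": report.counts.head(10).to_dict(),
        }
        if clf is not None:
            payload.update({
                "confusion": {"tp": clf.tp, "tn": clf.tn,
                              "fp": clf.fp, "fn": clf.fn},
                "sensitivity": clf.sensitivity,
                "specificity": clf.specificity,
                "accuracy": clf.accuracy,
                "predictions": clf.predictions.to_dict(),
            })
        clf_path = cfg.out_dir / "classifier_report.json"
        clf_path.write_text(json.dumps(payload, indent=1))
        manifest["outputs"].append(str(clf_path))
        manifest["stages"]["classify"] = {
            "status": "done",
            "chosen": report.chosen,
            "accuracy": None if clf is None else clf.accuracy,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    else:
        manifest["stages"]["classify"] = {"status": "skipped"}

    if table is not None:
        manifest["counts"]["n_variables"] = len(table.feature_columns)
    _finish(cfg, manifest)
    return manifest


def _finish(cfg: PipelineConfig, manifest: dict) -> None:
    path = cfg.out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    manifest["manifest_path"] = str(path)
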