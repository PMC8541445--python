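"""Session and trial I/O: EDF + JSON sidecar in, array containers out.

Sessions are written as plain EDF (16-bit, one 1-second data record per
second, physical range +/-1000 uV) with a JSON sidecar holding the event
markers, group label and — for synthetic sessions — the injected ground
truth.  Reading goes through :func:`mne.io.read_raw_edf`, which also
serves as an independent check on the writer.  Epoched trials and other
intermediate arrays are stored as ``.npz`` containers with a JSON header
entry.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .preprocess import EEGSession, TrialSet
from .synthgen import GroundTruth

__all__ = [
    "write_edf",
    "write_sidecar",
    "write_session",
    "read_session",
    "save_trialset",
    "load_trialset",
    "peaks_to_frame",
    "frame_to_peaks",
    "ispc_to_frame",
    "frame_to_ispc",
]

_PHYS_MIN, _PHYS_MAX = -1000.0, 1000.0
_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")[:width]
    return b.ljust(width)


def write_edf(session: EEGSession, path: str | Path) -> Path:
    """Write the session as a plain EDF file (one file per subject).

    The sampling rate must be an integer (one data record per second);
    samples are quantized to 16 bits over +/-1000 uV and the last record
    is zero-padded to a whole second.
    """
    path = Path(path)
    fs = session.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    n_ch = len(session.channel_labels)
    n_samples = session.n_samples
    n_records = -(-n_samples // spr)

    sig = np.clip(session.signal, _PHYS_MIN, _PHYS_MAX)
    scale = (_DIG_MAX - _DIG_MIN) / (_PHYS_MAX - _PHYS_MIN)
    digital = np.round((sig - _PHYS_MIN) * scale).astype(np.int64) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    padded = np.zeros((n_ch, n_records * spr), dtype="<i2")
    padded[:, :n_samples] = digital

    header_bytes = 256 + 256 * n_ch
    head = b"".join([
        _fixed("0", 8),
        _fixed(session.subject_id, 80),
        _fixed(f"group {session.group_label}", 80),
        _fixed("01.01.01", 8),
        _fixed("00.00.00", 8),
        _fixed(str(header_bytes), 8),
        _fixed("", 44),
        _fixed(str(n_records), 8),
        _fixed("1", 8),
        _fixed(str(n_ch), 4),
    ])
    fields = [
        (16, [ch for ch in session.channel_labels]),
        (80, ["EEG"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{_PHYS_MIN:g}"] * n_ch),
        (8, [f"{_PHYS_MAX:g}"] * n_ch),
        (8, [str(_DIG_MIN)] * n_ch),
        (8, [str(_DIG_MAX)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(spr)] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_head = b"".join(
        b"".join(_fixed(v, width) for v in values) for width, values in fields
    )

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig_head)
        # records: for each second, all channels sequentially
        records = padded.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(records).tobytes())
    return path


def _truth_to_json(truth: GroundTruth) -> dict:
    d = asdict(truth)
    d["pair_kappa"] = {":".join(k): v for k, v in truth.pair_kappa.items()}
    return d


def _truth_from_json(d: dict) -> GroundTruth:
    pairs = {tuple(k.split(":")): v for k, v in d["pair_kappa"].items()}
    return GroundTruth(
        subject_id=d["subject_id"],
        group_label=d["group_label"],
        beta_power_multiplier=d["beta_power_multiplier"],
        erp_latency_ms=d["erp_latency_ms"],
        erp_amp_scale=d["erp_amp_scale"],
        pair_kappa=pairs,
    )


def write_sidecar(session: EEGSession, path: str | Path,
                  truth: GroundTruth | None = None) -> Path:
    path = Path(path)
    payload = {
        "subject_id": session.subject_id,
        "group_label": session.group_label,
        "fs": session.fs,
        "channel_labels": list(session.channel_labels),
        "session_label": session.session_label,
        "n_samples": session.n_samples,
        "events": [[int(i), bool(t)] for i, t in session.events],
        "ground_truth": _truth_to_json(truth) if truth is not None else None,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_session(session: EEGSession, directory: str | Path,
                  truth: GroundTruth | None = None) -> tuple[Path, Path]:
    """Write ``<subject>.edf`` plus ``<subject>.json`` into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = session.subject_id if session.session_label is None \
        else f"{session.subject_id}_{session.session_label}"
    edf = write_edf(session, directory / f"{stem}.edf")
    sidecar = write_sidecar(session, directory / f"{stem}.json", truth)
    return edf, sidecar


def read_session(
    edf_path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[EEGSession, GroundTruth | None]:
    """Read an EDF recording and its JSON sidecar back into an EEGSession."""
    import mne

    edf_path = Path(edf_path)
    if sidecar_path is None:
        sidecar_path = edf_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne stores volts; sessions are in uV
    signal = signal[:, : meta["n_samples"]]

    truth = None
    if meta.get("ground_truth"):
        truth = _truth_from_json(meta["ground_truth"])
    session = EEGSession(
        subject_id=meta["subject_id"],
        group_label=meta["group_label"],
        fs=float(meta["fs"]),
        channel_labels=tuple(meta["channel_labels"]),
        signal=signal,
        events=[(int(i), bool(t)) for i, t in meta["events"]],
        session_label=meta.get("session_label"),
    )
    return session, truth


def peaks_to_frame(subject_id: str, group_label: str, peaks) -> "pd.DataFrame":
    """Tabulate PeakFeature records (one row per channel x band)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject": subject_id,
            "group": group_label,
            "channel": [p.channel for p in peaks],
            "band": [p.band for p in peaks],
            "peak_power_pct": [p.peak_power for p in peaks],
            "latency_ms": [p.latency_ms for p in peaks],
        }
    )


def frame_to_peaks(frame) -> list:
    from .tfpower import PeakFeature

    return [
        PeakFeature(row.channel, row.band, float(row.peak_power_pct),
                    float(row.latency_ms))
        for row in frame.itertuples()
    ]


def ispc_to_frame(subject_id: str, group_label: str, table) -> "pd.DataFrame":
    """Long-format (band, ch_x, ch_y, ispc) rows for the upper triangle."""
    import pandas as pd

    rows = []
    labels = table.channel_labels
    for band, mat in table.tables.items():
        for i, ch_x in enumerate(labels):
            for j in range(i + 1, len(labels)):
                rows.append((subject_id, group_label, band, ch_x, labels[j],
                             float(mat[i, j])))
    return pd.DataFrame(
        rows, columns=["subject", "group", "band", "ch_x", "ch_y", "ispc"])


def frame_to_ispc(frame, channel_labels, window_ms=(-250.0, 650.0)):
    from .connectivity import ISPCTable

    labels = tuple(channel_labels)
    idx = {c: i for i, c in enumerate(labels)}
    tables = {}
    for band, sub in frame.groupby("band"):
        m = np.eye(len(labels))
        for row in sub.itertuples():
            m[idx[row.ch_x], idx[row.ch_y]] = row.ispc
            m[idx[row.ch_y], idx[row.ch_x]] = row.ispc
        tables[band] = m
    return ISPCTable(tables=tables, channel_labels=labels,
                     window_ms=tuple(window_ms))


def save_trialset(trials: TrialSet, path: str | Path) -> Path:
    path = Path(path)
    header = {
        "fs": trials.fs,
        "channel_labels": list(trials.channel_labels),
        "subject_id": trials.subject_id,
        "group_label": trials.group_label,
        "rejection_reasons": trials.rejection_reasons,
    }
    np.savez_compressed(
        path,
        data=trials.data,
        time_ms=trials.time_ms,
        kept_mask=trials.kept_mask,
        header=np.array(json.dumps(header)),
    )
    return path


def load_trialset(path: str | Path) -> TrialSet:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        return TrialSet(
            data=z["data"],
            time_ms=z["time_ms"],
            fs=header["fs"],
            channel_labels=tuple(header["channel_labels"]),
            kept_mask=z["kept_mask"],
            rejection_reasons=[list(r) for r in header["rejection_reasons"]],
            subject_id=header["subject_id"],
            group_label=header["group_label"],
        )
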