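#!/usr/bin/env python
"""Epoch every session (-300..+700 ms around target stimuli), apply the
DC baseline correction, and reject artifact trials by the three rules
(peak-to-peak > 200 uV, post-stimulus SD > 50 uV, NSR > 0.7).

Reads scratch/sessions/, writes epoched trials to scratch/trials/ and a
per-subject rejection summary to results/rejection_summary.tsv.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from oddballeeg import baseline_correct, extract_trials, reject_trials
from oddballeeg.io import read_session, save_trialset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out_dir = ROOT / "scratch" / "trials"
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for edf in sorted((ROOT / "scratch" / "sessions").glob("*.edf")):
        session, _ = read_session(edf)
        ts = reject_trials(baseline_correct(extract_trials(session)))
        save_trialset(ts, out_dir / f"{session.subject_id}.npz")
        reasons = Counter(r for rs in ts.rejection_reasons for r in rs)
        rows.append(
            {
                "subject": session.subject_id,
                "group": session.group_label,
                "n_trials": ts.n_trials,
                "n_kept": ts.n_kept,
                "n_p2p": reasons.get("p2p", 0),
                "n_sd": reasons.get("sd", 0),
                "n_nsr": reasons.get("nsr", 0),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "results" / "rejection_summary.tsv", sep="\t",
                   index=False)
    kept, total = summary.n_kept.sum(), summary.n_trials.sum()
    print(f"kept {kept}/{total} trials "
          f"({100 * (1 - kept / total):.1f}% rejected)")


if __name__ == "__main__":
    main()
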