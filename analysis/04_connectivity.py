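#!/usr/bin/env python
"""Inter-site phase clustering (ISPC) between every electrode pair in each
band: zero-phase band-pass, Hilbert phase, magnitude of the mean phase-
difference phasor across the trial window and trials.

Reads scratch/trials/, writes long-format connectivity values to
results/ispc_values.tsv.
"""

from pathlib import Path

import pandas as pd

from oddballeeg import analytic_phase, ispc_all
from oddballeeg.io import ispc_to_frame, load_trialset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    frames = []
    for path in sorted((ROOT / "scratch" / "trials").glob("*.npz")):
        ts = load_trialset(path)
        table = ispc_all(analytic_phase(ts))
        frames.append(ispc_to_frame(ts.subject_id, ts.group_label, table))
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(ROOT / "results" / "ispc_values.tsv", sep="\t", index=False)
    print(f"computed {len(long)} pairwise ISPC values")
    key = long[(long.band == "alpha")
               & (long[["ch_x", "ch_y"]].isin(["PO7"]).any(axis=1))
               & (long[["ch_x", "ch_y"]].isin(["CZ"]).any(axis=1))]
    print("alpha PO7<->CZ ISPC by group:")
    print(key.groupby("group")["ispc"].median().round(3))


if __name__ == "__main__":
    main()
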