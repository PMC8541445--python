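#!/usr/bin/env python
"""Biomarker selection and classification: nested stratified 4x3-fold
rank-sum selection repeated 25 times, a linear SVM on the most-selected
variable evaluated by leave-one-out cross-validation, and kernel density
curves of that variable per group.

Reads results/variable_table.tsv; writes results/classifier_report.json
and results/kde_density.tsv (pass --plot for a PNG under
results/figures/).
"""

import json
import sys
from pathlib import Path

import pandas as pd

from oddballeeg import kde_density, loocv_svm, select_variables
from oddballeeg.groupstats import VariableTable
from oddballeeg.montage import BAND_ORDER, CHANNELS
from oddballeeg.synthgen import GROUP_ALS, GROUP_CONTROL

ROOT = Path(__file__).resolve().parents[1]
SEED = 2021


def main() -> None:
    frame = pd.read_csv(ROOT / "results" / "variable_table.tsv", sep="\t",
                        index_col=0)
    table = VariableTable(frame, CHANNELS, BAND_ORDER)

    report = select_variables(table, seed=SEED)
    chosen = report.chosen[0]
    clf = loocv_svm(table, report.chosen, seed=SEED)
    print(f"selected variable: {chosen} "
          f"({report.counts.iloc[0]}/{report.total_folds} folds, "
          f"{'stable' if report.stable else 'unstable'})")
    print(f"LOOCV: sensitivity {clf.sensitivity:.0%}, "
          f"specificity {clf.specificity:.0%}, accuracy {clf.accuracy:.0%}")

    payload = {
        "chosen_variable": chosen,
        "selection_counts_top5": report.counts.head(5).to_dict(),
        "selection_stable": report.stable,
        "confusion": {"tp": clf.tp, "tn": clf.tn, "fp": clf.fp, "fn": clf.fn},
        "sensitivity": clf.sensitivity,
        "specificity": clf.specificity,
        "accuracy": clf.accuracy,
    }
    (ROOT / "results" / "classifier_report.json").write_text(
        json.dumps(payload, indent=1))

    values = {
        g: frame.loc[frame.group == g, chosen].to_numpy()
        for g in (GROUP_CONTROL, GROUP_ALS)
    }
    grid, dens = kde_density(values)
    kde = pd.DataFrame({"value": grid, **dens})
    kde.to_csv(ROOT / "results" / "kde_density.tsv", sep="\t", index=False)

    if "--plot" in sys.argv:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for g, d in dens.items():
            ax.plot(grid, d, label=g)
        ax.set_xlabel(chosen)
        ax.set_ylabel("density")
        ax.legend()
        fig_dir = ROOT / "results" / "figures"
        fig_dir.mkdir(exist_ok=True)
        fig.savefig(fig_dir / "kde_density.png", dpi=150,
                    bbox_inches="tight")
        print(f"figure written to {fig_dir / 'kde_density.png'}")


if __name__ == "__main__":
    main()
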