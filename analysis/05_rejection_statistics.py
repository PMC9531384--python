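#!/usr/bin/env python
"""Group comparisons, ROC analysis and marker correlations.

Merges the per-case tables written by the earlier steps, runs the full
statistical layer (t-tests and ROC under the clinical and biopsy dichotomies,
three-group ANOVA with trend check, Pearson marker correlations with and
without rejection cases, sensitivity at the 1050 ms peak-T1 cutoff), and
writes the structured report plus ROC curves for the headline discriminators.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cardiot1tex.stats import rejection_analysis, report_to_markdown, roc

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--no-figure", action="store_true")
    args = ap.parse_args()

    inputs = pd.read_csv(RESULTS / "cohort_inputs.csv").drop(
        columns=["mean_t1", "peak_t1", "n_abnormal_segments"]
    )
    t1 = pd.read_csv(RESULTS / "t1_metrics.csv").drop(columns=["group"])
    tex = pd.read_csv(RESULTS / "texture_features.csv").drop(columns=["group"])
    fib = pd.read_csv(RESULTS / "fibrosis.csv")[["case_id", "fibrosis_percent"]]
    table = (
        inputs.drop(columns=["fibrosis_percent"])
        .merge(t1, on="case_id").merge(tex, on="case_id").merge(fib, on="case_id")
    )

    report = rejection_analysis(table)
    (RESULTS / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (RESULTS / "report.md").write_text(report_to_markdown(report))

    clin = report["clinical_dichotomy"]
    print(f"analysed {report['n_cases']} cases -> results/report.md")
    for var in ("mean_t1", "peak_t1", "energy", "entropy", "variance"):
        d = clin[var]
        print(f"  {var:9s}: AUC {d['auc']:.3f} (p={d['auc_p']:.2g}, t-test p={d['p']:.2g})")
    pc = report["peak_t1_cutoff"]
    print(
        f"  peak T1 > {pc['cutoff_ms']:g} ms: sensitivity "
        f"{100 * pc['sensitivity']:.0f}%, specificity {100 * pc['specificity']:.0f}%"
    )

    if not args.no_figure:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rej = table["group"].isin(["B", "C"]).to_numpy()
        fig, ax = plt.subplots(figsize=(5, 5))
        for var in ("mean_t1", "peak_t1", "entropy", "variance", "energy"):
            r = roc(table[var].to_numpy(), rej, direction="auto")
            ax.plot(r.fpr, r.tpr, label=f"{var} (AUC {r.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=8)
        fig.tight_layout()
        figdir = RESULTS / "figures"
        figdir.mkdir(exist_ok=True)
        fig.savefig(figdir / "roc_clinical_rejection.png", dpi=150)
        print("  wrote results/figures/roc_clinical_rejection.png")


if __name__ == "__main__":
    main()
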