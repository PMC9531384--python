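#!/usr/bin/env python
"""Segmental native-T1 quantification for every simulated case.

Regenerates the cohort's image stacks from the seed, applies the 16-ROI
septal/lateral protocol (middle-third masks on the middle six slices), and
writes per-case global mean T1, peak T1 and abnormal-segment counts.
"""

import argparse
from pathlib import Path

import pandas as pd

from cardiot1tex.cohort import CohortSpec, generate_cohort
from cardiot1tex.segmental import build_study_masks, segmental_t1

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cases", type=int, default=50)
    args = ap.parse_args()

    spec = CohortSpec(n_cases=args.n_cases, seed=args.seed)
    studies, table = generate_cohort(spec)
    rois = build_study_masks(studies[0], spec.phantom)

    rows = []
    for study in studies:
        seg = segmental_t1(study, rois)
        rows.append(
            {
                "case_id": study.case_id,
                "mean_t1": seg.global_mean_t1,
                "peak_t1": seg.peak_t1,
                "n_abnormal_segments": seg.n_abnormal,
            }
        )
    df = pd.DataFrame(rows).merge(table[["case_id", "group"]], on="case_id")
    out = RESULTS / "t1_metrics.csv"
    df.to_csv(out, index=False, float_format="%.4f")

    print(f"quantified {len(df)} cases x 16 segments -> {out}")
    for g, sub in df.groupby("group"):
        print(
            f"  group {g}: mean T1 {sub['mean_t1'].mean():7.1f} ms, "
            f"peak T1 {sub['peak_t1'].mean():7.1f} ms, "
            f"abnormal segments/case {sub['n_abnormal_segments'].mean():.1f}"
        )


if __name__ == "__main__":
    main()
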