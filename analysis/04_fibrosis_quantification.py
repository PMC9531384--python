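#!/usr/bin/env python
"""Digital fibrosis quantification of per-case trichrome slides.

Renders one synthetic Masson-trichrome slide per case at its true collagen
fraction and measures percentage tissue fibrosis back with the blue-collagen
colorimetric rule, writing measured vs true values per case.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cardiot1tex.cohort import CohortSpec, generate_cohort
from cardiot1tex.histology import fibrosis_percentage
from cardiot1tex.phantom import generate_trichrome_image

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cases", type=int, default=50)
    ap.add_argument("--slide-size", type=int, default=192)
    args = ap.parse_args()

    spec = CohortSpec(n_cases=args.n_cases, seed=args.seed)
    _, table = generate_cohort(spec)
    rng = np.random.default_rng(args.seed + 10_000)

    rows = []
    for case_id, true_pct in zip(table["case_id"], table["fibrosis_percent"]):
        img, _ = generate_trichrome_image(
            true_pct / 100.0, size=args.slide_size, seed=rng.integers(2**31)
        )
        res = fibrosis_percentage(img)
        rows.append(
            {
                "case_id": case_id,
                "fibrosis_true_percent": true_pct,
                "fibrosis_percent": res.fibrosis_percent,
                "n_collagen": res.n_collagen,
                "n_tissue": res.n_tissue,
            }
        )
    df = pd.DataFrame(rows).merge(table[["case_id", "group"]], on="case_id")
    out = RESULTS / "fibrosis.csv"
    df.to_csv(out, index=False, float_format="%.4f")

    err = (df["fibrosis_percent"] - df["fibrosis_true_percent"]).abs().max()
    rej = df["group"].isin(["B", "C"])
    print(f"measured fibrosis on {len(df)} slides -> {out}")
    print(f"  max |measured - true| = {err:.3f} percentage points")
    print(
        f"  no-rejection {df.loc[~rej, 'fibrosis_percent'].mean():.1f}%  "
        f"rejection {df.loc[rej, 'fibrosis_percent'].mean():.1f}%  "
        "(drawn independent of group)"
    )


if __name__ == "__main__":
    main()
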