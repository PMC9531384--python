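"""Group comparison, correlation and ROC statistics for the rejection study.

The cohort table has one row per case: outcome group A (no rejection), B
(mild rejection, maintenance therapy augmented) or C (acute rejection, new
therapy), biopsy grade (0R/1R/2R), T1 metrics, texture features, fibrosis
percentage and graft-dysfunction markers.  Rejection is analysed under two
dichotomies: clinical (A vs B+C) and histological (grade 0R vs >=1R).

Test choices mirror the source protocol: pooled-variance Student's t (Welch
behind a flag), one-way ANOVA across the three groups, Pearson correlation
against markers, empirical ROC curves with AUC significance from the
tie-corrected Mann-Whitney normal approximation, and sensitivity at the
institutional peak-T1 cutoff with a strict ``>`` convention.  No multiple
-testing correction is applied; p-values are reported raw and labelled so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "MARKER_COLUMNS",
    "TEXTURE_COLUMNS",
    "TwoGroupResult",
    "ROCResult",
    "two_group_test",
    "one_way_anova",
    "pearson",
    "roc",
    "rejection_analysis",
    "report_to_markdown",
]

MARKER_COLUMNS = (
    "bnp_pg_ml",
    "lvef_percent",
    "mitral_e_over_eprime",
    "ra_mean_mmhg",
    "rv_systolic_mmhg",
    "rvedp_mmhg",
    "pa_mean_mmhg",
    "wedge_mmhg",
    "lvedv_ml",
    "rvedv_ml",
)

TEXTURE_COLUMNS = (
    "energy",
    "contrast",
    "entropy",
    "homogeneity",
    "correlation",
    "sum_average",
    "variance",
    "dissimilarity",
    "autocorrelation",
)


@dataclass
class TwoGroupResult:
    t: float
    p: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int
    method: str = "Student t (pooled variance), two-sided"


def two_group_test(x, y, equal_var: bool = True) -> TwoGroupResult:
    """Two-sided two-sample t-test with group summaries (mean +/- SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x.mean() == y.mean():
            # identical constants: no evidence of difference, by convention
            return TwoGroupResult(0.0, 1.0, x.mean(), y.mean(), 0.0, 0.0, x.size, y.size)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    method = "Student t (pooled variance), two-sided" if equal_var else "Welch t, two-sided"
    return TwoGroupResult(
        t=float(t),
        p=float(p),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)),
        sd_y=float(y.std(ddof=1)),
        n_x=x.size,
        n_y=y.size,
        method=method,
    )


def one_way_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects F test across >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    n_total = sum(a.size for a in arrays)
    if n_total - len(arrays) < 1 or any(a.size < 1 for a in arrays):
        raise ValueError("not enough observations for ANOVA")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0  # all observations identical: no between- or within-group variance
    F, p = sps.f_oneway(*arrays)
    return float(F), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ROCResult:
    """Empirical ROC curve with Mann-Whitney AUC and significance."""

    auc: float
    p_value: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    direction: str  # "high" = positive class scores higher on the original scale
    _scores: np.ndarray = field(repr=False, default=None)
    _labels: np.ndarray = field(repr=False, default=None)

    def sensitivity_at(self, threshold: float) -> float:
        """True-positive rate of the rule ``score > threshold`` (original scale)."""
        pos = self._scores[self._labels]
        return float(np.mean(pos > threshold))

    def specificity_at(self, threshold: float) -> float:
        neg = self._scores[~self._labels]
        return float(np.mean(neg <= threshold))


def roc(scores, labels, direction: str = "high") -> ROCResult:
    """ROC curve and AUC for a continuous score against binary labels.

    ``direction="high"`` treats higher scores as positive; ``"low"`` negates
    the score first (used for features depressed in the positive class, e.g.
    GLCM energy in rejection) so the reported AUC is >= 0.5 when the effect
    runs that way; ``"auto"`` picks the direction from the observed class
    means and records it.  Ties receive half credit (Mann-Whitney AUC); the
    p-value tests AUC != 0.5 via the tie-corrected normal approximation.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if s.size != lab.size:
        raise ValueError("scores and labels must be the same length")
    if lab.all() or not lab.any():
        raise ValueError("ROC requires both classes present")
    if direction == "auto":
        direction = "high" if s[lab].mean() >= s[~lab].mean() else "low"
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high', 'low' or 'auto'")
    oriented = s if direction == "high" else -s

    auc = float(roc_auc_score(lab, oriented))
    fpr, tpr, thr = roc_curve(lab, oriented, drop_intermediate=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact-tie warnings on degenerate scores
        mw = sps.mannwhitneyu(
            oriented[lab], oriented[~lab], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
    return ROCResult(
        auc=auc,
        p_value=float(mw.pvalue),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        direction=direction,
        _scores=s,
        _labels=lab,
    )


def _clinical_labels(table: pd.DataFrame) -> np.ndarray:
    return table["group"].isin(["B", "C"]).to_numpy()


def _biopsy_labels(table: pd.DataFrame) -> np.ndarray:
    return (table["biopsy_grade"] != "0R").to_numpy()


def _two_group_block(table: pd.DataFrame, labels: np.ndarray, variables) -> dict:
    out: dict[str, dict] = {}
    for var in variables:
        x = table.loc[~labels, var].to_numpy()
        y = table.loc[labels, var].to_numpy()
        tt = two_group_test(x, y)
        rr = roc(table[var].to_numpy(), labels, direction="auto")
        out[var] = {
            "negative_mean": tt.mean_x,
            "negative_sd": tt.sd_x,
            "positive_mean": tt.mean_y,
            "positive_sd": tt.sd_y,
            "t": tt.t,
            "p": tt.p,
            "auc": rr.auc,
            "auc_p": rr.p_value,
            "roc_direction": rr.direction,
        }
    return out


def rejection_analysis(
    table: pd.DataFrame,
    peak_t1_cutoff: float = 1050.0,
    markers: tuple[str, ...] | None = None,
) -> dict:
    """The full statistical layer of the study, as one structured report.

    Runs, for mean T1, peak T1, each texture feature and fibrosis %:
    pooled t-tests and ROC under the clinical (A vs B+C) and biopsy
    (0R vs >=1R) dichotomies; one-way ANOVA and a monotone group-mean trend
    check across A/B/C; Pearson correlations (and supplementary least-squares
    fits) of mean/peak T1 against each marker on the full cohort and on the
    rejection-free subset; and sensitivity/specificity of peak T1 at the
    institutional cutoff.  Raises ``KeyError`` naming any missing column.
    """
    required = ["group", "biopsy_grade", "mean_t1", "peak_t1", "fibrosis_percent"]
    texture_vars = [c for c in TEXTURE_COLUMNS if c in table.columns]
    if markers is None:
        markers = tuple(c for c in MARKER_COLUMNS if c in table.columns)
    missing = [c for c in required + list(markers) if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")

    continuous = ["mean_t1", "peak_t1"] + texture_vars + ["fibrosis_percent"]
    clinical = _clinical_labels(table)
    biopsy = _biopsy_labels(table)

    report: dict = {
        "n_cases": int(len(table)),
        "group_counts": table["group"].value_counts().to_dict(),
        "caveats": [
            "p-values are raw (no multiple-testing correction applied)",
            "cases are treated as independent even when one patient "
            "contributes repeat encounters",
        ],
    }

    report["clinical_dichotomy"] = _two_group_block(table, clinical, continuous)
    if biopsy.any() and not biopsy.all():
        report["biopsy_dichotomy"] = _two_group_block(table, biopsy, continuous)
    else:
        report["biopsy_dichotomy"] = {"skipped": "only one biopsy class present"}

    anova: dict[str, dict] = {}
    trend: dict[str, dict] = {}
    groups = [table.loc[table["group"] == g] for g in ("A", "B", "C")]
    for var in ["mean_t1", "peak_t1"] + texture_vars:
        F, p = one_way_anova([g[var].to_numpy() for g in groups])
        means = [float(g[var].mean()) for g in groups]
        anova[var] = {"F": F, "p": p, "group_means": dict(zip("ABC", means))}
        trend[var] = {
            "monotone_increasing": bool(means[0] < means[1] < means[2]),
            "monotone_decreasing": bool(means[0] > means[1] > means[2]),
        }
    report["anova"] = anova
    report["group_trend"] = trend

    def _marker_block(sub: pd.DataFrame) -> dict:
        block: dict[str, dict] = {}
        for t1_var in ("mean_t1", "peak_t1"):
            for mk in markers:
                r, p = pearson(sub[t1_var], sub[mk])
                ls = sps.linregress(sub[t1_var], sub[mk])
                block[f"{t1_var}_vs_{mk}"] = {
                    "r": r,
                    "p": p,
                    "slope": float(ls.slope),
                    "intercept": float(ls.intercept),
                    "r_squared": float(ls.rvalue**2),
                }
        return block

    report["marker_correlations"] = {"all_cases": _marker_block(table)}
    no_rejection = table.loc[~clinical]
    if len(no_rejection) >= 3:
        report["marker_correlations"]["rejection_excluded"] = _marker_block(no_rejection)

    peak_roc = roc(table["peak_t1"].to_numpy(), clinical, direction="high")
    report["peak_t1_cutoff"] = {
        "cutoff_ms": peak_t1_cutoff,
        "sensitivity": peak_roc.sensitivity_at(peak_t1_cutoff),
        "specificity": peak_roc.specificity_at(peak_t1_cutoff),
        "rule": f"positive if peak T1 > {peak_t1_cutoff} ms (strict)",
    }
    return report


def report_to_markdown(report: dict) -> str:
    """Human-readable summary of a rejection_analysis report."""
    lines = ["# Rejection analysis report", ""]
    lines.append(f"Cases: {report['n_cases']}  (groups: {report['group_counts']})")
    lines.append("")
    for dich in ("clinical_dichotomy", "biopsy_dichotomy"):
        block = report[dich]
        title = "A vs B+C (clinical)" if dich == "clinical_dichotomy" else "0R vs >=1R (biopsy)"
        lines.append(f"## Two-group comparisons — {title}")
        if "skipped" in block:
            lines.append(f"_{block['skipped']}_")
            lines.append("")
            continue
        lines.append("")
        lines.append("| variable | negative (mean ± SD) | positive (mean ± SD) | t | p | AUC | AUC p | direction |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for var, d in block.items():
            lines.append(
                f"| {var} | {d['negative_mean']:.3g} ± {d['negative_sd']:.3g} "
                f"| {d['positive_mean']:.3g} ± {d['positive_sd']:.3g} "
                f"| {d['t']:.3f} | {d['p']:.4g} | {d['auc']:.3f} | {d['auc_p']:.4g} "
                f"| {d['roc_direction']} |"
            )
        lines.append("")
    lines.append("## ANOVA across groups A/B/C")
    lines.append("")
    lines.append("| variable | F | p | mean A | mean B | mean C |")
    lines.append("|---|---|---|---|---|---|")
    for var, d in report["anova"].items():
        gm = d["group_means"]
        lines.append(
            f"| {var} | {d['F']:.3f} | {d['p']:.4g} | {gm['A']:.4g} | {gm['B']:.4g} | {gm['C']:.4g} |"
        )
    lines.append("")
    lines.append("## Correlations of T1 with graft-dysfunction markers")
    lines.append("")
    for subset, block in report["marker_correlations"].items():
        lines.append(f"### {subset}")
        lines.append("")
        lines.append("| pair | r | p |")
        lines.append("|---|---|---|")
        for pair, d in block.items():
            lines.append(f"| {pair} | {d['r']:.3f} | {d['p']:.4g} |")
        lines.append("")
    pc = report["peak_t1_cutoff"]
    lines.append("## Peak T1 cutoff")
    lines.append("")
    lines.append(
        f"Sensitivity at peak T1 > {pc['cutoff_ms']:g} ms: {100 * pc['sensitivity']:.1f}% "
        f"(specificity {100 * pc['specificity']:.1f}%)"
    )
    lines.append("")
    lines.append("Caveats: " + "; ".join(report["caveats"]))
    lines.append("")
    return "\n".join(lines)
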