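"""Synthetic study cohorts with the statistical structure of the rejection study.

A cohort is a set of cases split into outcome groups A (no rejection), B
(mild rejection) and C (acute rejection) in a 74/12/14 split by default.
Normal myocardium is spatially smooth at map resolution (correlated noise).
Rejection cases get (i) a diffuse, pixel-scale heterogeneous T1 elevation
over the whole myocardium whose mean equals the group shift — patchy
inflammation raises T1 on average but unevenly — and (ii) at least one focal
raised-cosine hotspot centred on an analysed (septal or lateral) segment, so
both the 16-ROI segmental protocol and the mid-slice texture analysis can
see the lesion.  This construction makes rejection maps more heterogeneous
(higher GLCM entropy/variance, lower energy) as well as globally elevated.
Graft-dysfunction markers are linear functions of the realized peak T1 plus
Gaussian noise calibrated to a target Pearson correlation; biopsy fibrosis
percentage is drawn independently of group, emulating the study's null
finding for random right-ventricular sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import T1Study
from .phantom import HotspotSpec, PhantomConfig, generate_t1_study
from .segmental import build_study_masks, segmental_t1

__all__ = ["CohortSpec", "MarkerModel", "MARKER_MODELS", "generate_cohort"]


@dataclass(frozen=True)
class MarkerModel:
    """Population location/scale and correlation sign of one marker."""

    name: str
    mean: float
    sd: float
    sign: int  # +1: marker rises with peak T1, -1: falls


# Location/scale loosely matched to the cohort demographics table of a
# pediatric transplant surveillance population; signs follow the observed
# direction of each marker's association with peak T1.
MARKER_MODELS: tuple[MarkerModel, ...] = (
    MarkerModel("bnp_pg_ml", 780.0, 1400.0, +1),
    MarkerModel("lvef_percent", 63.0, 5.0, -1),
    MarkerModel("mitral_e_over_eprime", 8.0, 2.0, -1),
    MarkerModel("ra_mean_mmhg", 10.0, 4.0, +1),
    MarkerModel("rv_systolic_mmhg", 28.0, 5.0, +1),
    MarkerModel("rvedp_mmhg", 11.0, 4.0, +1),
    MarkerModel("pa_mean_mmhg", 20.0, 5.0, +1),
    MarkerModel("wedge_mmhg", 12.0, 5.0, +1),
    MarkerModel("lvedv_ml", 110.0, 30.0, -1),
    MarkerModel("rvedv_ml", 115.0, 30.0, -1),
)

# Biopsy-grade mixtures per outcome group (clinical rejection is defined by
# treatment, not grade, so group A contains some 1R and groups B/C some 0R).
_GRADE_PROBS = {
    "A": (("0R", 0.84), ("1R", 0.16)),
    "B": (("0R", 0.29), ("1R", 0.71)),
    "C": (("1R", 0.67), ("2R", 0.33)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a simulated cohort."""

    n_cases: int = 50
    group_fractions: tuple[float, float, float] = (0.74, 0.12, 0.14)
    group_t1_shift: tuple[float, float, float] = (0.0, 40.0, 80.0)
    hotspot_rate: tuple[float, float, float] = (0.0, 2.0, 3.0)
    # optional per-group multiplier on the pixel noise SD (additional diffuse
    # edema severity); 1.0 leaves the scanner noise model untouched
    group_noise_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    marker_correlation: float = 0.45
    fibrosis_mean: float = 7.6
    fibrosis_sd: float = 4.7
    seed: int = 0
    phantom: PhantomConfig = field(
        default_factory=lambda: PhantomConfig(noise_correlation_px=2.0)
    )

    def __post_init__(self) -> None:
        if self.n_cases < 3:
            raise ValueError("n_cases must be at least 3")
        fr = np.asarray(self.group_fractions, dtype=float)
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("group_fractions must be nonnegative and sum to 1")
        if not -1.0 <= self.marker_correlation <= 1.0:
            raise ValueError("marker_correlation must be in [-1, 1]")


def _group_counts(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of n cases over the three groups."""
    quotas = np.asarray(fractions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts))
    for k in range(remainder):
        counts[order[k]] += 1
    return counts.tolist()


def _analysis_slice_indices(config: PhantomConfig) -> list[int]:
    from .core import middle_six_levels

    levels = middle_six_levels(config.n_slices)
    return [i for i, lvl in enumerate(levels) if lvl != "excluded"]


def _draw_hotspots(
    rng: np.random.Generator, config: PhantomConfig, rate: float, shift: float
) -> list[list[HotspotSpec]]:
    """Lesion burden for one rejection case, mapped onto the per-slice lists.

    ``shift`` > 0 adds the diffuse component on every slice: a whole-annulus
    pixel-scale heterogeneous elevation, Uniform(0.05, 1.95) x shift per
    pixel, so the mean myocardial elevation equals the group shift.  The
    first ("primary") focal hotspot is centred near an analysed segment
    centre with a wide core, guaranteeing a segmental middle-third elevation
    well above the abnormality cutoff; further hotspots are placed freely,
    so lesions vary in position, extent and amplitude across cases.
    """
    per_slice: list[list[HotspotSpec]] = [[] for _ in range(config.n_slices)]
    if shift > 0:
        diffuse = HotspotSpec(
            center_angle=0.0,
            angular_width=360.0,
            radial_span=1.0,
            delta_t1=shift,
            skirt_width=0.0,
            interior_spread=0.95,
        )
        for lst in per_slice:
            lst.append(diffuse)
    if rate <= 0:
        return per_slice
    n_hot = 1 + int(rng.poisson(max(rate - 1.0, 0.0)))
    analysed = _analysis_slice_indices(config)
    segment_centers = [
        (config.septal_center + 30.0) % 360.0,
        (config.septal_center - 30.0) % 360.0,
        config.lateral_center,
    ]
    for k in range(n_hot):
        if k == 0:
            center = rng.choice(segment_centers) + rng.uniform(-15.0, 15.0)
            spec = HotspotSpec(
                center_angle=center % 360.0,
                angular_width=rng.uniform(90.0, 120.0),
                radial_span=rng.uniform(0.75, 1.0),
                delta_t1=rng.uniform(100.0, 180.0),
                skirt_width=rng.uniform(30.0, 50.0),
                interior_spread=rng.uniform(0.5, 0.8),
            )
        else:
            spec = HotspotSpec(
                center_angle=rng.uniform(0.0, 360.0),
                angular_width=rng.uniform(60.0, 120.0),
                radial_span=rng.uniform(0.5, 1.0),
                delta_t1=rng.uniform(40.0, 140.0),
                skirt_width=rng.uniform(20.0, 40.0),
                interior_spread=rng.uniform(0.5, 0.8),
            )
        run = int(rng.integers(2, 5))  # lesion spans 2-4 contiguous slices
        start = int(rng.integers(0, len(analysed)))
        for pos in range(start, min(start + run, len(analysed))):
            per_slice[analysed[pos]].append(spec)
    return per_slice


def _draw_markers(
    rng: np.random.Generator, peak_t1: np.ndarray, target_r: float
) -> pd.DataFrame:
    """Markers as linear functions of realized peak T1 plus calibrated noise.

    marker = mean + sd * (sign*r*z + sqrt(1-r^2)*eps) with z the
    standardized peak T1, so the population correlation equals the target.
    """
    sd_t = peak_t1.std()
    z = (peak_t1 - peak_t1.mean()) / sd_t if sd_t > 0 else np.zeros_like(peak_t1)
    cols = {}
    for mk in MARKER_MODELS:
        eps = rng.standard_normal(peak_t1.size)
        signal = mk.sign * target_r * z
        cols[mk.name] = mk.mean + mk.sd * (signal + np.sqrt(1.0 - target_r**2) * eps)
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> tuple[list[T1Study], pd.DataFrame]:
    """Generate the image studies and the cohort table for one simulated study.

    Fully reproducible from ``spec.seed``; each case's image stack has its
    own derived seed so cases can be regenerated independently.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    case_seeds = ss.spawn(spec.n_cases)

    counts = _group_counts(spec.n_cases, spec.group_fractions)
    if any(c == 0 for c in counts):
        warnings.warn(
            f"cohort of {spec.n_cases} cases cannot realize all groups "
            f"(counts {counts}); proceeding",
            stacklevel=2,
        )
    labels = np.repeat(list("ABC"), counts)
    rng.shuffle(labels)

    shift = dict(zip("ABC", spec.group_t1_shift))
    rate = dict(zip("ABC", spec.hotspot_rate))
    noise_scale = dict(zip("ABC", spec.group_noise_scale))

    # segment masks depend only on geometry, so build them once from a
    # template study and reuse across cases
    template = generate_t1_study(spec.phantom, seed=ss.spawn(1)[0])
    rois = build_study_masks(template, spec.phantom)

    studies: list[T1Study] = []
    rows = []
    for i, group in enumerate(labels):
        case_id = f"case{i:03d}"
        config = replace(
            spec.phantom, noise_sd=spec.phantom.noise_sd * noise_scale[group]
        )
        hotspots = _draw_hotspots(rng, config, rate[group], shift[group])
        study = generate_t1_study(config, hotspots, seed=case_seeds[i], case_id=case_id)
        studies.append(study)
        seg = segmental_t1(study, rois)

        grades, probs = zip(*_GRADE_PROBS[group])
        grade = rng.choice(grades, p=probs)
        fibrosis = float(np.clip(rng.normal(spec.fibrosis_mean, spec.fibrosis_sd), 0.2, 40.0))
        rows.append(
            {
                "case_id": case_id,
                "group": group,
                "biopsy_grade": grade,
                "mean_t1": seg.global_mean_t1,
                "peak_t1": seg.peak_t1,
                "n_abnormal_segments": seg.n_abnormal,
                "fibrosis_percent": fibrosis,
            }
        )

    table = pd.DataFrame(rows)
    markers = _draw_markers(rng, table["peak_t1"].to_numpy(), spec.marker_correlation)
    table = pd.concat([table, markers], axis=1)
    return studies, table
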