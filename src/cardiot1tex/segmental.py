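"""Segmental native-T1 quantification on the AHA 17-segment layout.

The protocol measures septal and lateral wall only (anterior and inferior
sectors are skipped to avoid partial-volume effects): on each of the middle
six slices of the stack, basal and mid levels contribute two septal segments
(AHA 2/3 and 8/9) plus one combined lateral region (5+6 and 11+12), apical
levels one septal (14) and one lateral (16) region — 16 regional means per
study.  Each ROI is restricted to the radial middle third of the wall before
averaging.  Global mean T1 is the unweighted mean of the 16 segmental
values, peak T1 their maximum, and a segment is abnormal when its value
strictly exceeds the upper normal bound (default 1050 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NormalRange, T1Map, T1Study, in_angular_window, polar_grid

__all__ = [
    "SegmentROI",
    "SegmentalT1Result",
    "ICCResult",
    "build_segment_masks",
    "build_study_masks",
    "extract_middle_third",
    "segmental_t1",
    "interobserver_icc",
]


@dataclass
class SegmentROI:
    """One segmental region of interest on one slice."""

    segment_id: str  # AHA label: 2, 3, 5+6, 8, 9, 11+12, 14, 16
    slice_index: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(
                f"empty mask for segment {self.segment_id} on slice {self.slice_index}"
            )


@dataclass
class SegmentalT1Result:
    """16 segmental means plus the derived global metrics."""

    segmental_means: dict[tuple[int, str], float]
    global_mean_t1: float
    peak_t1: float
    abnormal_flags: dict[tuple[int, str], bool]
    n_abnormal: int
    normal_range: NormalRange
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "slice_index": sl,
                "segment_id": seg,
                "t1_ms": val,
                "abnormal": self.abnormal_flags[(sl, seg)],
            }
            for (sl, seg), val in self.segmental_means.items()
        ]
        return pd.DataFrame(rows)


# AHA segment labels by slice level; septal halves first (towards anterior,
# then towards inferior), lateral region last.
_LEVEL_SEGMENTS = {
    "basal": ("2", "3", "5+6"),
    "mid": ("8", "9", "11+12"),
    "apical": ("14", "16"),
}


def build_segment_masks(t1map: T1Map, geometry) -> list[SegmentROI]:
    """Full-wall segment masks for one phantom slice.

    ``geometry`` is the :class:`~cardiot1tex.phantom.PhantomConfig` that
    produced the slice.  For real clinical images, user-drawn label rasters
    replace this constructor (see :func:`segmental_t1`, which accepts any
    ROI list).  Basal/mid slices yield 3 ROIs, apical slices 2; the anterior
    and inferior sectors are excluded by construction.
    """
    if t1map.slice_level == "excluded":
        raise ValueError("cannot build segment masks for an excluded slice")
    shape = t1map.pixels.shape
    radius, theta = polar_grid(shape, geometry.center_rc)
    annulus = (radius >= geometry.endo_radius) & (radius < geometry.epi_radius)

    cs = geometry.septal_center
    cl = geometry.lateral_center
    level = t1map.slice_level
    labels = _LEVEL_SEGMENTS[level]
    rois: list[SegmentROI] = []
    if level in ("basal", "mid"):
        sectors = [
            (labels[0], (cs + 30.0) % 360.0, 60.0),  # anteroseptal half
            (labels[1], (cs - 30.0) % 360.0, 60.0),  # inferoseptal half
            (labels[2], cl, 120.0),  # combined lateral region
        ]
    else:
        sectors = [(labels[0], cs, 120.0), (labels[1], cl, 120.0)]
    for seg_id, center_angle, width in sectors:
        mask = annulus & in_angular_window(theta, center_angle, width)
        rois.append(SegmentROI(segment_id=seg_id, slice_index=t1map.slice_index, mask=mask))
    return rois


def extract_middle_third(
    roi: SegmentROI,
    endo_radius: float,
    epi_radius: float,
    center: tuple[float, float],
) -> SegmentROI:
    """Restrict a wall ROI to the radial middle third of the wall.

    Keeps pixels with endo + w/3 <= r < endo + 2w/3 (w = epi - endo); avoids
    blood-pool contamination at the endocardial border and partial-volume
    artifact at the epicardium.
    """
    radius, _ = polar_grid(roi.mask.shape, center)
    if np.any(roi.mask & ((radius < endo_radius - 0.5) | (radius >= epi_radius + 0.5))):
        raise ValueError("ROI mask extends outside the endo/epi annulus")
    w = epi_radius - endo_radius
    band = (radius >= endo_radius + w / 3.0) & (radius < endo_radius + 2.0 * w / 3.0)
    new_mask = roi.mask & band
    if not new_mask.any():
        raise ValueError(
            f"middle third of segment {roi.segment_id} is empty: "
            "wall too thin at this resolution"
        )
    return SegmentROI(segment_id=roi.segment_id, slice_index=roi.slice_index, mask=new_mask)


def build_study_masks(
    study: T1Study, geometry, middle_third: bool = True
) -> list[SegmentROI]:
    """All 16 middle-third ROIs for a tagged middle-six study."""
    study.validate_middle_six()
    rois: list[SegmentROI] = []
    for m in study.analysis_maps:
        for roi in build_segment_masks(m, geometry):
            if middle_third:
                roi = extract_middle_third(
                    roi, geometry.endo_radius, geometry.epi_radius, geometry.center_rc
                )
            rois.append(roi)
    return rois


def segmental_t1(
    study: T1Study,
    rois: list[SegmentROI],
    normal: NormalRange = NormalRange(),
) -> SegmentalT1Result:
    """Segmental means over the 16 ROIs and the derived global mean/peak.

    ROIs are assumed already restricted to the middle third (or, for
    user-drawn clinical masks, traced with that technique); when the
    restriction was applied by this package it is recorded in provenance.
    """
    if len(rois) != 16:
        raise ValueError(f"expected exactly 16 ROIs, got {len(rois)}")
    maps_by_index = {m.slice_index: m for m in study.analysis_maps}
    means: dict[tuple[int, str], float] = {}
    for roi in rois:
        if roi.slice_index not in maps_by_index:
            raise ValueError(f"ROI references slice {roi.slice_index} not tagged for analysis")
        pixels = maps_by_index[roi.slice_index].pixels
        if not roi.mask.any():
            raise ValueError("empty ROI mask")
        key = (roi.slice_index, roi.segment_id)
        if key in means:
            raise ValueError(f"duplicate ROI for {key}")
        means[key] = float(pixels[roi.mask].mean())

    values = np.array(list(means.values()))
    flags = {k: bool(v > normal.upper) for k, v in means.items()}
    return SegmentalT1Result(
        segmental_means=means,
        global_mean_t1=float(values.mean()),
        peak_t1=float(values.max()),
        abnormal_flags=flags,
        n_abnormal=int(sum(flags.values())),
        normal_range=normal,
        provenance={"n_rois": 16, "abnormal_rule": f"value > {normal.upper} ms (strict)"},
    )


@dataclass
class ICCResult:
    """Single-measure absolute-agreement ICC (two-way random effects)."""

    icc: float
    ci95: tuple[float, float]
    form: str = "ICC2 (two-way random effects, absolute agreement, single measure)"
    n: int = 0


def interobserver_icc(reader1, reader2) -> ICCResult:
    """Interobserver agreement between two readers' paired measurements."""
    x = np.asarray(reader1, dtype=float)
    y = np.asarray(reader2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("readers must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("ICC undefined: zero variance in both readers")

    import pingouin as pg  # deferred: pingouin import is slow

    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["r1", "r2"], n),
            "rating": np.concatenate([x, y]),
        }
    )
    table = pg.intraclass_corr(
        data=df, targets="target", raters="rater", ratings="rating"
    ).set_index("Type")
    # absolute-agreement single-measure row; label differs across pingouin versions
    label = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    return ICCResult(icc=float(row["ICC"]), ci95=tuple(row[ci_col]), n=n)
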