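"""GLCM texture analysis of a segmented myocardial T1 map.

Workflow: Otsu-threshold the map to isolate the myocardial annulus (blood
pool and background removed, one-pixel erosion at the epicardial border),
min-max normalize the in-mask T1 values to 256 gray levels, accumulate a
256x256 gray-level co-occurrence matrix over unit-distance offsets, and
reduce it to nine scalar features: energy, contrast, entropy, homogeneity,
correlation, sum average, variance, dissimilarity and autocorrelation.

Conventions that the literature leaves open are explicit parameters and are
recorded in each result's provenance: offsets (default the four unit
directions, symmetric, pooled into one matrix), entropy log base (default
2), homogeneity kernel (default 1/(1+|i-j|)), and level indexing (0..255, so
sum average ranges over k = 0..510).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .core import T1Map

__all__ = [
    "MyocardiumMask",
    "QuantizedImage",
    "GLCM",
    "TextureFeatures",
    "DEFAULT_OFFSETS",
    "otsu_threshold",
    "segment_myocardium",
    "normalize_intensities",
    "compute_glcm",
    "glcm_features",
]

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


def otsu_threshold(values) -> float:
    """Otsu's threshold: the cut maximizing between-class variance.

    Works on the exact value histogram (no binning).  Returns the midpoint
    between the last value of the low class and the first value of the high
    class; classification is ``value > threshold``.  Ties are broken towards
    the lowest maximizing cut.
    """
    v = np.asarray(values, dtype=float).ravel()
    uniq, counts = np.unique(v, return_counts=True)
    if uniq.size < 2:
        raise ValueError("Otsu threshold undefined for constant input")
    w = counts / counts.sum()
    cum_w = np.cumsum(w)[:-1]  # weight of class <= uniq[k]
    cum_mean = np.cumsum(w * uniq)
    mu_total = cum_mean[-1]
    mu0 = cum_mean[:-1] / cum_w
    mu1 = (mu_total - cum_mean[:-1]) / (1.0 - cum_w)
    between = cum_w * (1.0 - cum_w) * (mu0 - mu1) ** 2
    k = int(np.argmax(between))
    return float((uniq[k] + uniq[k + 1]) / 2.0)


@dataclass
class MyocardiumMask:
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty myocardium mask")


def segment_myocardium(t1map: T1Map, geometry_hint=None) -> MyocardiumMask:
    """Semiautomatic LV myocardium segmentation by two-stage Otsu thresholding.

    Stage 1 separates body from background; stage 2 separates myocardium
    (lower T1) from blood pool (higher T1) within the body.  The largest
    connected myocardial component is kept and a one-pixel erosion is
    applied at its outer (epicardial) boundary only, mirroring the careful
    exclusion of epicardial myocardium; the endocardial border is untouched.
    ``geometry_hint`` is unused for phantoms but kept for API symmetry with
    clinical images.
    """
    img = t1map.pixels
    t_background = otsu_threshold(img)
    body = img > t_background
    if not body.any():
        raise ValueError("no foreground found")
    t_blood = otsu_threshold(img[body])
    myo = body & (img <= t_blood)

    labels, n_comp = ndimage.label(myo)
    if n_comp == 0:
        raise ValueError("no myocardial component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    myo = labels == (1 + int(np.argmax(sizes)))

    filled = ndimage.binary_fill_holes(myo)
    if not (filled & ~myo).any():
        raise ValueError("no annular myocardial component found (no enclosed blood pool)")
    eroded_outer = ndimage.binary_erosion(filled)
    mask = myo & eroded_outer
    if not mask.any():
        raise ValueError("myocardium vanished after epicardial erosion")
    return MyocardiumMask(
        mask=mask,
        provenance={
            "background_threshold": t_background,
            "blood_threshold": t_blood,
            "steps": [
                "otsu background/body",
                "otsu myocardium/blood",
                "largest component",
                "1-px epicardial erosion",
            ],
        },
    )


@dataclass
class QuantizedImage:
    """In-mask intensities mapped onto integer gray levels 0..n_levels-1."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int = 256
    scaling: tuple[float, float] = (0.0, 0.0)
    degenerate: bool = False


def normalize_intensities(
    t1map: T1Map, mask: MyocardiumMask | np.ndarray, n_levels: int = 256
) -> QuantizedImage:
    """Min-max quantization of in-mask values to ``n_levels`` gray levels.

    level = floor((n_levels-1) * (v - min) / (max - min)), computed within
    the mask; the in-mask maximum maps to n_levels-1.  A constant region
    degenerates to all-zero levels with ``degenerate=True`` recorded.
    """
    m = mask.mask if isinstance(mask, MyocardiumMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    v = t1map.pixels[m]
    vmin, vmax = float(v.min()), float(v.max())
    levels = np.zeros(t1map.pixels.shape, dtype=np.int32)
    degenerate = vmax == vmin
    if not degenerate:
        scaled = (n_levels - 1) * (t1map.pixels[m] - vmin) / (vmax - vmin)
        levels[m] = np.clip(np.floor(scaled).astype(np.int32), 0, n_levels - 1)
    return QuantizedImage(
        levels=levels, mask=m, n_levels=n_levels, scaling=(vmin, vmax), degenerate=degenerate
    )


@dataclass
class GLCM:
    """Normalized co-occurrence probability matrix with its provenance."""

    P: np.ndarray
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool
    n_pairs: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("GLCM must be square")
        if abs(self.P.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM entries must sum to 1")
        if self.n_pairs <= 0:
            raise ValueError("GLCM built from zero pairs")


def compute_glcm(
    q: QuantizedImage,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCM:
    """Accumulate the co-occurrence matrix over all offsets.

    Only pairs with *both* pixels in-mask are counted (no padding, so
    background never leaks into myocardial texture).  In symmetric mode each
    pair contributes to (i, j) and (j, i).
    """
    n = q.n_levels
    lv = q.levels
    m = q.mask
    counts = np.zeros(n * n, dtype=np.int64)
    h, w = lv.shape
    for dr, dc in offsets:
        if abs(dr) >= h or abs(dc) >= w:
            continue
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ai, bi = a[valid], b[valid]
        counts += np.bincount(ai * n + bi, minlength=n * n)
        if symmetric:
            counts += np.bincount(bi * n + ai, minlength=n * n)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no valid in-mask pixel pairs for the given offsets")
    P = counts.reshape(n, n).astype(float) / total
    return GLCM(P=P, offsets=tuple(offsets), symmetric=symmetric, n_pairs=total)


@dataclass
class TextureFeatures:
    energy: float
    contrast: float
    entropy: float
    homogeneity: float
    correlation: float
    sum_average: float
    variance: float
    dissimilarity: float
    autocorrelation: float
    provenance: dict = field(default_factory=dict)

    FEATURE_NAMES = (
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

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FEATURE_NAMES}


def glcm_features(
    g: GLCM, log_base: float = 2.0, homogeneity_variant: str = "abs"
) -> TextureFeatures:
    """The nine scalar texture features of a normalized GLCM.

    With p(i, j) the matrix entries, marginals p_x, p_y, marginal moments
    (mu_x, mu_y, sigma_x, sigma_y) and grand mean mu = (mu_x + mu_y)/2:

    energy          = sum p^2
    contrast        = sum p (i - j)^2
    entropy         = -sum p log p          (0 log 0 := 0; base configurable)
    homogeneity     = sum p / (1 + |i - j|)    ("abs" variant; "squared"
                       uses 1 + (i - j)^2)
    correlation     = sum (i - mu_x)(j - mu_y) p / (sigma_x sigma_y)
    sum average     = sum_k k p_{x+y}(k),    k = 0 .. 2(n-1)
    variance        = sum (i - mu)^2 p
    dissimilarity   = sum p |i - j|
    autocorrelation = sum i j p

    A single-level (degenerate) image leaves correlation undefined; it is
    reported as NaN with a provenance note.
    """
    P = g.P
    n = P.shape[0]
    idx = np.arange(n, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    diff = i - j

    energy = float((P**2).sum())
    contrast = float((P * diff**2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(log_base))).sum())
    if homogeneity_variant == "abs":
        homog = float((P / (1.0 + np.abs(diff))).sum())
    elif homogeneity_variant == "squared":
        homog = float((P / (1.0 + diff**2)).sum())
    else:
        raise ValueError(f"unknown homogeneity variant {homogeneity_variant!r}")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sig_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))
    degenerate = sig_x * sig_y == 0.0
    if degenerate:
        correlation = float("nan")
    else:
        correlation = float((((i - mu_x) * (j - mu_y)) * P).sum() / (sig_x * sig_y))

    # p_{x+y}(k): distribution of the level sum over pairs
    k_sum = (np.arange(n)[:, None] + np.arange(n)[None, :]).ravel()
    p_xy = np.bincount(k_sum, weights=P.ravel(), minlength=2 * n - 1)
    sum_average = float((np.arange(2 * n - 1) * p_xy).sum())

    mu = 0.5 * (mu_x + mu_y)
    variance = float(((i - mu) ** 2 * P).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    autocorrelation = float((i * j * P).sum())

    return TextureFeatures(
        energy=energy,
        contrast=contrast,
        entropy=entropy,
        homogeneity=homog,
        correlation=correlation,
        sum_average=sum_average,
        variance=variance,
        dissimilarity=dissimilarity,
        autocorrelation=autocorrelation,
        provenance={
            "offsets": list(g.offsets),
            "symmetric": g.symmetric,
            "n_pairs": g.n_pairs,
            "log_base": log_base,
            "homogeneity_variant": homogeneity_variant,
            "level_origin": 0,
            "degenerate_correlation": degenerate,
        },
    )
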