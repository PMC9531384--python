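"""Synthetic short-axis T1 phantoms and trichrome slide images.

The phantom is a circular left-ventricular cross-section: a blood pool disk
inside an annular myocardial wall on a zero background.  Focal T1 elevations
("hotspots") are angular wedges with an optional raised-cosine skirt, so a
lesion can have either a sharp or a graded boundary.  All randomness is
explicit: every generator takes a seed (or ``numpy.random.SeedSequence``)
and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import T1Map, T1Study, angular_distance, middle_six_levels, polar_grid
from .histology import HistologyImage

__all__ = [
    "PhantomConfig",
    "HotspotSpec",
    "generate_t1_slice",
    "generate_t1_study",
    "generate_trichrome_image",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and signal model of one synthetic LV short-axis stack.

    ``rv_insertion_angle`` is the angular reference: the septum is the 120°
    arc centered on ``rv_insertion_angle + 90``; the lateral wall is the 120°
    arc opposite it; the remaining two 60° arcs are the anterior (about 0°,
    image up) and inferior sectors, which the segmental protocol never
    analyses.
    """

    image_size: int = 128
    endo_radius: float = 18.0
    epi_radius: float = 34.0
    center: tuple[float, float] | None = None
    baseline_t1: float = 980.0
    blood_t1: float = 1600.0
    noise_sd: float = 20.0
    # spatial correlation length (px) of the map noise: 0 = independent per
    # pixel; > 0 smooths the noise field (marginal SD preserved), emulating
    # the in-plane smoothness of fitted MOLLI maps
    noise_correlation_px: float = 0.0
    rv_insertion_angle: float = 180.0
    n_slices: int = 8
    pixel_spacing: float = 1.4

    def __post_init__(self) -> None:
        if not 0 < self.endo_radius < self.epi_radius < self.image_size / 2:
            raise ValueError(
                "invalid geometry: need 0 < endo_radius < epi_radius < image_size/2"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_slices < 6:
            raise ValueError("n_slices must be at least 6")

    @property
    def center_rc(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.image_size - 1) / 2.0, (self.image_size - 1) / 2.0)

    @property
    def wall_thickness(self) -> float:
        return self.epi_radius - self.endo_radius

    @property
    def septal_center(self) -> float:
        return (self.rv_insertion_angle + 90.0) % 360.0

    @property
    def lateral_center(self) -> float:
        return (self.rv_insertion_angle + 270.0) % 360.0


@dataclass(frozen=True)
class HotspotSpec:
    """A focal T1 elevation.

    The core wedge (``angular_width`` wide, radially ``[endo, endo +
    radial_span*wall)``) is elevated by the full ``delta_t1``; beyond the
    core the elevation falls off as a raised cosine over ``skirt_width``
    degrees (0 = sharp edge).  ``interior_spread`` models the patchy,
    pixel-scale heterogeneity of inflamed tissue: each in-lesion pixel's
    elevation is scaled by an independent Uniform(1-s, 1+s) factor, so the
    mean elevation stays ``delta_t1 * amplitude`` while the lesion interior
    becomes textured rather than a flat plateau (0 = uniform elevation).
    """

    center_angle: float
    angular_width: float
    radial_span: float = 1.0
    delta_t1: float = 150.0
    skirt_width: float = 0.0
    interior_spread: float = 0.0

    def __post_init__(self) -> None:
        if self.angular_width <= 0:
            raise ValueError("angular_width must be positive")
        if not 0 < self.radial_span <= 1:
            raise ValueError("radial_span must be in (0, 1]")
        if self.skirt_width < 0:
            raise ValueError("skirt_width must be nonnegative")
        if not 0 <= self.interior_spread < 1:
            raise ValueError("interior_spread must be in [0, 1)")

    def amplitude(self, theta: np.ndarray) -> np.ndarray:
        """Angular elevation profile (fraction of delta_t1) at angles theta."""
        d = angular_distance(theta, self.center_angle)
        half = self.angular_width / 2.0
        amp = np.zeros_like(d)
        amp[d <= half] = 1.0
        if self.skirt_width > 0:
            sk = (d > half) & (d <= half + self.skirt_width)
            amp[sk] = 0.5 * (1.0 + np.cos(np.pi * (d[sk] - half) / self.skirt_width))
        return amp


def generate_t1_slice(
    config: PhantomConfig,
    hotspots: list[HotspotSpec] | None = None,
    slice_level: str = "mid",
    seed: int | np.random.SeedSequence = 0,
    slice_index: int = 0,
) -> T1Map:
    """Render one short-axis T1 map.

    Myocardium (annulus) = baseline + hotspot elevations + N(0, noise_sd);
    blood pool (inside the annulus) = blood_t1 + noise; background exactly 0.
    """
    hotspots = hotspots or []
    rng = np.random.default_rng(seed)
    shape = (config.image_size, config.image_size)
    radius, theta = polar_grid(shape, config.center_rc)
    myo = (radius >= config.endo_radius) & (radius < config.epi_radius)
    blood = radius < config.endo_radius

    img = np.zeros(shape, dtype=float)
    img[blood] = config.blood_t1
    img[myo] = config.baseline_t1
    for h in hotspots:
        r_outer = config.endo_radius + h.radial_span * config.wall_thickness
        region = myo & (radius < r_outer)
        elevation = h.delta_t1 * h.amplitude(theta[region])
        if h.interior_spread > 0:
            u = rng.uniform(-h.interior_spread, h.interior_spread, size=elevation.size)
            elevation *= 1.0 + u
        img[region] += elevation
    if config.noise_sd > 0:
        body = myo | blood
        if config.noise_correlation_px > 0:
            from scipy.ndimage import gaussian_filter

            field_ = gaussian_filter(
                rng.standard_normal(shape), config.noise_correlation_px, mode="wrap"
            )
            field_ /= field_.std()  # keep the marginal per-pixel SD at noise_sd
            img[body] += config.noise_sd * field_[body]
        else:
            img[body] += rng.normal(0.0, config.noise_sd, size=int(body.sum()))
    np.maximum(img, 0.0, out=img)  # T1 is physically nonnegative
    return T1Map(
        pixels=img,
        pixel_spacing=config.pixel_spacing,
        slice_index=slice_index,
        slice_level=slice_level,
    )


def generate_t1_study(
    config: PhantomConfig,
    hotspots_per_slice: list[list[HotspotSpec]] | None = None,
    seed: int | np.random.SeedSequence = 0,
    case_id: str = "phantom",
) -> T1Study:
    """Render an ordered base→apex stack of ``config.n_slices`` maps.

    The middle six slices are tagged 2 basal / 2 mid / 2 apical for the
    downstream segmental protocol; any extra end slices are tagged excluded.
    """
    n = config.n_slices
    if hotspots_per_slice is None:
        hotspots_per_slice = [[] for _ in range(n)]
    if len(hotspots_per_slice) != n:
        raise ValueError(
            f"hotspots_per_slice has {len(hotspots_per_slice)} entries, expected {n}"
        )
    levels = middle_six_levels(n)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    maps = [
        generate_t1_slice(
            config,
            hotspots_per_slice[i],
            slice_level=levels[i],
            seed=children[i],
            slice_index=i,
        )
        for i in range(n)
    ]
    return T1Study(maps=maps, case_id=case_id)


# --- trichrome slide generator -------------------------------------------------

# Palettes chosen to sit strictly inside (collagen) / outside (cytoplasm) the
# default colorimetric rule (blue >= 100, blue-red >= 20, blue-green >= 20)
# even after the +/- jitter below, so recovery is exact by construction.
_COLLAGEN_BASE = np.array([60, 60, 180])
_CYTOPLASM_BASE = np.array([180, 70, 80])
_BACKGROUND = np.array([245, 245, 245])
_JITTER = 15


def generate_trichrome_image(
    collagen_fraction: float,
    size: int = 256,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[HistologyImage, dict[str, np.ndarray]]:
    """Synthesize a Masson-trichrome-like RGB slide.

    A central disk of tissue on a white background; exactly
    ``round(collagen_fraction * n_tissue)`` tissue pixels get the
    blue-dominant collagen palette, the rest the red-dominant cytoplasm
    palette.  Returns the image plus ground-truth ``tissue`` and
    ``collagen`` masks.
    """
    if not 0.0 <= collagen_fraction <= 1.0:
        raise ValueError("collagen_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (size, size)
    radius, _ = polar_grid(shape, ((size - 1) / 2.0, (size - 1) / 2.0))
    tissue = radius < 0.45 * size
    n_tissue = int(tissue.sum())
    n_collagen = int(round(collagen_fraction * n_tissue))

    flat_idx = np.flatnonzero(tissue)
    collagen_idx = rng.choice(flat_idx, size=n_collagen, replace=False)
    collagen = np.zeros(shape, dtype=bool)
    collagen.flat[collagen_idx] = True

    rgb = np.empty((*shape, 3), dtype=float)
    rgb[:] = _BACKGROUND
    cyto = tissue & ~collagen
    for mask, base in ((cyto, _CYTOPLASM_BASE), (collagen, _COLLAGEN_BASE)):
        n = int(mask.sum())
        if n:
            rgb[mask] = base + rng.integers(-_JITTER, _JITTER + 1, size=(n, 3))
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    img = HistologyImage(rgb=rgb)
    return img, {"tissue": tissue, "collagen": collagen}
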