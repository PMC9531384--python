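"""Digital fibrosis quantification of trichrome-stained biopsy images.

Percentage tissue fibrosis is the fraction of tissue pixels classified as
blue-stained collagen by a colorimetric rule.  The default rule works on raw
RGB channels: a pixel is collagen iff it is tissue, its blue channel exceeds
``blue_min`` and dominates both red and green by at least ``margin``.  An HSV
hue-window variant is available behind ``mode="hsv"``.  Endocardial collagen
and artifacts are handled through a user-supplied exclusion mask, removed
from numerator and denominator alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.color import rgb2hsv


@dataclass
class HistologyImage:
    """An 8-bit RGB slide image with an optional exclusion mask."""

    rgb: np.ndarray
    exclusion_mask: np.ndarray | None = None
    pixel_size: float | None = None  # micrometres per pixel

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an (H, W, 3) array")
        if self.rgb.dtype != np.uint8:
            if self.rgb.min() < 0 or self.rgb.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.rgb = self.rgb.astype(np.uint8)
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if self.exclusion_mask.shape != self.rgb.shape[:2]:
                raise ValueError("exclusion_mask shape must match the image")


@dataclass(frozen=True)
class ColorimetricRule:
    """Parameters of the blue-collagen classifier (all recorded in results)."""

    blue_min: int = 100
    margin: int = 20
    background_luminance_cutoff: float = 230.0
    mode: str = "rgb"  # "rgb" channel-margin rule or "hsv" hue window
    hue_window: tuple[float, float] = (0.5, 0.75)  # used in hsv mode
    min_saturation: float = 0.15


@dataclass
class FibrosisResult:
    fibrosis_percent: float
    n_collagen: int
    n_tissue: int
    threshold_params: dict = field(default_factory=dict)


def tissue_mask(img: HistologyImage, background_luminance_cutoff: float = 230.0):
    """Non-background, non-excluded pixels: mean channel value below cutoff."""
    luminance = img.rgb.mean(axis=2)
    mask = luminance < background_luminance_cutoff
    if img.exclusion_mask is not None:
        mask &= ~img.exclusion_mask
    if not mask.any():
        raise ValueError("no tissue pixels found (image all background/excluded)")
    return mask


def blue_collagen_mask(
    img: HistologyImage, params: ColorimetricRule = ColorimetricRule()
):
    """Boolean collagen mask under the colorimetric rule (subset of tissue)."""
    tissue = tissue_mask(img, params.background_luminance_cutoff)
    if params.mode == "rgb":
        rgb = img.rgb.astype(np.int16)
        r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
        collagen = (
            (b >= params.blue_min)
            & (b - r >= params.margin)
            & (b - g >= params.margin)
        )
    elif params.mode == "hsv":
        hsv = rgb2hsv(img.rgb)
        lo, hi = params.hue_window
        collagen = (
            (hsv[..., 0] >= lo)
            & (hsv[..., 0] <= hi)
            & (hsv[..., 1] >= params.min_saturation)
        )
    else:  # pragma: no cover - guarded by dataclass users
        raise ValueError(f"unknown colorimetric mode {params.mode!r}")
    return collagen & tissue


def fibrosis_percentage(
    img: HistologyImage, params: ColorimetricRule = ColorimetricRule()
) -> FibrosisResult:
    """Percentage tissue fibrosis: 100 * collagen pixels / tissue pixels."""
    tissue = tissue_mask(img, params.background_luminance_cutoff)
    collagen = blue_collagen_mask(img, params)
    n_tissue = int(tissue.sum())
    n_collagen = int(collagen.sum())
    return FibrosisResult(
        fibrosis_percent=100.0 * n_collagen / n_tissue,
        n_collagen=n_collagen,
        n_tissue=n_tissue,
        threshold_params=asdict(params),
    )
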