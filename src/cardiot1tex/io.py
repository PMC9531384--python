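"""Disk formats: T1 studies as 16-bit TIFF stacks with a JSON sidecar,
histology as 8-bit RGB PNG with single-channel mask PNGs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import T1Map, T1Study
from .histology import HistologyImage

__all__ = [
    "write_t1_study",
    "read_t1_study",
    "write_histology_image",
    "read_histology_image",
]


def write_t1_study(study: T1Study, directory: str | Path) -> Path:
    """One integer-rounded 16-bit TIFF per slice plus ``study.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {"case_id": study.case_id, "slices": []}
    for m in study.maps:
        fname = f"slice{m.slice_index:02d}.tif"
        data = np.clip(np.round(m.pixels), 0, 65535).astype(np.uint16)
        tifffile.imwrite(directory / fname, data)
        sidecar["slices"].append(
            {
                "file": fname,
                "slice_index": m.slice_index,
                "slice_level": m.slice_level,
                "pixel_spacing_mm": m.pixel_spacing,
            }
        )
    path = directory / "study.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def read_t1_study(directory: str | Path) -> T1Study:
    directory = Path(directory)
    sidecar = json.loads((directory / "study.json").read_text())
    maps = []
    for entry in sorted(sidecar["slices"], key=lambda e: e["slice_index"]):
        pixels = tifffile.imread(directory / entry["file"]).astype(float)
        maps.append(
            T1Map(
                pixels=pixels,
                pixel_spacing=entry["pixel_spacing_mm"],
                slice_index=entry["slice_index"],
                slice_level=entry["slice_level"],
            )
        )
    return T1Study(maps=maps, case_id=sidecar["case_id"])


def write_histology_image(img: HistologyImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img.rgb)
    if img.exclusion_mask is not None:
        iio.imwrite(
            path.with_name(path.stem + "_exclusion.png"),
            (img.exclusion_mask.astype(np.uint8) * 255),
        )
    return path


def read_histology_image(
    path: str | Path, exclusion_path: str | Path | None = None
) -> HistologyImage:
    rgb = iio.imread(path)
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[..., :3]
    exclusion = None
    if exclusion_path is not None:
        exclusion = iio.imread(exclusion_path) > 0
    return HistologyImage(rgb=rgb, exclusion_mask=exclusion)
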