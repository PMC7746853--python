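"""Image, mask, seed and history I/O.

Conventions: images are loaded as float fields normalized to [0, 1] by
the source bit-depth maximum (so intensity parameters such as sigma_i
are bit-depth independent); masks are strict {0,1} fields stored as
0/255 8-bit PNG; seeds travel as JSON with 0-based (row, col)
coordinates, origin top-left.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .convergence import History
from .levelset import SeedRegion

#: ITU-R BT.601 luminance weights for RGB conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale (or RGB, converted by luminance) image as [0, 1] floats."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"{path}: zero-size image")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(float)
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError(f"{path}: float image must already be scaled to [0, 1]")
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA if arr.shape[-1] >= 3 else arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image must be scaled to [0, 1] before saving")
    iio.imwrite(Path(path), np.round(img * 255).astype(np.uint8))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as a 0/255 8-bit PNG.  Non-binary input is an error."""
    arr = np.asarray(mask)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("mask must contain only 0 and 1")
    iio.imwrite(Path(path), (arr.astype(np.uint8) * 255))


def load_mask(path: str | Path) -> np.ndarray:
    """Load a 0/255 PNG as a {0,1} uint8 mask.  Other gray values are an error."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel")
    values = np.unique(arr)
    if not np.isin(values, (0, 255)).all():
        raise ValueError(f"{path}: mask file must be 0/255, found values {values[:5]}")
    return (arr > 0).astype(np.uint8)


def seeds_to_json(seeds, path: str | Path | None = None) -> str:
    payload = {
        "seeds": [
            {
                "type": s.kind,
                "center": list(s.center),
                ("radii" if s.kind == "ellipse" else "extents"): list(s.extents),
            }
            for s in seeds
        ]
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def load_seeds(source: str | Path) -> list[SeedRegion]:
    """Parse seed regions from a JSON file or JSON string."""
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    data = json.loads(text)
    seeds = []
    for entry in data["seeds"]:
        kind = entry.get("type", "ellipse")
        kind = "rect" if kind in ("rect", "rectangle") else kind
        extents = entry.get("radii", entry.get("extents"))
        if extents is None:
            raise ValueError(f"seed entry missing radii/extents: {entry}")
        seeds.append(
            SeedRegion(kind=kind, center=tuple(entry["center"]), extents=tuple(extents))
        )
    if not seeds:
        raise ValueError("seed file contains no seed regions")
    return seeds


def save_history(history: History, path: str | Path) -> None:
    history.to_dataframe().to_csv(Path(path), index=False)
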