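"""Reading and writing images, masks and result tables.

Supported image formats are single-page grayscale TIFF (8- or 16-bit) and
grayscale PNG; RGB input is rejected with instructions to convert.  Result
tables are CSV with a fixed column order and '.' decimal separator, and JSON
reports that round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import UnsupportedImageError
from .segmentation import BinaryMask

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "write_csv",
    "read_csv",
    "write_json",
    "read_json",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale 8-/16-bit TIFF or PNG as an integer array."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image not found: {p}")
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        arr = iio.imread(p)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise UnsupportedImageError(
            f"{p.name}: RGB/multichannel images are not supported; convert to "
            "single-channel grayscale first"
        )
    if arr.ndim != 2:
        raise UnsupportedImageError(f"{p.name}: expected a 2-D image, got ndim={arr.ndim}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise UnsupportedImageError(
            f"{p.name}: unsupported bit depth {arr.dtype}; expected uint8 or uint16"
        )
    return arr


def write_image(path: str | Path, pixels: np.ndarray, bit_depth: int = 8) -> Path:
    """Write a [0, 1] float or integer grid as a grayscale TIFF/PNG."""
    p = Path(path)
    pixels = np.asarray(pixels)
    if np.issubdtype(pixels.dtype, np.floating):
        if bit_depth == 8:
            data = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
        elif bit_depth == 16:
            data = np.round(np.clip(pixels, 0, 1) * 65535).astype(np.uint16)
        else:
            raise UnsupportedImageError(f"bit_depth must be 8 or 16, got {bit_depth}")
    else:
        data = pixels
    p.parent.mkdir(parents=True, exist_ok=True)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, data)
    else:
        iio.imwrite(p, data)
    return p


def write_mask(path: str | Path, mask: BinaryMask) -> Path:
    """Write a binary mask as an 8-bit 0/255 TIFF."""
    return write_image(path, mask.mask.astype(np.uint8) * 255)


def read_mask(path: str | Path, um_per_px: float) -> BinaryMask:
    arr = read_image(path)
    return BinaryMask(mask=arr > 0, um_per_px=um_per_px)


def write_csv(path: str | Path, table: pd.DataFrame) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(p, index=False, float_format="%.10g")
    return p


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, payload: dict) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return p


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
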