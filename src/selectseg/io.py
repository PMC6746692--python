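"""Reading and writing of images, masks, markers and float fields."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .grid import BinaryMask, ImageGrid, normalize_image

__all__ = [
    "read_image",
    "write_mask_png",
    "read_mask_png",
    "write_mask_rle",
    "read_mask_rle",
    "read_markers",
    "write_float_tiff",
]


def read_image(path) -> ImageGrid:
    """Load a greyscale PNG/TIFF (8/16-bit) and normalise it to [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.ptp(arr[..., :3], axis=2).max() == 0:
            arr = arr[..., 0]  # grey stored as RGB
        else:
            raise ValueError("colour images are not supported; provide a "
                             "single-channel greyscale image")
    return normalize_image(arr)


def write_mask_png(path, mask: BinaryMask) -> None:
    iio.imwrite(path, (mask.values.astype(np.uint8) * 255))


def read_mask_png(path) -> BinaryMask:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127)


def write_mask_rle(path, mask: BinaryMask) -> None:
    """Plain-text run-length mask format for small fixtures.

    First line: ``H W``; second line: run lengths of alternating 0/1
    values over the flattened (row-major) mask, starting with zeros.
    """
    flat = mask.values.ravel().astype(np.int8)
    edges = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], edges, [flat.size]])
    runs = np.diff(bounds)
    if flat[0] == 1:  # leading zero-run of length 0
        runs = np.concatenate([[0], runs])
    h, w = mask.shape
    Path(path).write_text(
        f"{h} {w}\n" + " ".join(str(int(r)) for r in runs) + "\n")


def read_mask_rle(path) -> BinaryMask:
    lines = Path(path).read_text().split("\n")
    h, w = (int(x) for x in lines[0].split())
    runs = [int(x) for x in lines[1].split()]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            flat[pos:pos + r] = True
        pos += r
        val = not val
    if pos != h * w:
        raise ValueError("run lengths do not cover the mask")
    return BinaryMask(flat.reshape(h, w))


def read_markers(path) -> np.ndarray:
    """Marker points from a CSV ('row,col' per line) or JSON file."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        data = json.loads(text)
        pts = data["markers"] if isinstance(data, dict) else data
        return np.asarray(pts, dtype=float)
    rows = []
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        r, c = line.split(",")[:2]
        try:
            rows.append((float(r), float(c)))
        except ValueError:
            continue  # header line
    return np.asarray(rows, dtype=float)


def write_float_tiff(path, values: np.ndarray) -> None:
    """Export a scalar field (distance/fitting map) as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
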