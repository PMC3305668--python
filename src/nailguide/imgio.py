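"""Image and sidecar file round-tripping (8/16-bit grayscale PNG/TIFF)."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as float in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    out = arr.astype(float)
    if out.max() > 1.0:
        out = out / out.max()
    return out


def write_image(path, pixels: np.ndarray, bit_depth: int = 16) -> str:
    """Write float [0, 1] pixels as 8- or 16-bit grayscale PNG/TIFF."""
    path = Path(path)
    img = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        data = np.round(img * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        data = np.round(img * 255.0).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, data)
    return str(path)


def write_json(path, obj) -> str:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return str(path)


def read_json(path):
    return json.loads(Path(path).read_text())
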