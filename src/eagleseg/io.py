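"""Image and histogram I/O.

RGB inputs are converted to 8-bit luminance with ITU-R BT.601 weights
(0.299, 0.587, 0.114) and round-half-up, so loading is bit-exact and
reproducible across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["to_grayscale", "load_image", "save_mask", "save_image", "save_histogram", "load_histogram"]

_BT601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an image array to 8-bit grayscale (BT.601 luminance)."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[2] == 3:
            arr = np.floor(arr.astype(float) @ _BT601 + 0.5)
        elif arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(f"cannot interpret image with {arr.shape[2]} channels")
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {arr.shape}")
    return np.clip(arr, 0, 255).astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Read a raster image (PNG/TIFF/BMP/JPEG) as 8-bit grayscale."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"cannot read image at {path}: {exc}") from exc
    return to_grayscale(arr)


def save_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def save_mask(path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit {0,255} PNG."""
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def save_histogram(path, hist) -> None:
    """Serialize a 256-bin histogram as a JSON list."""
    p = np.asarray(hist, dtype=float)
    Path(path).write_text(json.dumps([float(v) for v in p]))


def load_histogram(path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    p = np.asarray(data, dtype=float)
    if p.shape != (256,):
        raise ValueError(f"histogram file must hold 256 values, got {p.shape}")
    return p
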