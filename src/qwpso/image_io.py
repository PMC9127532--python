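"""Reading and writing 8-bit grayscale images and binary masks.

PNG and TIFF are supported through :mod:`imageio`. Masks are written as
0/255 PNGs; label maps as 16-bit PNGs.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .types import InputError

# ITU-R BT.601 luma weights, the conventional RGB -> gray reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


def read_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF image as a (H, W) uint8 grayscale array.

    RGB(A) input is converted to luminance and rounded; a grayscale image
    round-trips losslessly.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / missing / undecodable
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise InputError(f"image {path!r} is zero-sized")
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3].astype(np.float64) @ _LUMA
        else:
            arr = arr[..., 0].astype(np.float64)
    elif arr.ndim != 2:
        raise InputError(f"image {path!r} has unsupported shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.floor(arr.astype(np.float64) + 0.5), 0, 255)
    return np.ascontiguousarray(arr, dtype=np.uint8)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 PNG; round-trips bit-exactly."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InputError(f"mask must be 2-D, got shape {mask.shape}")
    img = np.where(mask.astype(bool), 255, 0).astype(np.uint8)
    try:
        iio.imwrite(path, img)
    except Exception as exc:
        raise InputError(f"cannot write mask {path!r}: {exc}") from exc


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a 0/255 PNG mask back to booleans (threshold at 127)."""
    return read_gray_image(path) > 127


def write_label_map(path: str | os.PathLike, labels: np.ndarray) -> None:
    """Write an integer label map as a 16-bit PNG."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise InputError("label ids must fit in uint16")
    try:
        iio.imwrite(path, labels.astype(np.uint16))
    except Exception as exc:
        raise InputError(f"cannot write label map {path!r}: {exc}") from exc
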