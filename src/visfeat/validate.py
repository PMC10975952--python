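"""Shared input validation for intensity images and masks.

Conventions used throughout the package: images are 2-D float arrays with
values in [0, 1], indexed 0-based as (row, col); binary masks are arrays of
{0, 1} with the same shape as their paired image.
"""

from __future__ import annotations

import numpy as np

MIN_SIZE = 16  # pipeline minimum along each image axis


def as_intensity(image: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate and return an intensity image as float64 in [0, 1]."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIZE or arr.shape[1] < MIN_SIZE:
        raise ValueError(f"{name} must be at least {MIN_SIZE}x{MIN_SIZE}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return arr


def as_mask(mask: np.ndarray, shape: tuple[int, int] | None = None, name: str = "mask") -> np.ndarray:
    """Validate and return a binary mask as uint8 {0, 1}."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    arr = arr.astype(np.uint8, copy=False)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} values must be exactly 0 or 1")
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"{name} shape {arr.shape} does not match image shape {tuple(shape)}")
    return arr
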