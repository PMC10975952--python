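"""Image reading and writing (PNG/TIFF/JPEG via imageio).

Intensity images are held as float in [0, 1]; 8/16-bit files are rescaled
by their dtype range on read.  Masks are written as 8-bit PNG {0, 255};
float responses as 32-bit TIFF.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def read_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return np.clip(arr, 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    img = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, img.astype(np.float32))
    else:
        iio.imwrite(path, np.clip(img * 255.0, 0, 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)
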