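"""Image loading, intensity normalization and quantization.

All downstream texture features consume a *gray image*: a 2-D integer
array with values in ``[0, L-1]`` (``L = 256`` by default).  This module
standardizes arbitrary PNG/JPEG inputs into that form:

1. :func:`load_and_standardize` — decode, collapse color to a single
   channel, resize to a fixed grid.
2. :func:`histogram_stretch` — min–max normalization ("inter-scan
   normalization") mapping intensities to ``[0, 1]``.
3. :func:`quantize` — map ``[0, 1]`` back onto ``L`` integer levels.

Stretching followed by re-quantization makes intensities comparable
across scanners while preserving rank order, so co-occurrence and LBP
statistics are computed on the same dynamic range for every image.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "DegenerateInputError",
    "load_and_standardize",
    "histogram_stretch",
    "quantize",
    "list_labeled_images",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but carries no usable signal
    (e.g. a constant image with zero dynamic range)."""


def load_and_standardize(
    path: str | os.PathLike, target_size: tuple[int, int] | None = None
) -> np.ndarray:
    """Load a PNG/JPEG as a 2-D integer grayscale array.

    Color inputs are collapsed to one channel by the unweighted mean of the
    RGB channels (alpha, if present, is dropped).  When ``target_size =
    (rows, cols)`` differs from the native size the image is resampled with
    bilinear interpolation and rounded back to integers; an identical target
    size leaves pixel values untouched.

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    ValueError
        If ``target_size`` has a zero or negative dimension, or the
        resulting image is smaller than 3x3 (too small for any
        neighborhood-based texture feature).
    """
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"unsupported image layout with shape {arr.shape}: {path}")
    if target_size is not None:
        rows, cols = int(target_size[0]), int(target_size[1])
        if rows <= 0 or cols <= 0:
            raise ValueError(f"target_size must be positive, got {target_size}")
        if (rows, cols) != arr.shape:
            im_f = Image.fromarray(arr.astype(np.float32), mode="F")
            arr = np.asarray(
                im_f.resize((cols, rows), Image.Resampling.BILINEAR), dtype=np.float64
            )
    out = np.rint(arr).astype(np.int64)
    out[out < 0] = 0
    if out.shape[0] < 3 or out.shape[1] < 3:
        raise ValueError(f"image {path} is smaller than 3x3: shape {out.shape}")
    return out


def histogram_stretch(img: np.ndarray) -> np.ndarray:
    """Min–max stretch intensities to the unit interval.

    Implements ``O = (N - N_min) / (N_max - N_min)`` per pixel.  The output
    attains 0 exactly at every minimum pixel and 1 at every maximum pixel,
    and preserves the ordering of intensities.

    Raises
    ------
    DegenerateInputError
        If the image is constant (``N_max == N_min``): the stretch would
        divide by a zero dynamic range.
    """
    arr = np.asarray(img, dtype=np.float64)
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        raise DegenerateInputError(
            f"cannot stretch a constant image: zero dynamic range at value {lo}"
        )
    return (arr - lo) / (hi - lo)


def quantize(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Map unit-interval intensities onto ``levels`` integer gray levels.

    Each value ``v`` maps to ``floor(v * (levels - 1) + 0.5)`` (round half
    up), so 0 and 1 land exactly on the first and last level.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    arr = np.asarray(img, dtype=np.float64)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("quantize expects values in [0, 1]; run histogram_stretch first")
    return np.floor(arr * (levels - 1) + 0.5).astype(np.int64)


def list_labeled_images(root: str | os.PathLike) -> list[tuple[Path, str]]:
    """Enumerate a ``<root>/<class_name>/*.png|jpg`` dataset.

    Returns (path, class_name) pairs sorted by path so feature-matrix row
    order is deterministic.  Class names are the directory names, verbatim.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    pairs: list[tuple[Path, str]] = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        found = [
            p for p in sorted(class_dir.iterdir())
            if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
        ]
        if not found:
            raise FileNotFoundError(f"class directory {class_dir} contains no PNG/JPEG images")
        pairs.extend((p, class_dir.name) for p in found)
    if not pairs:
        raise FileNotFoundError(f"no class directories found under {root}")
    return pairs
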