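"""Texture feature extraction: first-order statistics, GLCM, LBP.

The default configuration produces a 286-dimensional vector per image:

* 6 first-order histogram statistics (mean, variance, std, skewness,
  kurtosis, entropy in nats),
* 6 gray-level co-occurrence features (contrast, dissimilarity,
  homogeneity, ASM, energy, correlation) at each of the four canonical
  orientations 0°, 45°, 90°, 135° with pixel distance d = 1 (24 values),
* the normalized 256-bin histogram of circular local binary pattern
  codes with P = 8 neighbors at radius R = 1.0.

Conventions that matter for reproducibility:

* GLCM counts *ordered* (reference, neighbor) pairs at a single offset
  per orientation — 0° → (0,+d), 45° → (−d,+d), 90° → (−d,0),
  135° → (−d,−d) in (row, col) — and is normalized to sum to 1 before
  features are computed.  A ``symmetric`` flag accumulates both
  directions.
* First-order skewness and kurtosis use the population standard
  deviation (divisor N); on a constant image (std = 0) both are
  returned as 0 by convention.
* LBP compares each circularly-sampled neighbor g_p against the center
  g_c with the unit step S(x) = 1 iff x >= 0 and packs bits as
  sum S(g_p - g_c) * 2^p; neighbors at non-integer coordinates are
  bilinearly interpolated, and pixels within R of the border are
  excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import (
    DegenerateInputError,
    histogram_stretch,
    list_labeled_images,
    load_and_standardize,
    quantize,
)

__all__ = [
    "FeatureConfig",
    "FirstOrderFeatures",
    "GLCMFeatures",
    "first_order_features",
    "compute_glcm",
    "glcm_features",
    "lbp_code_image",
    "lbp_histogram",
    "extract_feature_vector",
    "extract_feature_matrix",
    "extract_feature_matrix_from_arrays",
    "write_feature_csv",
    "read_feature_csv",
]

#: (row, col) offset of the neighbor pixel for each orientation, distance 1.
GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class FeatureConfig:
    """Layout and parameters of the extracted feature vector."""

    levels: int = 256
    distance: int = 1
    orientations: tuple[int, ...] = (0, 45, 90, 135)
    average_angles: bool = False  # pool GLCM features over orientations
    symmetric_glcm: bool = False
    lbp_points: int = 8
    lbp_radius: float = 1.0
    lbp_mode: str = "circular"  # or "grid" (3x3 Moore neighborhood)
    normalize_lbp: bool = True
    normalize_images: bool = True  # histogram-stretch + re-quantize inputs

    def feature_names(self) -> list[str]:
        names = [f"fo_{s}" for s in ("mean", "variance", "std", "skewness", "kurtosis", "entropy")]
        glcm_feats = ("contrast", "dissimilarity", "homogeneity", "asm", "energy", "correlation")
        if self.average_angles:
            names += [f"glcm_avg_{f}" for f in glcm_feats]
        else:
            for theta in self.orientations:
                names += [f"glcm_{theta}deg_{f}" for f in glcm_feats]
        names += [f"lbp_{b:03d}" for b in range(2 ** self.lbp_points)]
        return names


@dataclass(frozen=True)
class FirstOrderFeatures:
    mean: float
    variance: float
    std: float
    skewness: float
    kurtosis: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean, self.variance, self.std, self.skewness, self.kurtosis, self.entropy]
        )


@dataclass(frozen=True)
class GLCMFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    asm: float
    energy: float
    correlation: float
    degenerate_correlation: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.contrast,
                self.dissimilarity,
                self.homogeneity,
                self.asm,
                self.energy,
                self.correlation,
            ]
        )


def first_order_features(img: np.ndarray, levels: int = 256) -> FirstOrderFeatures:
    """Histogram statistics of the intensity distribution.

    Mean and std use the population convention (divisor N); skewness and
    kurtosis are the standardized third and fourth moments (kurtosis is not
    excess-corrected, so a two-point symmetric distribution has kurtosis 1).
    Entropy is computed over the L-bin normalized histogram in nats with the
    convention 0·ln 0 = 0, hence 0 <= entropy <= ln(L).
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    m = arr.mean()
    centered = arr - m
    var = np.mean(centered**2)
    std = math.sqrt(var)
    if std > 0:
        skew = float(np.mean(centered**3) / std**3)
        kurt = float(np.mean(centered**4) / std**4)
    else:
        skew = 0.0
        kurt = 0.0
    hist = np.bincount(np.asarray(img, dtype=np.int64).ravel(), minlength=levels)
    p = hist / hist.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return FirstOrderFeatures(float(m), float(var), std, skew, kurt, entropy)


def compute_glcm(
    img: np.ndarray,
    d: int = 1,
    theta: int = 0,
    levels: int = 256,
    normalized: bool = True,
    symmetric: bool = False,
) -> np.ndarray:
    """Gray-level co-occurrence matrix at one offset.

    Counts ordered pairs (reference, neighbor) where the neighbor sits at
    the (row, col) offset implied by ``theta`` and distance ``d``.  With
    ``symmetric`` the opposite direction is accumulated as well (G + G^T).
    When ``normalized`` the matrix is divided by the total pair count.
    """
    if d < 1:
        raise ValueError(f"distance d must be >= 1, got {d}")
    if theta not in GLCM_OFFSETS:
        raise ValueError(f"theta must be one of {sorted(GLCM_OFFSETS)}, got {theta}")
    arr = np.asarray(img, dtype=np.int64)
    if arr.min() < 0 or arr.max() >= levels:
        raise ValueError(f"pixel values must lie in [0, {levels - 1}]")
    dr, dc = (o * d for o in GLCM_OFFSETS[theta])
    rows, cols = arr.shape
    r0, r1 = max(0, -dr), rows - max(0, dr)
    c0, c1 = max(0, -dc), cols - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise DegenerateInputError(
            f"image of shape {arr.shape} admits no pixel pair at distance {d}, theta {theta}"
        )
    ref = arr[r0:r1, c0:c1].ravel()
    nbr = arr[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    G = np.bincount(ref * levels + nbr, minlength=levels * levels).reshape(levels, levels)
    G = G.astype(np.float64)
    if symmetric:
        G = G + G.T
    if normalized:
        G = G / G.sum()
    return G


def glcm_features(G: np.ndarray) -> GLCMFeatures:
    """Contrast, dissimilarity, homogeneity, ASM, energy and correlation of a
    normalized co-occurrence matrix.

    Correlation uses the marginal means/standard deviations of G.  If either
    marginal deviation is zero (a constant image concentrates all mass in one
    cell) the gray level is perfectly predictable and correlation is returned
    as 1 with ``degenerate_correlation`` set.
    """
    G = np.asarray(G, dtype=np.float64)
    total = G.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("glcm_features expects a normalized GLCM (entries summing to 1)")
    L = G.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j
    contrast = float((diff**2 * G).sum())
    dissimilarity = float((np.abs(diff) * G).sum())
    homogeneity = float((G / (1.0 + diff**2)).sum())
    asm = float((G**2).sum())
    energy = math.sqrt(asm)
    pi = G.sum(axis=1)
    pj = G.sum(axis=0)
    mu_i = float(np.dot(np.arange(L), pi))
    mu_j = float(np.dot(np.arange(L), pj))
    sig_i = math.sqrt(float(np.dot((np.arange(L) - mu_i) ** 2, pi)))
    sig_j = math.sqrt(float(np.dot((np.arange(L) - mu_j) ** 2, pj)))
    if sig_i <= 1e-15 or sig_j <= 1e-15:
        return GLCMFeatures(
            contrast, dissimilarity, homogeneity, asm, energy, 1.0, degenerate_correlation=True
        )
    corr = float((((i - mu_i) * (j - mu_j) * G) / (sig_i * sig_j)).sum())
    return GLCMFeatures(contrast, dissimilarity, homogeneity, asm, energy, corr)


def _circular_offsets(P: int, R: float) -> list[tuple[float, float]]:
    # angle 0 points east; positive angles advance counter-clockwise in
    # image coordinates (decreasing row). Offsets snapped at 1e-8 so exact
    # integer positions bypass interpolation error.
    out = []
    for p in range(P):
        ang = 2.0 * math.pi * p / P
        out.append((round(-R * math.sin(ang), 8), round(R * math.cos(ang), 8)))
    return out


_GRID_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def _sample_shifted(arr: np.ndarray, m: int, dr: float, dc: float) -> np.ndarray:
    """Bilinearly sample ``arr`` at (r+dr, c+dc) for every interior pixel,
    where interior means rows/cols m..end-m."""
    rows, cols = arr.shape
    fr, fc = math.floor(dr), math.floor(dc)
    tr, tc = dr - fr, dc - fc

    def block(br: int, bc: int) -> np.ndarray:
        return arr[m + br : rows - m + br, m + bc : cols - m + bc]

    if tr == 0.0 and tc == 0.0:
        return block(fr, fc).astype(np.float64)
    a = block(fr, fc).astype(np.float64)
    b = block(fr, fc + 1).astype(np.float64)
    c = block(fr + 1, fc).astype(np.float64)
    dd = block(fr + 1, fc + 1).astype(np.float64)
    return (1 - tr) * ((1 - tc) * a + tc * b) + tr * ((1 - tc) * c + tc * dd)


def lbp_code_image(
    img: np.ndarray, P: int = 8, R: float = 1.0, mode: str = "circular"
) -> np.ndarray:
    """Local binary pattern codes for every interior pixel.

    ``mode='circular'`` samples P neighbors at angles 2πp/P on the circle of
    radius R (bilinear interpolation); ``mode='grid'`` uses the 3x3 Moore
    neighborhood in the same angular order (P=8, R=1 only).  Pixels within
    ceil(R) of the border are excluded, so the code grid of an r x c image
    is (r-2m) x (c-2m) with m = ceil(R).
    """
    arr = np.asarray(img, dtype=np.float64)
    m = max(1, math.ceil(R))
    if arr.shape[0] < 2 * m + 1 or arr.shape[1] < 2 * m + 1:
        raise DegenerateInputError(
            f"image of shape {arr.shape} too small for LBP with radius {R}"
        )
    if mode == "circular":
        offsets = _circular_offsets(P, R)
    elif mode == "grid":
        if P != 8 or R != 1.0:
            raise ValueError("grid mode requires P=8, R=1.0")
        offsets = [(float(r), float(c)) for r, c in _GRID_OFFSETS]
    else:
        raise ValueError(f"unknown LBP mode {mode!r}")
    center = arr[m:-m, m:-m]
    codes = np.zeros(center.shape, dtype=np.int64)
    # 1e-9 guard absorbs float rounding of interpolated samples on flat
    # patches; genuine intensity differences on integer images are far larger.
    for p, (dr, dc) in enumerate(offsets):
        sample = _sample_shifted(arr, m, dr, dc)
        codes |= ((sample - center) >= -1e-9).astype(np.int64) << p
    return codes


def lbp_histogram(codes: np.ndarray, bins: int = 256, normalized: bool = False) -> np.ndarray:
    """Histogram of LBP codes; bin b counts occurrences of code b."""
    hist = np.bincount(np.asarray(codes, dtype=np.int64).ravel(), minlength=bins).astype(
        np.float64
    )
    if normalized:
        hist = hist / hist.sum()
    return hist


def extract_feature_vector(img: np.ndarray, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Concatenate [first-order | GLCM per orientation | LBP histogram].

    The order and naming follow :meth:`FeatureConfig.feature_names`; under the
    defaults the result has 6 + 24 + 256 = 286 finite values.
    """
    fo = first_order_features(img, levels=config.levels).as_array()
    glcm_blocks = []
    for theta in config.orientations:
        G = compute_glcm(
            img,
            d=config.distance,
            theta=theta,
            levels=config.levels,
            normalized=True,
            symmetric=config.symmetric_glcm,
        )
        glcm_blocks.append(glcm_features(G).as_array())
    if config.average_angles:
        glcm_part = np.mean(glcm_blocks, axis=0)
    else:
        glcm_part = np.concatenate(glcm_blocks)
    codes = lbp_code_image(img, P=config.lbp_points, R=config.lbp_radius, mode=config.lbp_mode)
    hist = lbp_histogram(codes, bins=2 ** config.lbp_points, normalized=config.normalize_lbp)
    return np.concatenate([fo, glcm_part, hist])


def _standardized_image(img: np.ndarray, config: FeatureConfig) -> np.ndarray:
    if config.normalize_images:
        return quantize(histogram_stretch(img), config.levels)
    return np.asarray(img, dtype=np.int64)


def extract_feature_matrix_from_arrays(
    images: list[np.ndarray],
    labels: np.ndarray | list[int],
    ids: list[str] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Feature matrix for in-memory images: one row per image, a ``label``
    column (0 = healthy, 1 = MS), index = sample id."""
    if ids is None:
        ids = [f"img_{k:04d}" for k in range(len(images))]
    rows = []
    for sid, img in zip(ids, images):
        try:
            rows.append(extract_feature_vector(_standardized_image(img, config), config))
        except Exception as exc:  # re-raise with sample context
            raise RuntimeError(f"feature extraction failed for sample {sid!r}: {exc}") from exc
    df = pd.DataFrame(np.asarray(rows), index=pd.Index(ids, name="sample_id"),
                      columns=config.feature_names())
    df["label"] = np.asarray(labels, dtype=np.int64)
    return df


def extract_feature_matrix(
    root: str | Path,
    config: FeatureConfig = FeatureConfig(),
    target_size: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Extract features for a ``<root>/<class>/*.png|jpg`` dataset.

    Rows are ordered by sorted path; class directory names are mapped to
    integer labels by sorted order (two classes expected: the
    lexicographically later name — e.g. ``ms`` after ``healthy`` — gets 1).
    """
    pairs = list_labeled_images(root)
    class_names = sorted({name for _, name in pairs})
    label_of = {name: k for k, name in enumerate(class_names)}
    images, labels, ids = [], [], []
    for path, name in pairs:
        try:
            images.append(load_and_standardize(path, target_size))
        except Exception as exc:
            raise RuntimeError(f"failed to load image {path}: {exc}") from exc
        labels.append(label_of[name])
        ids.append(str(path))
    return extract_feature_matrix_from_arrays(images, labels, ids, config)


def write_feature_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix as CSV: first column sample_id, last column label."""
    df.to_csv(path, index=True)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_feature_csv`."""
    df = pd.read_csv(path, index_col="sample_id")
    if "label" not in df.columns:
        raise ValueError(f"feature CSV {path} lacks a 'label' column")
    return df
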