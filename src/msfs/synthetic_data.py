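"""Synthetic benchmarks with the statistical structure the pipeline assumes.

Two generators stand in for the non-public clinical MRI datasets:

* :func:`make_texture_images` builds *paired* two-class grayscale images:
  a smooth blurred-noise background shared by each healthy/lesioned pair,
  with the lesioned member carrying bright elliptical blobs (emulating
  the hyperintense appearance of demyelinating lesions on T2/FLAIR
  slices).  Pairing isolates the lesion signal, so feature-level
  assertions (e.g. the lesioned mean intensity is strictly larger) hold
  deterministically.

* :func:`make_feature_table` builds a samples x D table in which k known
  "informative" columns are class-shifted Gaussians (shift δ in units of
  the within-class standard deviation) hidden among pure-noise columns —
  the regime where wrapper feature selection demonstrably helps.

Two analytic objectives support optimizer testing without a classifier:
:func:`sphere_objective` and :func:`planted_mask_objective` (a
deterministic stand-in for the wrapper fitness whose unique binary
minimizer is a known mask).

All generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "TextureImageSpec",
    "TableSpec",
    "LabeledImages",
    "make_texture_images",
    "make_feature_table",
    "planted_mask_objective",
    "sphere_objective",
]


@dataclass(frozen=True)
class TextureImageSpec:
    """Parameters of the paired lesioned/healthy image generator.

    Intensities are in gray levels (0-255).  The background is blurred
    uniform noise rescaled to [background_low, background_high]; pixel
    noise is additive Gaussian (std in levels); each lesion adds
    ``lesion_boost`` levels inside a random ellipse.  Separability by
    construction requires boost > 2 x noise_std.
    """

    size: tuple[int, int] = (128, 128)
    blur_sigma: float = 6.0
    lesion_count: tuple[int, int] = (2, 4)
    lesion_radius: tuple[float, float] = (5.0, 8.0)
    lesion_boost: float = 70.0
    noise_std: float = 8.0
    background_low: float = 30.0
    background_high: float = 160.0
    background_mean: float = 95.0
    n_pairs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_boost <= 2 * self.noise_std:
            raise ValueError("lesion_boost must exceed 2 x noise_std for separable classes")
        if self.lesion_radius[1] * 2 >= min(self.size):
            raise ValueError("lesion radius too large for the image size")
        if self.lesion_count[0] < 1:
            raise ValueError("at least one lesion per lesioned image")


@dataclass
class LabeledImages:
    images: list[np.ndarray]
    labels: np.ndarray  # 0 = healthy, 1 = lesioned
    ids: list[str]


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float], angle: float
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    w = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (w / axes[1]) ** 2 <= 1.0


def make_texture_images(spec: TextureImageSpec = TextureImageSpec()) -> LabeledImages:
    """Generate ``2 * n_pairs`` images: each pair shares its background and
    noise field; the lesioned member additionally carries bright blobs."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.size
    images: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    rmin, rmax = spec.lesion_radius
    margin = rmax + 2
    for pair in range(spec.n_pairs):
        base = gaussian_filter(rng.random((rows, cols)), spec.blur_sigma)
        lo, hi = base.min(), base.max()
        base = spec.background_low + (base - lo) / (hi - lo) * (
            spec.background_high - spec.background_low
        )
        # anchor the mean so class brightness differs only by lesion load
        base = base - base.mean() + spec.background_mean
        noise = rng.normal(0.0, spec.noise_std, size=(rows, cols)) if spec.noise_std > 0 else 0.0
        healthy = base + noise
        blobs = np.zeros((rows, cols))
        n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
        for _ in range(n_lesions):
            center = (
                rng.uniform(margin, rows - margin),
                rng.uniform(margin, cols - margin),
            )
            axes = (rng.uniform(rmin, rmax), rng.uniform(rmin, rmax))
            angle = rng.uniform(0.0, math.pi)
            blobs[_ellipse_mask((rows, cols), center, axes, angle)] = spec.lesion_boost
        lesioned = healthy + blobs
        for img, lab, tag in ((healthy, 0, "healthy"), (lesioned, 1, "lesioned")):
            images.append(np.clip(np.rint(img), 0, 255).astype(np.int64))
            labels.append(lab)
            ids.append(f"pair{pair:03d}_{tag}")
    return LabeledImages(images, np.asarray(labels, dtype=np.int64), ids)


@dataclass(frozen=True)
class TableSpec:
    """Parameters of the planted-feature Gaussian table generator."""

    n_per_class: int = 150
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 1.5  # class-mean shift, units of within-class std
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_informative < self.n_features):
            raise ValueError("need 1 <= n_informative < n_features")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")


def make_feature_table(spec: TableSpec = TableSpec()) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-class Gaussian table with ``n_informative`` planted columns.

    Informative columns are N(0,1) for class 0 and N(δ,1) for class 1; all
    other columns are N(0,1) for both classes.  Column order is shuffled;
    the returned index array gives the post-shuffle positions of the
    informative columns.  The DataFrame carries feature columns named
    ``f000..`` plus a final ``label`` column, indexed by sample id.
    """
    rng = np.random.default_rng(spec.seed)
    n, D, k = spec.n_per_class, spec.n_features, spec.n_informative
    X = rng.normal(0.0, 1.0, size=(2 * n, D))
    y = np.repeat([0, 1], n)
    X[y == 1, :k] += spec.effect_size
    perm = rng.permutation(D)
    X = X[:, perm]
    informative = np.sort(np.argsort(perm)[:k])
    ids = [f"s{i:04d}" for i in range(2 * n)]
    df = pd.DataFrame(
        X, index=pd.Index(ids, name="sample_id"), columns=[f"f{j:03d}" for j in range(D)]
    )
    df["label"] = y
    return df, informative


def planted_mask_objective(planted: np.ndarray, alpha: float = 0.99):
    """Deterministic wrapper-fitness stand-in with a known binary minimizer.

    f(x) = α · Hamming(binarize(x), planted)/D + (1−α) · S/D, where S is the
    number of selected coordinates.  Among binary patterns the planted mask
    is the unique minimizer (each wrong bit costs α/D > (1−α)/D, and each
    correctly selected bit saves α/D at a (1−α)/D size cost).
    """
    planted = np.asarray(planted, dtype=bool)
    if not planted.any():
        raise ValueError("planted mask must select at least one feature")
    D = planted.size

    def objective(position: np.ndarray) -> float:
        mask = np.asarray(position) > 0.5
        hamming = int(np.count_nonzero(mask != planted))
        S = int(np.count_nonzero(mask))
        return alpha * hamming / D + (1.0 - alpha) * S / D

    return objective


def sphere_objective(dim: int):
    """f(x) = sum (x_d - 0.5)^2, minimized at the hypercube center."""
    if dim < 1:
        raise ValueError("dim must be >= 1")

    def objective(position: np.ndarray) -> float:
        return float(np.sum((np.asarray(position) - 0.5) ** 2))

    return objective
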