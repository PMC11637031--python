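"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops over pixels/cells so it
shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def first_order_bruteforce(img: np.ndarray, levels: int = 256) -> dict:
    vals = [float(v) for row in np.asarray(img) for v in row]
    N = len(vals)
    m = sum(vals) / N
    var = sum((v - m) ** 2 for v in vals) / N
    std = math.sqrt(var)
    if std > 0:
        skew = sum((v - m) ** 3 for v in vals) / N / std**3
        kurt = sum((v - m) ** 4 for v in vals) / N / std**4
    else:
        skew = kurt = 0.0
    hist = [0] * levels
    for v in vals:
        hist[int(v)] += 1
    entropy = -sum((h / N) * math.log(h / N) for h in hist if h > 0)
    return {"mean": m, "variance": var, "std": std, "skewness": skew,
            "kurtosis": kurt, "entropy": entropy}


def glcm_bruteforce(
    img: np.ndarray, d: int, theta: int, levels: int, normalized: bool = True
) -> np.ndarray:
    arr = np.asarray(img)
    dr, dc = (o * d for o in GLCM_OFFSETS[theta])
    G = np.zeros((levels, levels))
    rows, cols = arr.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                G[arr[r, c], arr[r2, c2]] += 1.0
    return G / G.sum() if normalized else G


def glcm_features_bruteforce(G: np.ndarray) -> dict:
    L = G.shape[0]
    contrast = dissim = homog = asm = 0.0
    for i in range(L):
        for j in range(L):
            g = G[i, j]
            contrast += (i - j) ** 2 * g
            dissim += abs(i - j) * g
            homog += g / (1.0 + (i - j) ** 2)
            asm += g * g
    mu_i = sum(i * G[i, j] for i in range(L) for j in range(L))
    mu_j = sum(j * G[i, j] for i in range(L) for j in range(L))
    sig_i = math.sqrt(sum((i - mu_i) ** 2 * G[i, j] for i in range(L) for j in range(L)))
    sig_j = math.sqrt(sum((j - mu_j) ** 2 * G[i, j] for i in range(L) for j in range(L)))
    if sig_i == 0 or sig_j == 0:
        corr = 1.0
    else:
        corr = sum(
            (i - mu_i) * (j - mu_j) * G[i, j] for i in range(L) for j in range(L)
        ) / (sig_i * sig_j)
    return {"contrast": contrast, "dissimilarity": dissim, "homogeneity": homog,
            "asm": asm, "energy": math.sqrt(asm), "correlation": corr}


def lbp_bruteforce(img: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """Per-pixel circular LBP with scalar bilinear interpolation."""
    arr = np.asarray(img, dtype=float)
    rows, cols = arr.shape
    m = max(1, math.ceil(R))

    def sample(rr: float, cc: float) -> float:
        r0, c0 = math.floor(rr), math.floor(cc)
        tr, tc = rr - r0, cc - c0

        def at(r, c):  # corners with zero weight may fall outside the grid
            return arr[r, c] if r < rows and c < cols else 0.0

        return (
            (1 - tr) * ((1 - tc) * at(r0, c0) + tc * at(r0, c0 + 1))
            + tr * ((1 - tc) * at(r0 + 1, c0) + tc * at(r0 + 1, c0 + 1))
        )

    codes = np.zeros((rows - 2 * m, cols - 2 * m), dtype=int)
    for r in range(m, rows - m):
        for c in range(m, cols - m):
            gc = arr[r, c]
            code = 0
            for p in range(P):
                ang = 2 * math.pi * p / P
                dr = round(-R * math.sin(ang), 8)
                dc = round(R * math.cos(ang), 8)
                gp = sample(r + dr, c + dc)
                if gp - gc >= -1e-9:
                    code += 2**p
            codes[r - m, c - m] = code
    return codes


def friedman_bruteforce(values: np.ndarray, lower_is_better: bool) -> dict:
    """Rank-by-rank Friedman statistic for tie-free tables."""
    values = np.asarray(values, dtype=float)
    R, k = values.shape
    ranks = np.zeros_like(values)
    for b in range(R):
        row = values[b] if lower_is_better else -values[b]
        order = sorted(range(k), key=lambda j: row[j])
        for rank0, j in enumerate(order):
            ranks[b, j] = rank0 + 1
    sums = ranks.sum(axis=0)
    stat = 12.0 / (R * k * (k + 1)) * sum(s * s for s in sums) - 3.0 * R * (k + 1)
    return {"statistic": stat, "mean_ranks": ranks.mean(axis=0)}
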