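"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here recomputes a quantity with a deliberately naive
algorithm (explicit loops, exhaustive search, direct definitions) and is
kept independent of the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def brute_force_log_otsu(pixels: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over all log-histogram bin boundaries for the
    threshold maximizing between-class variance."""
    lx = np.log1p(np.asarray(pixels, dtype=float).ravel())
    hist, edges = np.histogram(lx, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    best_k, best_v = 0, -np.inf
    for k in range(nbins - 1):
        w0 = p[:k + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (p[:k + 1] * centers[:k + 1]).sum() / w0
        mu1 = (p[k + 1:] * centers[k + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_k = v, k
    return float(np.expm1(edges[best_k + 1]))


def brute_force_shells(mask: np.ndarray, patch: np.ndarray, n_shells: int
                       ) -> np.ndarray:
    """Per-pixel loop version of radial shell binning."""
    dist = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    dmax = dist.max()
    sums = np.zeros(n_shells)
    counts = np.zeros(n_shells)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            norm = dist[r, c] / dmax if dmax > 0 else 0.0
            b = min(int(norm * n_shells), n_shells - 1)
            sums[b] += patch[r, c]
            counts[b] += 1
    overall = patch[mask].mean()
    out = np.empty(n_shells)
    for b in range(n_shells):
        out[b] = sums[b] / counts[b] if counts[b] else overall
    return out


def checkerboard_glcm_stats(n: int = 8) -> tuple[float, float]:
    """Hand-enumerated contrast and ASM of a 2-level checkerboard at the
    0-degree offset: every horizontal pair is (0,1) or (1,0), so the
    symmetric normalized GLCM is [[0, .5], [.5, 0]], giving contrast
    sum(P * (i-j)^2) = 1 and ASM = sum(P^2) = 0.5."""
    return 1.0, 0.5


def naive_reconstruction(seed: np.ndarray, mask_img: np.ndarray) -> np.ndarray:
    """Morphological reconstruction by iterated 4-neighbour dilation."""
    cur = np.minimum(seed, mask_img)
    footprint = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    while True:
        dil = ndimage.grey_dilation(cur, footprint=footprint)
        nxt = np.minimum(dil, mask_img)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def brute_force_granularity(mask: np.ndarray, patch: np.ndarray, n: int
                            ) -> np.ndarray:
    """Opening-by-reconstruction sequence computed from first principles
    with an explicit disk(1) erosion and naive reconstruction."""
    img = np.where(mask, patch.astype(float), 0.0)
    start = img.sum()
    out = np.zeros(n)
    if start <= 0:
        return out
    footprint = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    eroded = img.copy()
    prev = start
    for g in range(n):
        eroded = ndimage.grey_erosion(eroded, footprint=footprint)
        rec = naive_reconstruction(eroded, img)
        cur = rec.sum()
        out[g] = 100.0 * (prev - cur) / start
        prev = cur
        if cur <= 0:
            break
    return out


def brute_force_dr(values, threshold: float) -> float:
    """Count-by-loop damage ratio."""
    n_above = 0
    n = 0
    for v in values:
        if np.isfinite(v):
            n += 1
            if v > threshold:
                n_above += 1
    return n_above / n


def brute_force_map_bins(rows_um, cols_um, damage, center_um, diameter_mm,
                         bin_mm, threshold=None):
    """Per-bin loop computation of mean damage (or DR when ``threshold``
    is given) over the circular field; returns dict {(i, j): value}."""
    half_um = diameter_mm * 1000 / 2
    n = int(np.ceil(diameter_mm / bin_mm))
    bins: dict[tuple[int, int], list[float]] = {}
    for r, c, d in zip(rows_um, cols_um, damage):
        if not np.isfinite(d):
            continue
        dr = r - center_um[0]
        dc = c - center_um[1]
        if np.hypot(dr, dc) > half_um:
            continue
        i = int(np.floor((dr + half_um) / (bin_mm * 1000)))
        j = int(np.floor((dc + half_um) / (bin_mm * 1000)))
        if not (0 <= i < n and 0 <= j < n):
            continue
        bins.setdefault((i, j), []).append(d)
    out = {}
    for key, vals in bins.items():
        if threshold is None:
            out[key] = float(np.mean(vals))
        else:
            out[key] = brute_force_dr(vals, threshold)
    return out


def direct_dft_descriptors(contour: np.ndarray, k: int, n_samples: int = 128
                           ) -> np.ndarray:
    """Fourier boundary descriptors via an explicit DFT sum (no FFT)."""
    b = np.asarray(contour, dtype=float)
    if not np.allclose(b[0], b[-1]):
        b = np.vstack([b, b[:1]])
    seg = np.hypot(*np.diff(b, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n_samples, endpoint=False)
    z = np.interp(t, s, b[:, 0]) + 1j * np.interp(t, s, b[:, 1])
    idx = np.arange(n_samples)

    def coeff(f):
        return (z * np.exp(-2j * np.pi * f * idx / n_samples)).sum() / n_samples

    fundamental = max(abs(coeff(1)), abs(coeff(-1)))
    out = [min(abs(coeff(1)), abs(coeff(-1))) / fundamental]
    f = 2
    while len(out) < k:
        out.append(abs(coeff(f)) / fundamental)
        if len(out) < k:
            out.append(abs(coeff(-f)) / fundamental)
        f += 1
    return np.array(out[:k])


def tile_coverage_count(shape, tiles) -> np.ndarray:
    """Per-pixel count of how many tiles cover it."""
    cov = np.zeros(shape, dtype=int)
    for t, (r0, c0) in tiles:
        cov[r0:r0 + t.shape[0], c0:c0 + t.shape[1]] += 1
    return cov
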