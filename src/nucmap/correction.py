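"""Background, stripe and foreground intensity correction.

The correction order is fixed and enforced by :class:`CorrectionModel`:

1. additive background surface (estimated from cell-free pixels),
2. multiplicative fast-axis stripe factors,
3. DAPI foreground normalization anchoring the G1 band at 1 and the G2
   band at 2 via lowess fits of the band centers along the slow axis,
4. gamma-H2AX baseline flattening from the bottom 2-4% of G1-cell
   intensities per ~1 mm^2 block.

Steps 1-2 operate on pixel rasters; steps 3-4 correct the per-nucleus
integrated intensities (sufficient for all downstream consumers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator, griddata
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .types import SlideImage


class InsufficientBackgroundError(ValueError):
    pass


class UnimodalIntensityError(ValueError):
    """DAPI band anchoring needs both a G1 and a G2 band."""


@dataclass
class CorrectionModel:
    """Fitted correction state, in application order."""
    background_surface: np.ndarray | None = None
    stripe_factors: np.ndarray | None = None
    dapi_gain_curve: dict | None = None          # {'x': slow_um, 'g1': ..., 'g2': ...}
    gh2ax_baseline: dict | None = None           # block grid + values
    metadata: dict = field(default_factory=dict)


# -- 1. background surface --------------------------------------------------

def estimate_background_surface(image: SlideImage, background_mask: np.ndarray,
                                block: int = 64, smooth_blocks: float = 1.5
                                ) -> np.ndarray:
    """Smooth additive background field from cell-free pixels.

    The raster is divided into ``block``-pixel squares; each block
    contributes the median of its background pixels, missing blocks are
    nearest-filled, the coarse grid is Gaussian-smoothed and bilinearly
    upsampled.  Requires background coverage of at least 5% of pixels.
    """
    bg = np.asarray(background_mask, dtype=bool)
    if bg.shape != image.shape:
        raise ValueError("background_mask shape mismatch")
    if bg.mean() < 0.05:
        raise InsufficientBackgroundError(
            f"background covers only {bg.mean():.1%} of pixels (needs >= 5%); "
            "estimate on lower-confluence tiles")
    h, w = image.shape
    nr, nc = -(-h // block), -(-w // block)
    coarse = np.full((nr, nc), np.nan)
    px = image.pixels
    for i in range(nr):
        for j in range(nc):
            sl = (slice(i * block, (i + 1) * block), slice(j * block, (j + 1) * block))
            sel = bg[sl]
            if sel.sum() >= 20:
                coarse[i, j] = np.median(px[sl][sel])
    if np.all(np.isnan(coarse)):
        raise InsufficientBackgroundError("no block has enough background pixels")
    # nearest-fill gaps then smooth
    missing = np.isnan(coarse)
    if missing.any():
        idx = ndimage.distance_transform_edt(missing, return_distances=False,
                                             return_indices=True)
        coarse = coarse[tuple(idx)]
    # smooth the residual around a least-squares plane so boundary padding
    # cannot flatten genuinely sloped backgrounds
    gr, gc = np.meshgrid(np.arange(nr, dtype=float), np.arange(nc, dtype=float),
                         indexing="ij")
    A = np.stack([np.ones(coarse.size), gr.ravel(), gc.ravel()], axis=1)
    coef, *_ = np.linalg.lstsq(A, coarse.ravel(), rcond=None)
    plane = (A @ coef).reshape(nr, nc)
    coarse = plane + ndimage.gaussian_filter(coarse - plane, smooth_blocks)

    cr = np.minimum(np.arange(nr) * block + block / 2, h - 0.5)
    cc = np.minimum(np.arange(nc) * block + block / 2, w - 0.5)
    if nr == 1 and nc == 1:
        return np.full((h, w), coarse[0, 0])
    if nr == 1:
        return np.tile(np.interp(np.arange(w), cc, coarse[0])[None, :], (h, 1))
    if nc == 1:
        return np.tile(np.interp(np.arange(h), cr, coarse[:, 0])[:, None], (1, w))
    # linear extrapolation beyond the outermost block centers avoids a flat
    # clamp that would bias sloped backgrounds near the borders
    rgi = RegularGridInterpolator((cr, cc), coarse, method="linear",
                                  bounds_error=False, fill_value=None)
    pr, pc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    return rgi(np.stack([pr.ravel(), pc.ravel()], 1)).reshape(h, w)


def subtract_background(image: SlideImage, surface: np.ndarray) -> SlideImage:
    """Subtract the background surface, clipping at zero counts."""
    return image.with_pixels(np.maximum(image.pixels - surface, 0.0))


# -- 2. stripe removal ------------------------------------------------------

def remove_stripes(image: SlideImage, background_mask: np.ndarray,
                   background_surface: np.ndarray,
                   rolling: int = 31, min_bg_px: int = 50
                   ) -> tuple[SlideImage, np.ndarray]:
    """Estimate and divide out per-scan-line multiplicative stripe factors.

    ``image`` must already be background-flattened; ``background_surface``
    is the surface that was subtracted (needed to convert the residual
    background level of a striped line into its multiplicative factor).
    Scan lines run along ``image.fast_axis``; one factor is estimated per
    line from the line's background residual relative to a rolling median
    across neighbouring lines.  Lines with too few background pixels keep
    factor 1.
    """
    if image.fast_axis not in ("rows", "cols"):
        raise ValueError("fast_axis metadata missing or invalid")
    bg = np.asarray(background_mask, dtype=bool)
    px = image.pixels
    surf = np.asarray(background_surface, dtype=float)
    slow = image.slow_axis
    if slow == 1:
        px_v, bg_v, surf_v = px.T, bg.T, surf.T
    else:
        px_v, bg_v, surf_v = px, bg, surf

    n = px_v.shape[0]
    resid = np.full(n, np.nan)
    level = np.full(n, np.nan)
    for i in range(n):
        sel = bg_v[i]
        if sel.sum() >= min_bg_px:
            resid[i] = np.median(px_v[i][sel])
            level[i] = np.median(surf_v[i][sel])
    ok = np.isfinite(resid)
    if not ok.any():
        return image, np.ones(n)
    # rolling median of residuals across lines captures any leftover trend
    filled = np.interp(np.arange(n), np.flatnonzero(ok), resid[ok])
    trend = ndimage.median_filter(filled, size=rolling, mode="reflect")
    lvl = np.interp(np.arange(n), np.flatnonzero(ok), level[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 + (filled - trend) / np.maximum(lvl, 1e-9)
    factors = np.clip(factors, 0.2, 5.0)

    # divide the raw line (flattened + surface) by its factor, re-flatten
    corrected = (px_v + surf_v) / factors[:, None] - surf_v
    corrected = np.maximum(corrected, 0.0)
    if slow == 1:
        corrected = corrected.T
    return image.with_pixels(np.ascontiguousarray(corrected)), factors


# -- 3. DAPI foreground normalization --------------------------------------

def _em_two_gaussians(x: np.ndarray, max_iter: int = 200, tol: float = 1e-10
                      ) -> tuple[float, float, float]:
    """Deterministic 1D band-center EM; returns (m_lo, m_hi, w_lo_rel).

    Two Gaussians (the G1 and G2 bands) plus a fixed-density uniform
    component over the sample range that absorbs the S-phase cells
    between the bands, so they do not bias the band means.  Percentile
    initialization and the data-range uniform keep the whole procedure
    affine-equivariant, which is what makes the DAPI band normalization
    idempotent.
    """
    x = np.asarray(x, dtype=float)
    m = np.array([np.percentile(x, 25), np.percentile(x, 75)])
    if m[0] == m[1]:
        raise UnimodalIntensityError("degenerate intensity sample")
    s = np.full(2, max(x.std() / 4, 1e-12 * abs(m[1] - m[0]) + 1e-300))
    span = x.max() - x.min()
    log_u = -np.log(span) if span > 0 else 0.0
    w = np.array([0.45, 0.45, 0.10])     # [lo band, hi band, uniform]
    prev = -np.inf
    for _ in range(max_iter):
        logp = np.empty((x.size, 3))
        d = (x[:, None] - m[None, :]) / s[None, :]
        logp[:, :2] = (-0.5 * d * d - np.log(s[None, :])
                       - 0.5 * np.log(2 * np.pi) + np.log(w[None, :2] + 1e-300))
        logp[:, 2] = log_u + np.log(w[2] + 1e-300)
        mx = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - mx)
        tot = p.sum(axis=1, keepdims=True)
        ll = float(np.sum(np.log(tot) + mx[:, 0]))
        r = p / tot
        nk = r.sum(axis=0) + 1e-12
        w = nk / x.size
        m = (r[:, :2] * x[:, None]).sum(axis=0) / nk[:2]
        s = np.sqrt((r[:, :2] * (x[:, None] - m[None, :]) ** 2).sum(axis=0) / nk[:2])
        s = np.maximum(s, 1e-9 * (abs(m).max() + 1))
        if ll - prev < tol * max(abs(ll), 1.0):
            break
        prev = ll
    order = np.argsort(m)
    w_rel = w[order[0]] / (w[order[0]] + w[order[1]])
    return float(m[order[0]]), float(m[order[1]]), float(w_rel)


def normalize_dapi_foreground(records: pd.DataFrame,
                              intensity_col: str = "i_dapi",
                              slow_col: str = "slow_um",
                              n_windows: int = 12,
                              lowess_frac: float = 0.3,
                              min_per_window: int = 150,
                              identity_tol: float = 0.02
                              ) -> tuple[pd.DataFrame, dict]:
    """Anchor the G1 band at 1.0 and the G2 band at 2.0 along the slow axis.

    Per slow-axis window a two-component Gaussian mixture on the
    integrated DAPI intensity locates the band centers; lowess (fraction
    ``lowess_frac``, non-robust so the fit stays linear in the data) tracks
    each band against position, and every nucleus is affinely rescaled so
    the fitted G1 curve maps to 1 and the G2 curve to 2 at its position.

    Returns the updated records (new column ``i_dapi_corr``) and the gain
    curve ``{'x', 'g1', 'g2'}``.  Raises :class:`UnimodalIntensityError`
    when a G2 band cannot be anchored.

    When the fitted bands already sit at 1 and 2 (within ``identity_tol``
    everywhere) the correction is declared converged and returns the
    intensities unchanged, which makes the operation idempotent.
    """
    if len(records) < 500:
        raise ValueError(f"need >= 500 nuclei to anchor DAPI bands, got {len(records)}")
    x = records[slow_col].to_numpy(dtype=float)
    y = records[intensity_col].to_numpy(dtype=float)

    # bimodality is checked per window: a window only contributes when its
    # fitted band centers show a plausible G1/G2 ratio, and fewer than two
    # usable windows is reported as an unimodal distribution below
    n_windows = max(2, min(n_windows, len(records) // (2 * min_per_window)))
    edges = np.quantile(x, np.linspace(0, 1, n_windows + 1))
    centers, g1s, g2s = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (x >= a) & (x <= b)
        if sel.sum() < min_per_window:
            continue
        try:
            m1, m2, _ = _em_two_gaussians(y[sel])
        except UnimodalIntensityError:
            continue
        if not (1.4 <= m2 / max(m1, 1e-12) <= 3.0):
            continue
        centers.append(0.5 * (a + b))
        g1s.append(m1)
        g2s.append(m2)
    if len(centers) < 2:
        raise UnimodalIntensityError("too few windows with resolvable G1/G2 bands")
    centers = np.asarray(centers)
    g1_fit = sm_lowess(np.asarray(g1s), centers, frac=lowess_frac, it=0,
                       return_sorted=True)
    g2_fit = sm_lowess(np.asarray(g2s), centers, frac=lowess_frac, it=0,
                       return_sorted=True)
    g1 = np.interp(x, g1_fit[:, 0], g1_fit[:, 1])
    g2 = np.interp(x, g2_fit[:, 0], g2_fit[:, 1])
    if np.any(g2 - g1 <= 0):
        raise UnimodalIntensityError("fitted G2 band does not sit above G1 band")

    if (np.abs(g1 - 1.0).max() < identity_tol
            and np.abs(g2 - 2.0).max() < 2 * identity_tol):
        corrected = y.copy()        # already anchored: exact identity
    else:
        corrected = 1.0 + (y - g1) / (g2 - g1)
    out = records.copy()
    out["i_dapi_corr"] = corrected
    curve = {"x": centers, "g1": np.asarray(g1s, dtype=float),
             "g2": np.asarray(g2s, dtype=float),
             "g1_fit": g1_fit, "g2_fit": g2_fit, "lowess_frac": lowess_frac}
    return out, curve


# -- 4. gamma-H2AX baseline flattening --------------------------------------

def flatten_gh2ax_foreground(records: pd.DataFrame,
                             gh2ax_col: str = "i_gh2ax",
                             dapi_col: str = "i_dapi_corr",
                             row_col: str = "row_um", col_col: str = "col_um",
                             block_um: float = 1000.0,
                             percentile_band: tuple[float, float] = (2.0, 4.0),
                             g1_range: tuple[float, float] = (0.7, 1.3),
                             min_g1_per_block: int = 20
                             ) -> tuple[pd.DataFrame, dict]:
    """Subtract the locally varying undamaged-cell gamma-H2AX baseline.

    G1 cells (corrected DAPI in ``g1_range``) are grouped into
    ``block_um``-sized blocks; each block's baseline is the mean of its G1
    gamma-H2AX intensities between the 2nd and 4th percentile (undamaged
    cells, since the G1 damage ratio never exceeds 50%).  The baseline is
    capped at the block's G1 median as a guard against flattening real
    damage.  Block baselines are interpolated into a smooth surface,
    subtracted from every nucleus and clipped at zero (new column
    ``i_gh2ax_corr``).
    """
    if dapi_col not in records:
        raise ValueError("run normalize_dapi_foreground first (missing corrected DAPI)")
    r = records[row_col].to_numpy(dtype=float)
    c = records[col_col].to_numpy(dtype=float)
    g = records[gh2ax_col].to_numpy(dtype=float)
    g1 = records[dapi_col].between(*g1_range).to_numpy()

    lo, hi = percentile_band
    bi = np.floor((r - r.min()) / block_um).astype(int)
    bj = np.floor((c - c.min()) / block_um).astype(int)
    pts, vals = [], []
    n_blocks = 0
    for i in np.unique(bi):
        for j in np.unique(bj):
            sel = g1 & (bi == i) & (bj == j)
            n_blocks += 1
            if sel.sum() < min_g1_per_block:
                continue
            sub = g[sel]
            p_lo, p_hi = np.percentile(sub, [lo, hi])
            band = sub[(sub >= p_lo) & (sub <= p_hi)]
            base = float(band.mean()) if band.size else float(p_lo)
            base = min(base, float(np.median(sub)))   # damage-flattening guard
            pts.append((r.min() + (i + 0.5) * block_um,
                        c.min() + (j + 0.5) * block_um))
            vals.append(base)
    if not pts:
        raise ValueError(
            f"no block of {block_um} um contains >= {min_g1_per_block} G1 cells")
    pts = np.asarray(pts)
    vals = np.asarray(vals)
    if len(pts) == 1:
        baseline = np.full(len(records), vals[0])
    else:
        baseline = griddata(pts, vals, np.stack([r, c], 1), method="linear")
        nn = griddata(pts, vals, np.stack([r, c], 1), method="nearest")
        baseline = np.where(np.isfinite(baseline), baseline, nn)
    out = records.copy()
    out["i_gh2ax_corr"] = np.maximum(g - baseline, 0.0)
    surface = {"points_um": pts, "values": vals, "block_um": block_um,
               "percentile_band": percentile_band, "n_blocks": n_blocks}
    return out, surface
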