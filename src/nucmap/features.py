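"""Per-nucleus feature extraction from the DAPI (and gamma-H2AX) channels.

Feature families: shape (region properties + Fourier boundary
descriptors), intensity statistics, radial shell intensities, Haralick
texture on the gray-level co-occurrence matrix, and a morphological
granularity spectrum.  The gamma-H2AX channel contributes intensity
statistics only.

Defaults (versioned in :data:`FEATURE_CONFIG`): 16 Fourier magnitudes,
4 shells, 13 Haralick statistics at distance 1 averaged over 4 offsets
with 64 gray levels, 16 granularity elements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .types import QCMask, SlideImage

FEATURE_CONFIG = {
    "fourier_k": 16,
    "shells": 4,
    "haralick_levels": 64,
    "granularity_elements": 16,
    "version": 1,
}

ALL_FAMILIES = ("shape", "fourier", "intensity", "shell", "haralick", "granularity")


# -- shape ------------------------------------------------------------------

def shape_features(region_mask: np.ndarray, pixel_size: float) -> dict:
    """Area, perimeter (um), eccentricity, solidity, orientation of one region."""
    m = np.asarray(region_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty region")
    props = measure.regionprops(m.astype(np.uint8))[0]
    return {
        "area_um2": props.area * pixel_size**2,
        "perimeter_um": props.perimeter * pixel_size,
        "eccentricity": props.eccentricity,
        "solidity": props.solidity,
        "orientation": props.orientation,
    }


def region_contour(region_mask: np.ndarray) -> np.ndarray:
    """Closed sub-pixel boundary of the largest connected region."""
    padded = np.pad(np.asarray(region_mask, dtype=float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("region has no boundary")
    return max(contours, key=len) - 1.0


def fourier_descriptors(boundary: np.ndarray, k: int = 16,
                        n_samples: int = 128) -> np.ndarray:
    """Translation/rotation/scale/start-point invariant boundary descriptors.

    The closed contour is resampled to ``n_samples`` points by arc length,
    read as complex numbers, Fourier transformed; the DC term is dropped
    and magnitudes are normalized by the first (fundamental) harmonic.
    Descriptor order interleaves negative and positive frequencies:
    ``|c_-1|, |c_2|, |c_-2|, |c_3|, ...`` over the fundamental magnitude.
    """
    b = np.asarray(boundary, dtype=float)
    if len(b) < 2 * k:
        raise ValueError(f"contour of {len(b)} points too short for K={k}")
    if not np.allclose(b[0], b[-1]):
        b = np.vstack([b, b[:1]])
    seg = np.hypot(*np.diff(b, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour")
    t = np.linspace(0.0, total, n_samples, endpoint=False)
    z = np.interp(t, s, b[:, 0]) + 1j * np.interp(t, s, b[:, 1])
    coeffs = np.fft.fft(z) / n_samples
    fundamental = max(abs(coeffs[1]), abs(coeffs[-1]))
    if fundamental == 0:
        raise ValueError("degenerate contour (zero fundamental harmonic)")
    minor = min(abs(coeffs[1]), abs(coeffs[-1]))
    out = [minor / fundamental]
    f = 2
    while len(out) < k:
        out.append(abs(coeffs[f % n_samples]) / fundamental)
        if len(out) < k:
            out.append(abs(coeffs[-f % n_samples]) / fundamental)
        f += 1
    return np.array(out[:k])


# -- radial shells ----------------------------------------------------------

def shell_intensities(region_mask: np.ndarray, image_patch: np.ndarray,
                      n_shells: int = 4) -> np.ndarray:
    """Mean intensity in equal-width bins of normalized boundary distance.

    Distance-to-boundary is normalized to [0, 1] (0 = boundary, 1 =
    innermost); shell 0 is the outermost ring, shell ``n_shells - 1`` the
    core.  Empty shells (possible for very small regions) report the
    region mean.
    """
    if n_shells < 2:
        raise ValueError("need at least 2 shells")
    m = np.asarray(region_mask, dtype=bool)
    if m.sum() < n_shells:
        raise ValueError(f"region of {m.sum()} px too small for {n_shells} shells")
    dist = ndimage.distance_transform_edt(np.pad(m, 1))[1:-1, 1:-1]
    dmax = dist.max()
    norm = dist / dmax if dmax > 0 else dist
    bins = np.clip((norm * n_shells).astype(int), 0, n_shells - 1)
    vals = np.asarray(image_patch, dtype=float)
    out = np.empty(n_shells)
    overall = vals[m].mean()
    for sidx in range(n_shells):
        sel = m & (bins == sidx)
        out[sidx] = vals[sel].mean() if sel.any() else overall
    return out


# -- Haralick texture -------------------------------------------------------

_HARALICK_NAMES = [
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "imc1", "imc2",
]

_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))   # 0, 45, 90, 135 degrees


def quantize(image_patch: np.ndarray, region_mask: np.ndarray, levels: int
             ) -> np.ndarray:
    """Per-region min-max quantization to ``levels`` gray levels; pixels
    outside the region get the sentinel value ``levels``."""
    m = np.asarray(region_mask, dtype=bool)
    vals = np.asarray(image_patch, dtype=float)
    lo, hi = vals[m].min(), vals[m].max()
    q = np.full(vals.shape, levels, dtype=np.int32)
    if hi > lo:
        q[m] = np.minimum(((vals[m] - lo) / (hi - lo) * levels).astype(int),
                          levels - 1)
    else:
        q[m] = 0
    return q


def glcm(quantized: np.ndarray, offset: tuple[int, int], levels: int
         ) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one offset,
    counting only pairs with both pixels inside the region."""
    dr, dc = offset
    h, w = quantized.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = quantized[r0s:r0e, c0s:c0e].ravel()
    b = quantized[r0s + dr:r0e + dr, c0s + dc:c0e + dc].ravel()
    ok = (a < levels) & (b < levels)
    p = np.zeros((levels, levels))
    np.add.at(p, (a[ok], b[ok]), 1.0)
    p = p + p.T
    tot = p.sum()
    return p / tot if tot > 0 else p


def haralick_from_glcm(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized GLCM.

    Degenerate (constant-region) matrices return the closed-form limits:
    ASM 1, contrast 0, and correlation 0 by convention.
    """
    levels = p.shape[0]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    eps = 1e-12

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    asm = (p ** 2).sum()
    contrast = ((ii - jj) ** 2 * p).sum()
    if sd_x > 0 and sd_y > 0:
        correlation = (((ii - mu_x) * (jj - mu_y) * p).sum()) / (sd_x * sd_y)
    else:
        correlation = 0.0
    variance = ((ii - mu_x) ** 2 * p).sum()
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()

    k_sum = np.arange(2 * levels - 1)
    p_sum = np.zeros(2 * levels - 1)
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    sum_average = (k_sum * p_sum).sum()
    sum_variance = ((k_sum - sum_average) ** 2 * p_sum).sum()
    sum_entropy = -(p_sum * np.log(p_sum + eps)).sum()

    entropy = -(p * np.log(p + eps)).sum()

    k_diff = np.arange(levels)
    p_diff = np.zeros(levels)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    diff_average = (k_diff * p_diff).sum()
    difference_variance = ((k_diff - diff_average) ** 2 * p_diff).sum()
    difference_entropy = -(p_diff * np.log(p_diff + eps)).sum()

    hx = -(px * np.log(px + eps)).sum()
    hy = -(py * np.log(py + eps)).sum()
    pxy = px[:, None] * py[None, :]
    hxy1 = -(p * np.log(pxy + eps)).sum()
    hxy2 = -(pxy * np.log(pxy + eps)).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.array([asm, contrast, correlation, variance, idm, sum_average,
                     sum_variance, sum_entropy, entropy, difference_variance,
                     difference_entropy, imc1, imc2])


def haralick_features(region_mask: np.ndarray, image_patch: np.ndarray,
                      levels: int = 64,
                      offsets: tuple = _OFFSETS) -> np.ndarray:
    """13 Haralick statistics averaged over the four distance-1 offsets."""
    m = np.asarray(region_mask, dtype=bool)
    if m.sum() < 4:
        raise ValueError("region too small for texture analysis")
    if levels < 8:
        raise ValueError("need at least 8 gray levels")
    q = quantize(image_patch, m, levels)
    stats = [haralick_from_glcm(glcm(q, off, levels)) for off in offsets]
    return np.mean(stats, axis=0)


# -- granularity ------------------------------------------------------------

def granularity_spectrum(region_mask: np.ndarray, image_patch: np.ndarray,
                         n_elements: int = 16) -> np.ndarray:
    """Morphological granularity: percent of intensity removed per scale.

    Iteratively erodes the masked image with a 3x3 disk and reconstructs
    under the original; element g is the percentage of the starting
    integrated intensity removed between scales g-1 and g.  The spectrum
    sums to at most 100 and is invariant to global intensity scaling.
    """
    if n_elements < 1:
        raise ValueError("need at least one granularity element")
    m = np.asarray(region_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty region")
    img = np.where(m, np.asarray(image_patch, dtype=float), 0.0)
    start = img.sum()
    out = np.zeros(n_elements)
    if start <= 0:
        return out
    selem = morphology.disk(1)
    eroded = img.copy()
    prev = start
    for g in range(n_elements):
        eroded = morphology.erosion(eroded, selem)
        rec = morphology.reconstruction(np.minimum(eroded, img), img)
        cur = rec.sum()
        out[g] = 100.0 * (prev - cur) / start
        prev = cur
        if cur <= 0:
            break
    return out


# -- intensity --------------------------------------------------------------

_QUANTILES = (5, 25, 50, 75, 95)


def intensity_features(region_mask: np.ndarray, image_patch: np.ndarray) -> dict:
    """Integrated/mean/std intensity and the 5/25/50/75/95% quantiles."""
    m = np.asarray(region_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty region")
    v = np.asarray(image_patch, dtype=float)[m]
    qs = np.percentile(v, _QUANTILES)
    out = {"integrated": float(v.sum()), "mean": float(v.mean()),
           "std": float(v.std())}
    out.update({f"q{q:02d}": float(val) for q, val in zip(_QUANTILES, qs)})
    return out


# -- table-level extraction -------------------------------------------------

def feature_columns(families=ALL_FAMILIES, config=None) -> list[str]:
    """Stable, documented column order of the feature table."""
    cfg = {**FEATURE_CONFIG, **(config or {})}
    cols: list[str] = []
    if "shape" in families:
        cols += ["area_um2", "perimeter_um", "eccentricity", "solidity", "orientation"]
    if "fourier" in families:
        cols += [f"fd_{k:02d}" for k in range(1, cfg["fourier_k"] + 1)]
    if "intensity" in families:
        for ch in ("dapi", "gh2ax"):
            cols += [f"{ch}_{s}" for s in
                     ("integrated", "mean", "std", "q05", "q25", "q50", "q75", "q95")]
    if "shell" in families:
        cols += [f"shell_{s}" for s in range(1, cfg["shells"] + 1)]
    if "haralick" in families:
        cols += [f"har_{name}" for name in _HARALICK_NAMES]
    if "granularity" in families:
        cols += [f"gran_{g:02d}" for g in range(1, cfg["granularity_elements"] + 1)]
    return cols


def extract_features(labels: np.ndarray, dapi: SlideImage,
                     gh2ax: SlideImage | None = None,
                     families=ALL_FAMILIES,
                     qc: QCMask | None = None,
                     config: dict | None = None) -> pd.DataFrame:
    """Per-nucleus feature table for every label in raster order.

    Output columns: ``nucleus_id``, centroid in px and um, ``qc_pass``,
    then the families from :func:`feature_columns`.  Records whose
    centroid lands on a QC-masked tile are flagged ``qc_pass = False``
    and carry NaN features.  Extraction is deterministic and
    tile-order independent (regions are processed by label id).
    """
    cfg = {**FEATURE_CONFIG, **(config or {})}
    ps = dapi.pixel_size
    cols = feature_columns(families, cfg)
    rows = []
    gh_px = gh2ax.pixels if gh2ax is not None else None
    for p in measure.regionprops(labels, intensity_image=dapi.pixels):
        r0, c0, r1, c1 = p.bbox
        mask = p.image
        patch = p.image_intensity
        cen_r, cen_c = p.centroid
        rec: dict = {
            "nucleus_id": p.label,
            "centroid_row": cen_r, "centroid_col": cen_c,
            "row_um": cen_r * ps + dapi.origin[0],
            "col_um": cen_c * ps + dapi.origin[1],
            "qc_pass": True,
        }
        if qc is not None and not bool(qc.passes(np.array([cen_r]), np.array([cen_c]))[0]):
            rec["qc_pass"] = False
            rec.update({c: np.nan for c in cols})
            rows.append(rec)
            continue
        if "shape" in families:
            rec.update({
                "area_um2": p.area * ps**2,
                "perimeter_um": p.perimeter * ps,
                "eccentricity": p.eccentricity,
                "solidity": p.solidity,
                "orientation": p.orientation,
            })
        if "fourier" in families:
            try:
                fds = fourier_descriptors(region_contour(mask), cfg["fourier_k"])
            except ValueError:
                fds = np.full(cfg["fourier_k"], np.nan)
            rec.update({f"fd_{k:02d}": v for k, v in enumerate(fds, 1)})
        if "intensity" in families:
            for ch, img in (("dapi", patch),
                            ("gh2ax", gh_px[r0:r1, c0:c1] if gh_px is not None else None)):
                if img is None:
                    rec.update({f"{ch}_{s}": np.nan for s in
                                ("integrated", "mean", "std", "q05", "q25",
                                 "q50", "q75", "q95")})
                else:
                    rec.update({f"{ch}_{k}": v for k, v in
                                intensity_features(mask, img).items()})
        if "shell" in families:
            try:
                sh = shell_intensities(mask, patch, cfg["shells"])
            except ValueError:
                sh = np.full(cfg["shells"], np.nan)
            rec.update({f"shell_{s}": v for s, v in enumerate(sh, 1)})
        if "haralick" in families:
            try:
                har = haralick_features(mask, patch, cfg["haralick_levels"])
            except ValueError:
                har = np.full(13, np.nan)
            rec.update({f"har_{n}": v for n, v in zip(_HARALICK_NAMES, har)})
        if "granularity" in families:
            gr = granularity_spectrum(mask, patch, cfg["granularity_elements"])
            rec.update({f"gran_{g:02d}": v for g, v in enumerate(gr, 1)})
        rows.append(rec)
    base = ["nucleus_id", "centroid_row", "centroid_col", "row_um", "col_um", "qc_pass"]
    return pd.DataFrame(rows, columns=base + cols)
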