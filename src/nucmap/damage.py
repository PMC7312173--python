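"""Per-nucleus DNA-damage values, control-baseline subtraction, damage
ratios and spatially binned damage maps.

The per-nucleus damage is the gamma-H2AX / DAPI integrated-intensity
ratio mapped onto a 0-150 display scale.  The scale factor is calibrated
once per run (99.9th percentile of the treated cohort -> 150) and stored,
so a damage-ratio threshold of 75 reads as "half of maximum damage".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import QCMask

DAMAGE_MAX = 150.0
DEFAULT_DR_THRESHOLD = 75.0

#: reason codes in DamageMap.reasons
MAP_OK = 0
MAP_OUTSIDE = 1        # bin center outside the circular field of view
MAP_EMPTY = 2          # no cells in bin
MAP_QC = 3             # bin overlaps a discarded (QC-masked) region


def calibrate_damage_scale(ratios, percentile: float = 99.9) -> float:
    """Scale mapping raw intensity ratios to the 0-150 display range."""
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("cannot calibrate on an empty cohort")
    p = np.percentile(r, percentile)
    if p <= 0:
        raise ValueError("calibration percentile is non-positive")
    return DAMAGE_MAX / float(p)


def damage_value(i_gh2ax, i_dapi, scale: float) -> np.ndarray:
    """Per-nucleus damage, clamped to [0, 150]; NaN where I_DAPI <= 0."""
    g = np.asarray(i_gh2ax, dtype=float)
    d = np.asarray(i_dapi, dtype=float)
    out = np.full(np.broadcast(g, d).shape, np.nan)
    ok = d > 0
    out[ok] = np.clip(scale * np.broadcast_to(g, out.shape)[ok]
                      / np.broadcast_to(d, out.shape)[ok], 0.0, DAMAGE_MAX)
    return out


def subtract_control_baseline(treated, control) -> np.ndarray:
    """Subtract the flow-control median damage, flooring at zero."""
    c = np.asarray(control, dtype=float)
    c = c[np.isfinite(c)]
    if c.size == 0:
        raise ValueError("control cohort is empty")
    t = np.asarray(treated, dtype=float)
    return np.maximum(t - np.median(c), 0.0)


def damage_ratio(values, threshold: float = DEFAULT_DR_THRESHOLD) -> float:
    """Fraction of cells with damage strictly above ``threshold``."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("damage_ratio of an empty cohort is undefined")
    return float((v > threshold).sum() / v.size)


@dataclass
class DamageMap:
    """Square grid of spatially binned damage statistics.

    ``values`` and ``counts`` are (n, n) arrays over bins of ``bin_mm``
    covering a circular field of ``diameter_mm`` centered on
    ``center_um``.  ``reasons`` explains missing bins; values there are
    NaN and should render white.
    """
    values: np.ndarray
    counts: np.ndarray
    reasons: np.ndarray
    bin_mm: float
    diameter_mm: float
    center_um: tuple[float, float]
    statistic: str = "mean_damage"
    phase_filter: str = "all"
    metadata: dict = field(default_factory=dict)

    @property
    def bin_centers_mm(self) -> np.ndarray:
        """Signed bin-center offsets from the treatment center, in mm."""
        n = self.values.shape[0]
        return (np.arange(n) - (n - 1) / 2.0) * self.bin_mm

    def radial_profile(self, n_rings: int | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Azimuthally averaged map value vs radius (mm), count-weighted."""
        c = self.bin_centers_mm
        rr, cc = np.meshgrid(c, c, indexing="ij")
        rad = np.hypot(rr, cc)
        ok = np.isfinite(self.values)
        n_rings = n_rings or int(np.ceil(self.diameter_mm / 2 / self.bin_mm))
        edges = np.linspace(0, self.diameter_mm / 2, n_rings + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        prof = np.full(n_rings, np.nan)
        for i in range(n_rings):
            sel = ok & (rad >= edges[i]) & (rad < edges[i + 1])
            if sel.any():
                w = self.counts[sel]
                if w.sum() > 0:
                    prof[i] = np.average(self.values[sel], weights=w)
        return mids, prof

    def to_csv(self, path) -> None:
        c = self.bin_centers_mm
        df = pd.DataFrame(self.values, index=c, columns=c)
        df.to_csv(path, index_label="row_mm")

    def to_png(self, path, cmap: str = "inferno") -> None:
        """Render with missing bins in white."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        cm = plt.get_cmap(cmap).copy()
        cm.set_bad("white")
        half = self.diameter_mm / 2
        fig, ax = plt.subplots(figsize=(5, 4.4))
        im = ax.imshow(np.ma.masked_invalid(self.values), cmap=cm,
                       extent=[-half, half, half, -half])
        label = ("DR" if self.statistic == "DR" else "damage")
        fig.colorbar(im, ax=ax, label=label)
        ax.set_xlabel("mm")
        ax.set_ylabel("mm")
        ax.set_title(f"{self.statistic} ({self.phase_filter})")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_damage_map(records: pd.DataFrame,
                     treatment_center_um: tuple[float, float],
                     diameter_mm: float = 18.0,
                     bin_mm: float = 0.25,
                     statistic: str = "mean_damage",
                     phase_filter: str = "all",
                     qc: QCMask | None = None,
                     pixel_size: float | None = None,
                     dr_threshold: float = DEFAULT_DR_THRESHOLD,
                     damage_col: str = "damage",
                     phase_col: str = "phase") -> DamageMap:
    """Bin per-nucleus damage into a circular map around the treatment spot.

    ``statistic``: ``mean_damage``, ``median_damage`` or ``DR``.  Cells are
    assigned to the bin containing their centroid; bins outside the
    circular field, without cells, or overlapping QC-masked tiles are
    missing.  Records flagged ``qc_pass == False`` or with non-finite
    damage never contribute.
    """
    if statistic not in ("mean_damage", "median_damage", "DR"):
        raise ValueError(f"unknown statistic {statistic!r}")
    df = records
    if phase_filter != "all":
        df = df[df[phase_col] == phase_filter]
        if len(df) == 0:
            import logging
            logging.getLogger(__name__).warning(
                "no cells with phase %s; map will be empty", phase_filter)
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    dmg = df[damage_col].to_numpy(dtype=float)
    ok = np.isfinite(dmg)
    df = df[ok]
    dmg = dmg[ok]

    n = int(np.ceil(diameter_mm / bin_mm))
    half_um = diameter_mm * 1000.0 / 2.0
    r = df["row_um"].to_numpy(dtype=float) - treatment_center_um[0]
    c = df["col_um"].to_numpy(dtype=float) - treatment_center_um[1]
    inside = np.hypot(r, c) <= half_um
    bi = np.floor((r + half_um) / (bin_mm * 1000.0)).astype(int)
    bj = np.floor((c + half_um) / (bin_mm * 1000.0)).astype(int)
    inside &= (bi >= 0) & (bi < n) & (bj >= 0) & (bj < n)

    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    reasons = np.full((n, n), MAP_EMPTY, dtype=np.int8)

    cen = (np.arange(n) - (n - 1) / 2.0) * bin_mm
    rr, cc = np.meshgrid(cen, cen, indexing="ij")
    # a bin is outside only when no part of it intersects the disk, so every
    # in-disk cell lands in a live bin
    near_r = np.maximum(np.abs(rr) - bin_mm / 2.0, 0.0)
    near_c = np.maximum(np.abs(cc) - bin_mm / 2.0, 0.0)
    reasons[np.hypot(near_r, near_c) > diameter_mm / 2.0] = MAP_OUTSIDE

    if qc is not None and pixel_size is not None:
        qc_bad = qc.pixel_mask()
        for i in range(n):
            for j in range(n):
                if reasons[i, j] == MAP_OUTSIDE:
                    continue
                r0 = (treatment_center_um[0] - half_um + i * bin_mm * 1000) / pixel_size
                c0 = (treatment_center_um[1] - half_um + j * bin_mm * 1000) / pixel_size
                r1 = r0 + bin_mm * 1000 / pixel_size
                c1 = c0 + bin_mm * 1000 / pixel_size
                r0, c0 = max(int(r0), 0), max(int(c0), 0)
                r1 = min(int(np.ceil(r1)), qc_bad.shape[0])
                c1 = min(int(np.ceil(c1)), qc_bad.shape[1])
                if r0 < r1 and c0 < c1 and qc_bad[r0:r1, c0:c1].any():
                    reasons[i, j] = MAP_QC

    order = np.lexsort((bj[inside], bi[inside]))
    bi_s, bj_s, d_s = bi[inside][order], bj[inside][order], dmg[inside][order]
    if len(bi_s):
        cut = np.flatnonzero(np.diff(bi_s * n + bj_s)) + 1
        starts = np.concatenate([[0], cut])
        ends = np.concatenate([cut, [len(bi_s)]])
        for s, e in zip(starts, ends):
            i, j = int(bi_s[s]), int(bj_s[s])
            if reasons[i, j] in (MAP_OUTSIDE, MAP_QC):
                continue
            vals = np.sort(d_s[s:e])     # order-stable float reductions
            counts[i, j] = e - s
            if statistic == "mean_damage":
                values[i, j] = vals.mean()
            elif statistic == "median_damage":
                values[i, j] = float(np.median(vals))
            else:
                values[i, j] = damage_ratio(vals, dr_threshold)
            reasons[i, j] = MAP_OK

    return DamageMap(values=values, counts=counts, reasons=reasons,
                     bin_mm=bin_mm, diameter_mm=diameter_mm,
                     center_um=tuple(treatment_center_um), statistic=statistic,
                     phase_filter=phase_filter,
                     metadata={"dr_threshold": dr_threshold,
                               "n_records_binned": int(counts.sum())})
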