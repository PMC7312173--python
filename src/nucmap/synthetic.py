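"""Ground-truthed synthetic two-channel slides.

Renders ellipse-like nuclei with per-phase DNA content and morphology on a
dark background, adds a gamma-H2AX channel whose per-nucleus signal tracks a
configurable radial damage field, then layers on the acquisition artifacts a
real scanner produces: smooth foreground gain drift along the slow axis, an
additive background surface, multiplicative fast-axis stripes, locally
blurred rectangles and Poisson-Gaussian noise.

Everything is driven by a single integer seed and reproduces bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial import polynomial as npoly
from scipy import ndimage

from .types import FastAxis, SlideImage, rng_for

PHASES = ("G1", "S", "G2", "M2", "M3", "M4", "M5")
INTERPHASE = ("G1", "S", "G2")
MITOTIC = ("M2", "M3", "M4", "M5")


class PlacementError(RuntimeError):
    """Raised when nucleus placement cannot reach the requested density."""


@dataclass
class ArtifactSpec:
    """Acquisition-artifact and damage-field configuration.

    All spatial quantities are micrometres.  ``background_coeffs`` are 2D
    polynomial coefficients evaluated with ``polyval2d`` on normalized
    (row, col) in [0, 1]; the resulting additive surface must be
    non-negative.  ``stripe_factor`` multiplies every ``stripe_period``-th
    scan line (factors must stay positive).
    """

    # foreground gain drift along the slow axis: g(x) = 1 + A * sin(x / L)
    gain_amplitude: float = 0.0
    gain_length_um: float = 1000.0

    # additive background (counts), same surface for both channels unless
    # gh2ax_background_coeffs is given
    background_coeffs: list | None = None
    gh2ax_background_coeffs: list | None = None

    # multiplicative stripes along the fast axis
    stripe_period: int = 0          # 0 disables
    stripe_factor: float = 1.2

    # locally blurred rectangles: (r0, c0, r1, c1, sigma_px) in pixels
    blur_regions: list = field(default_factory=list)

    # noise: Poisson with `poisson_scale` counts/photon (0 disables) then
    # additive Gaussian sigma counts
    poisson_scale: float = 0.0
    gaussian_sigma: float = 0.0

    # damage field
    damage_mode: str = "none"        # none | plain | ring
    damage_amplitude: float = 0.8
    damage_decay_um: float = 1500.0
    ring_radius_um: float = 1000.0
    ring_width_um: float = 400.0
    damage_penetrance: float = 1.0   # fraction of cells that feel the field
    treatment_center_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.stripe_factor <= 0:
            raise ValueError("stripe_factor must be > 0")
        if self.damage_mode not in ("none", "plain", "ring"):
            raise ValueError(f"unknown damage_mode {self.damage_mode!r}")

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        if d["treatment_center_um"] is not None:
            d["treatment_center_um"] = list(d["treatment_center_um"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ArtifactSpec":
        d = yaml.safe_load(text) or {}
        if d.get("treatment_center_um") is not None:
            d["treatment_center_um"] = tuple(d["treatment_center_um"])
        return cls(**d)

    def background_surface(self, shape: tuple[int, int], channel: str = "dapi") -> np.ndarray:
        coeffs = self.background_coeffs
        if channel == "gh2ax" and self.gh2ax_background_coeffs is not None:
            coeffs = self.gh2ax_background_coeffs
        if coeffs is None:
            return np.zeros(shape)
        rr, cc = np.meshgrid(np.linspace(0.0, 1.0, shape[0]),
                             np.linspace(0.0, 1.0, shape[1]), indexing="ij")
        surf = npoly.polyval2d(rr, cc, np.asarray(coeffs, dtype=float)).astype(float)
        if surf.min() < 0:
            raise ValueError("background surface must be non-negative everywhere")
        return surf.copy()


def radial_damage_field(distance_um, spec: ArtifactSpec) -> np.ndarray:
    """True damage fraction at a given distance from the treatment center.

    ``plain`` mode decays monotonically (Gaussian falloff with scale
    ``damage_decay_um``); ``ring`` mode peaks at ``ring_radius_um``.
    """
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance from treatment center must be >= 0")
    if spec.damage_mode == "none":
        return np.zeros_like(d)
    if spec.damage_mode == "plain":
        return spec.damage_amplitude * np.exp(-0.5 * (d / spec.damage_decay_um) ** 2)
    # ring
    return spec.damage_amplitude * np.exp(
        -0.5 * ((d - spec.ring_radius_um) / spec.ring_width_um) ** 2)


# -- per-phase morphology ---------------------------------------------------

# mean area (um^2), mean DNA content (G1 population mean = 1), speckle sigma
_PHASE_PARAMS = {
    # phase: (area_mean, area_cv, dna_mean, dna_sd, axis_ratio_range, speckle)
    "G1": (180.0, 0.10, 1.0, 0.035, (0.70, 0.95), 0.18),
    "S":  (None,  0.08, None, 0.0,  (0.70, 0.95), 0.18),   # interpolated
    "G2": (320.0, 0.10, 2.0, 0.07, (0.70, 0.95), 0.18),
    "M2": (250.0, 0.08, 2.3, 0.08, (0.85, 1.00), 0.45),
    "M3": (250.0, 0.08, 2.3, 0.08, (0.30, 0.40), 0.45),
    "M4": (250.0, 0.08, 2.3, 0.08, (0.85, 1.00), 0.45),    # dumbbell
    "M5": (120.0, 0.08, 1.1, 0.05, (0.80, 0.95), 0.40),
}


def _sample_phase_geometry(phase: str, rng: np.random.Generator):
    area_mean, area_cv, dna_mean, dna_sd, ratio_rng, speckle = _PHASE_PARAMS[phase]
    if phase == "S":
        dna = rng.uniform(1.05, 1.95)
        frac = (dna - 1.0) / 1.0
        area_mean = 180.0 + frac * (320.0 - 180.0)
    else:
        dna = max(0.2, rng.normal(dna_mean, dna_sd))
    area = max(30.0, rng.normal(area_mean, area_cv * area_mean))
    ratio = rng.uniform(*ratio_rng)
    orientation = rng.uniform(0, np.pi)
    return area, ratio, orientation, dna, speckle


def _ellipse_mask(shape, center, major_px, minor_px, orientation):
    """Boolean raster of an ellipse plus the normalized elliptical radius."""
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    co, si = np.cos(orientation), np.sin(orientation)
    u = rr * co + cc * si
    v = -rr * si + cc * co
    rho = np.sqrt((u / major_px) ** 2 + (v / minor_px) ** 2)
    return rho <= 1.0, rho


def _render_soft_ellipse(rho: np.ndarray, edge: float = 0.15) -> np.ndarray:
    """Smooth ellipse profile, compactly supported inside rho <= 1.

    Smoothstep rolloff over the outer ``edge`` fraction of the radius, so
    every rendered photon lies inside the geometric (ground-truth) ellipse
    and per-nucleus integrated intensity matches DNA content exactly.
    """
    t = np.clip((1.0 - rho) / edge, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _speckle(shape, sigma, rng, smooth=1.0):
    tex = rng.normal(0.0, sigma, size=shape)
    if smooth > 0:
        tex = ndimage.gaussian_filter(tex, smooth)
    return np.exp(tex)


def _render_nucleus(phase, area_px2, ratio, orientation, rng, speckle_sigma,
                    center_frac=(0.0, 0.0)):
    """Render one nucleus on a local patch.

    ``center_frac`` is the sub-pixel offset of the true center, so the
    rendered profile and the ground-truth ellipse stay aligned when the
    patch is pasted at integer coordinates.  Returns (dapi_patch,
    ellipse_params) where the patch integrates to 1 and ellipse_params =
    (center_r, center_c, major_px, minor_px, orientation) in patch
    coordinates of the geometric (ground-truth) ellipse.
    """
    if phase == "M4":
        # two touching half-size lobes along the orientation axis
        lobe_area = area_px2 / 2.0
        r_lobe = np.sqrt(lobe_area / np.pi)
        sep = 1.55 * r_lobe
        size = int(np.ceil(2 * (sep + r_lobe) + 8)) | 1  # odd: integer paste offset
        patch = np.zeros((size, size))
        ctr_r = (size - 1) / 2.0 + center_frac[0]
        ctr_c = (size - 1) / 2.0 + center_frac[1]
        for sgn in (-1.0, 1.0):
            cr = ctr_r + sgn * (sep / 2.0) * np.cos(orientation)
            cc = ctr_c + sgn * (sep / 2.0) * np.sin(orientation)
            _, rho = _ellipse_mask(patch.shape, (cr, cc), r_lobe, r_lobe, 0.0)
            patch += _render_soft_ellipse(rho)
        patch *= _speckle(patch.shape, speckle_sigma, rng)
        major = sep / 2.0 + r_lobe
        params = (ctr_r, ctr_c, major, r_lobe, orientation)
    else:
        minor_px = np.sqrt(area_px2 * ratio / np.pi)
        major_px = minor_px / ratio
        size = int(np.ceil(2 * major_px + 8)) | 1  # odd: integer paste offset
        ctr_r = (size - 1) / 2.0 + center_frac[0]
        ctr_c = (size - 1) / 2.0 + center_frac[1]
        _, rho = _ellipse_mask((size, size), (ctr_r, ctr_c), major_px, minor_px, orientation)
        patch = _render_soft_ellipse(rho)
        if phase in ("M2", "M3", "M5"):
            # condensed chromatin: brighter, rougher core
            patch *= 1.0 + 0.5 * _render_soft_ellipse(rho / 0.6)
        patch *= _speckle(patch.shape, speckle_sigma, rng)
        params = (ctr_r, ctr_c, major_px, minor_px, orientation)
    s = patch.sum()
    if s <= 0:
        raise RuntimeError("degenerate nucleus render")
    return patch / s, params


def _render_gh2ax(mask_profile, damage, dna, rng):
    """gamma-H2AX patch integrating to 1: diffuse signal plus bright foci."""
    patch = 0.35 * mask_profile.copy()
    n_foci = rng.poisson(3 + 25 * damage)
    if n_foci > 0:
        rows, cols = np.nonzero(mask_profile > 0.5)
        if rows.size:
            idx = rng.integers(0, rows.size, size=n_foci)
            foci = np.zeros_like(patch)
            np.add.at(foci, (rows[idx], cols[idx]), 1.0)
            patch += ndimage.gaussian_filter(foci, 1.3) * 8.0
    patch *= mask_profile > 0.05
    s = patch.sum()
    return patch / s if s > 0 else mask_profile / mask_profile.sum()


@dataclass
class GroundTruth:
    """Per-nucleus ground truth plus the per-pixel label raster.

    ``table`` has one row per placed nucleus: nucleus_id, center_row/col
    (px), major/minor axes (px), orientation (rad), phase, dna_content
    (G1 mean = 1), true_damage_fraction in [0, 1].  ``labels[r, c]`` is
    the nucleus_id owning that pixel (0 = background).
    """

    table: pd.DataFrame
    labels: np.ndarray
    pixel_size: float

    def __len__(self) -> int:
        return len(self.table)


def generate_slide(
    n_nuclei: int,
    phase_mix: dict[str, float] | None = None,
    artifacts: ArtifactSpec | None = None,
    confluence: float = 0.3,
    seed: int = 0,
    shape: tuple[int, int] = (2048, 2048),
    pixel_size: float = 0.5,
    fast_axis: FastAxis = "rows",
    dapi_gain: float = 1.0e5,
    gh2ax_gain: float = 1.0e5,
    spacing: float = 1.05,
    positions: np.ndarray | None = None,
    max_retries: int = 1000,
) -> tuple[SlideImage, SlideImage, GroundTruth]:
    """Generate a two-channel synthetic slide with ground truth.

    Parameters
    ----------
    n_nuclei:
        Number of nuclei to place.
    phase_mix:
        Probabilities over the 7 phase classes (must sum to 1); default is
        a plausible cycling population.
    confluence:
        Target covered-area fraction in (0, 1]; used as a feasibility bound
        for placement.
    spacing:
        Minimum center distance between two nuclei as a multiple of the sum
        of their effective radii; < 1 permits overlaps.
    positions:
        Optional (n, 2) array of center (row, col) pixels, bypassing random
        placement (still bounds-checked).

    Returns ``(dapi, gh2ax, truth)``.  Before artifacts, each nucleus's
    rendered DAPI integrates exactly to ``dna_content * dapi_gain`` and its
    gamma-H2AX to ``true_damage_fraction * dna_content * gh2ax_gain``.
    """
    if phase_mix is None:
        phase_mix = {"G1": 0.45, "S": 0.15, "G2": 0.30, "M2": 0.025,
                     "M3": 0.025, "M4": 0.025, "M5": 0.025}
    probs = np.array([phase_mix.get(p, 0.0) for p in PHASES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError(f"phase_mix must sum to 1, got {probs.sum():.6f}")
    if not (0 < confluence <= 1):
        raise ValueError("confluence must lie in (0, 1]")
    artifacts = artifacts or ArtifactSpec()

    rng = rng_for(seed, "synthetic_slide")
    counts = rng.multinomial(n_nuclei, probs)
    phases = np.repeat(np.array(PHASES), counts)
    rng.shuffle(phases)

    # sample geometry first so placement can respect sizes
    geom = [_sample_phase_geometry(p, rng) for p in phases]
    areas_px2 = np.array([g[0] for g in geom]) / pixel_size**2
    radii = np.sqrt(areas_px2 / np.pi)
    # border margin must clear the longest major axis so no patch is clipped
    ratios = np.array([g[1] for g in geom]) if n_nuclei else np.ones(1)
    max_major = float((radii / np.sqrt(np.maximum(ratios, 0.2))).max()) if n_nuclei else 4.0

    total_area = float(areas_px2.sum())
    slide_area = shape[0] * shape[1]
    if n_nuclei and total_area > confluence * slide_area:
        raise PlacementError(
            f"requested {n_nuclei} nuclei need {total_area / slide_area:.2f} coverage, "
            f"above the confluence bound {confluence:.2f}")

    if positions is None:
        positions = _place(radii, shape, spacing, rng, max_retries, confluence,
                           margin=max_major + 5)
    else:
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (n_nuclei, 2):
            raise ValueError("positions must have shape (n_nuclei, 2)")

    dapi = np.zeros(shape)
    gh2ax = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)   # per-pixel best elliptical radius, for overlaps

    center = artifacts.treatment_center_um
    if center is None:
        center = (shape[0] * pixel_size / 2.0, shape[1] * pixel_size / 2.0)

    rows_out = []
    slow = 0 if fast_axis == "rows" else 1
    for k in range(n_nuclei):
        phase = phases[k]
        area_um2, ratio, orientation, dna, speckle = geom[k]
        r0, c0 = positions[k]
        frac = (r0 - np.round(r0), c0 - np.round(c0))
        patch, (pr, pc, major, minor, theta) = _render_nucleus(
            phase, areas_px2[k], ratio, orientation, rng, speckle, frac)

        dist = np.hypot(r0 * pixel_size - center[0], c0 * pixel_size - center[1])
        dmg = float(radial_damage_field(dist, artifacts))
        if artifacts.damage_penetrance < 1.0 and rng.random() > artifacts.damage_penetrance:
            dmg = 0.0
        dmg = float(np.clip(dmg + rng.normal(0, 0.015) * (dmg > 0), 0.0, 1.0))

        top = int(round(r0 - pr))
        left = int(round(c0 - pc))
        sl, patch_c = _paste_window(shape, patch.shape, top, left)
        p = patch[patch_c]
        dapi[sl] += dna * dapi_gain * p
        gpatch = _render_gh2ax(patch / patch.max(), dmg, dna, rng)[patch_c]
        gh2ax[sl] += dmg * dna * gh2ax_gain * gpatch

        # ground-truth label: geometric ellipse; overlap pixels go to the
        # nucleus whose elliptical radius is smallest (geometrically nearest)
        rr = np.arange(sl[0].start, sl[0].stop)[:, None] - r0
        cc = np.arange(sl[1].start, sl[1].stop)[None, :] - c0
        co, si = np.cos(theta), np.sin(theta)
        u = rr * co + cc * si
        v = -rr * si + cc * co
        rho2 = (u / major) ** 2 + (v / minor) ** 2
        take = (rho2 <= 1.0) & (rho2 < best[sl])
        labels[sl][take] = k + 1
        best[sl][take] = rho2[take]

        rows_out.append(dict(
            nucleus_id=k + 1, center_row=r0, center_col=c0,
            major_px=major, minor_px=minor, orientation=theta,
            phase=phase, dna_content=dna, true_damage_fraction=dmg,
            slow_um=positions[k][slow] * pixel_size,
        ))

    table = pd.DataFrame(rows_out, columns=[
        "nucleus_id", "center_row", "center_col", "major_px", "minor_px",
        "orientation", "phase", "dna_content", "true_damage_fraction", "slow_um"])

    dapi = _apply_artifacts(dapi, artifacts, pixel_size, fast_axis, rng, "dapi")
    gh2ax = _apply_artifacts(gh2ax, artifacts, pixel_size, fast_axis, rng, "gh2ax")

    truth = GroundTruth(table=table, labels=labels, pixel_size=pixel_size)
    mk = lambda px, ch: SlideImage(px, channel=ch, pixel_size=pixel_size, fast_axis=fast_axis)
    return mk(dapi, "dapi"), mk(gh2ax, "gh2ax"), truth


def _paste_window(shape, patch_shape, top, left):
    r0, r1 = max(top, 0), min(top + patch_shape[0], shape[0])
    c0, c1 = max(left, 0), min(left + patch_shape[1], shape[1])
    sl = (slice(r0, r1), slice(c0, c1))
    patch_c = (slice(r0 - top, r1 - top), slice(c0 - left, c1 - left))
    return sl, patch_c


def _place(radii, shape, spacing, rng, max_retries, confluence, margin=None):
    """Rejection-sample centers honouring a pairwise center-distance bound."""
    n = len(radii)
    if n == 0:
        return np.zeros((0, 2))
    cell = max(2.0 * radii.max() * max(spacing, 0.5), 4.0)
    grid: dict[tuple[int, int], list[int]] = {}
    pos = np.zeros((n, 2))
    if margin is None:
        margin = radii.max() + 2
    for k in range(n):
        ok = False
        for _ in range(max_retries):
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            gi, gj = int(r // cell), int(c // cell)
            good = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for j in grid.get((gi + di, gj + dj), ()):
                        dmin = spacing * (radii[k] + radii[j])
                        if (r - pos[j, 0]) ** 2 + (c - pos[j, 1]) ** 2 < dmin * dmin:
                            good = False
                            break
                    if not good:
                        break
                if not good:
                    break
            if good:
                pos[k] = (r, c)
                grid.setdefault((gi, gj), []).append(k)
                ok = True
                break
        if not ok:
            achieved = np.pi * float((radii[:k] ** 2).sum()) / (shape[0] * shape[1])
            raise PlacementError(
                f"placed only {k}/{n} nuclei after {max_retries} retries each; "
                f"achieved confluence {achieved:.3f} (requested bound {confluence:.2f})")
    return pos


def _apply_artifacts(img, spec: ArtifactSpec, pixel_size, fast_axis, rng, channel):
    """Artifacts in acquisition order: gain -> background -> stripes -> blur -> noise."""
    out = img
    if spec.gain_amplitude:
        slow_axis = 0 if fast_axis == "rows" else 1
        x = np.arange(img.shape[slow_axis]) * pixel_size
        g = 1.0 + spec.gain_amplitude * np.sin(x / spec.gain_length_um)
        out = out * (g[:, None] if slow_axis == 0 else g[None, :])
    bg = spec.background_surface(img.shape, channel)
    if bg.any():
        out = out + bg
    if spec.stripe_period:
        slow_axis = 0 if fast_axis == "rows" else 1
        f = np.ones(img.shape[slow_axis])
        f[::spec.stripe_period] = spec.stripe_factor
        out = out * (f[:, None] if slow_axis == 0 else f[None, :])
    for (r0, c0, r1, c1, sg) in spec.blur_regions:
        out = out.copy()
        out[r0:r1, c0:c1] = ndimage.gaussian_filter(out[r0:r1, c0:c1], sg)
    if spec.poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0) / spec.poisson_scale) * spec.poisson_scale
        out = out.astype(float)
    if spec.gaussian_sigma > 0:
        out = np.maximum(out + rng.normal(0, spec.gaussian_sigma, out.shape), 0.0)
    return np.ascontiguousarray(out, dtype=float)
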