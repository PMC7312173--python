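"""Self-contained synthetic benchmark experiments.

Each experiment generates its own ground-truthed data, runs the relevant
slice of the pipeline and measures an outcome against the generator's
truth.  They back both the acceptance test suite and the standalone
acceptance report script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from . import cellcycle, correction, damage as dmg, features as feat, segmentation
from .synthetic import ArtifactSpec, generate_slide


def kde_mode(values, n_grid: int = 1000) -> float:
    """Mode of a 1D sample via Gaussian kernel density."""
    from scipy.stats import gaussian_kde
    v = np.asarray(values, dtype=float)
    kde = gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def truth_phase_per_record(table: pd.DataFrame, truth) -> np.ndarray:
    """Ground-truth phase of the nucleus under each record's centroid."""
    cr = table["centroid_row"].round().astype(int).to_numpy()
    cc = table["centroid_col"].round().astype(int).to_numpy()
    gtl = truth.labels[cr, cc]
    tt = truth.table.set_index("nucleus_id")
    phases = np.array(["?"] * len(table), dtype=object)
    ok = gtl > 0
    phases[ok] = tt.loc[gtl[ok], "phase"].to_numpy()
    return phases


def band_anchoring_experiment(seed: int, n_nuclei: int = 5200,
                              shape: tuple[int, int] = (4096, 4096)) -> dict:
    """Full DAPI correction chain on a drifting, striped synthetic slide.

    The slide carries >= 5000 interphase nuclei, a 0.3-amplitude
    sinusoidal foreground gain drift along the slow axis, an additive
    background surface and a x1.2 stripe every 64th scan line.  Measures
    the post-correction KDE mode of the corrected integrated DAPI
    intensity separately for ground-truth G1 and G2 nuclei (targets 1.0
    and 2.0).
    """
    art = ArtifactSpec(gain_amplitude=0.3, gain_length_um=700.0,
                       background_coeffs=[[60.0, 30.0], [40.0, 0.0]],
                       stripe_period=64, stripe_factor=1.2,
                       gaussian_sigma=2.0)
    dapi, _, truth = generate_slide(
        n_nuclei, phase_mix={"G1": 0.52, "S": 0.10, "G2": 0.38},
        artifacts=art, seed=seed, shape=shape, pixel_size=1.0, spacing=1.1)

    labels = segmentation.segment_nuclei(dapi, adaptive_window=1024)
    labels = segmentation.partition_overlaps(labels, dapi)

    fg = ndimage.binary_dilation(labels > 0, iterations=3)
    surf = correction.estimate_background_surface(dapi, ~fg)
    flat = correction.subtract_background(dapi, surf)
    flat, _ = correction.remove_stripes(flat, ~fg, surf)

    table = feat.extract_features(labels, flat, families=("shape", "intensity"))
    table["i_dapi"] = table["dapi_integrated"]
    table["slow_um"] = table["centroid_row"] * dapi.pixel_size
    table, _ = correction.normalize_dapi_foreground(table)

    phases = truth_phase_per_record(table, truth)
    g1 = table.loc[phases == "G1", "i_dapi_corr"].dropna().to_numpy()
    g2 = table.loc[phases == "G2", "i_dapi_corr"].dropna().to_numpy()
    return {"g1_mode": kde_mode(g1), "g2_mode": kde_mode(g2),
            "n_nuclei": int(len(table)), "n_g1": int(len(g1)),
            "n_g2": int(len(g2))}


_CLASS_MIX = {
    1: {"G1": 0.4, "S": 0.2, "G2": 0.4},     # interphase
    2: {"M2": 1.0},                          # prometaphase
    3: {"M3": 1.0},                          # metaphase
    4: {"M4": 1.0},                          # early anaphase
    5: {"M5": 1.0},                          # late anaphase / telophase
}


def build_class_fixture(seed: int, per_class: int = 500) -> pd.DataFrame:
    """Balanced labelled feature table of the five nuclear morphology
    classes, rendered and measured through the normal feature pipeline."""
    art = ArtifactSpec(background_coeffs=[[80.0]], gaussian_sigma=2.0)
    tables = []
    for cls, mix in _CLASS_MIX.items():
        dapi, gh2ax, _ = generate_slide(
            per_class, phase_mix=mix, seed=seed * 100 + cls,
            shape=(2200, 2200), pixel_size=1.0, spacing=1.4, artifacts=art)
        labels = segmentation.segment_nuclei(dapi, adaptive_window=1024)
        tab = feat.extract_features(labels, dapi, gh2ax)
        tab["label"] = cls
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def classifier_experiment(seed: int, per_class: int = 500) -> dict:
    """Train the 5-class network on the balanced synthetic fixture and
    report held-out test accuracy (paper benchmark: 97%)."""
    table = build_class_fixture(seed, per_class)
    labels = table.pop("label").to_numpy()
    model = cellcycle.train_mitosis_classifier(table, labels, seed=seed)
    return {"accuracy": model.test_accuracy,
            "accuracy_pct": 100.0 * model.test_accuracy,
            "confusion": model.confusion,
            "n": int(len(labels)), "model": model}


def _measure_damage_table(dapi, gh2ax, labels):
    fg = ndimage.binary_dilation(labels > 0, iterations=3)
    flats = {}
    for name, img in (("dapi", dapi), ("gh2ax", gh2ax)):
        surf = correction.estimate_background_surface(img, ~fg)
        flat = correction.subtract_background(img, surf)
        flat, _ = correction.remove_stripes(flat, ~fg, surf)
        flats[name] = flat
    table = feat.extract_features(labels, flats["dapi"], flats["gh2ax"],
                                  families=("shape", "intensity"))
    table["i_dapi"] = table["dapi_integrated"]
    table["i_gh2ax"] = table["gh2ax_integrated"]
    table["slow_um"] = table["centroid_row"] * dapi.pixel_size
    table, _ = correction.normalize_dapi_foreground(table)
    table, _ = correction.flatten_gh2ax_foreground(table, block_um=800.0)
    ratios = (table["i_gh2ax_corr"]
              / table["i_dapi_corr"].clip(lower=1e-9)).to_numpy()
    scale = dmg.calibrate_damage_scale(ratios)
    table["damage"] = dmg.damage_value(table["i_gh2ax_corr"],
                                       table["i_dapi_corr"], scale)
    return table


def ring_experiment(seed: int, n_nuclei: int = 4500,
                    shape: tuple[int, int] = (4096, 4096)) -> dict:
    """End-to-end ring-mode damage mapping.

    Damage field peaks on a 1-mm-radius ring around the treatment center
    (the orifice-radius observation); reports the radius at which the DR
    map's radial profile peaks.
    """
    center = (shape[0] / 2.0, shape[1] / 2.0)
    art = ArtifactSpec(damage_mode="ring", damage_amplitude=0.7,
                       ring_radius_um=1000.0, ring_width_um=350.0,
                       damage_penetrance=0.85,
                       background_coeffs=[[40.0, 20.0], [15.0, 0.0]],
                       gh2ax_background_coeffs=[[30.0, 10.0], [20.0, 0.0]],
                       gaussian_sigma=2.0, treatment_center_um=center)
    dapi, gh2ax, truth = generate_slide(
        n_nuclei, phase_mix={"G1": 0.5, "S": 0.12, "G2": 0.38},
        artifacts=art, seed=seed, shape=shape, pixel_size=1.0, spacing=1.05)
    labels = segmentation.partition_overlaps(
        segmentation.segment_nuclei(dapi, adaptive_window=1024), dapi)
    table = _measure_damage_table(dapi, gh2ax, labels)
    m = dmg.build_damage_map(table, center, diameter_mm=4.0, bin_mm=0.25,
                             statistic="DR")
    radii, prof = m.radial_profile()
    ok = np.isfinite(prof)
    peak_mm = float(radii[ok][np.argmax(prof[ok])])
    return {"peak_mm": peak_mm, "radii_mm": radii, "profile": prof,
            "map": m, "table": table, "truth": truth}


def plain_decay_experiment(seed: int, n_nuclei: int = 2000,
                           shape: tuple[int, int] = (3000, 3000)) -> dict:
    """Plain radially decaying damage; reports the azimuthally averaged
    mean-damage profile (should decrease outward)."""
    center = (shape[0] / 2.0, shape[1] / 2.0)
    art = ArtifactSpec(damage_mode="plain", damage_amplitude=0.8,
                       damage_decay_um=800.0,
                       background_coeffs=[[40.0, 20.0], [15.0, 0.0]],
                       gh2ax_background_coeffs=[[30.0, 10.0], [20.0, 0.0]],
                       gaussian_sigma=2.0, treatment_center_um=center)
    dapi, gh2ax, truth = generate_slide(
        n_nuclei, phase_mix={"G1": 0.5, "S": 0.12, "G2": 0.38},
        artifacts=art, seed=seed, shape=shape, pixel_size=1.0, spacing=1.1)
    labels = segmentation.partition_overlaps(
        segmentation.segment_nuclei(dapi, adaptive_window=1024), dapi)
    table = _measure_damage_table(dapi, gh2ax, labels)
    m = dmg.build_damage_map(table, center, diameter_mm=3.0, bin_mm=0.25,
                             statistic="mean_damage")
    radii, prof = m.radial_profile(n_rings=5)
    return {"radii_mm": radii, "profile": prof, "map": m, "table": table}


def mog_recovery_experiment(seed: int, n: int = 20_000) -> dict:
    """Constrained-mixture parameter recovery on a known generating model."""
    rng = np.random.default_rng(seed)
    g1 = np.array([170.0, 1.0])
    g2 = np.array([310.0, 2.0])
    spacing = np.array([0, 1, 2, 3, 4, 5, 6, 0]) / 6.0
    means = g1 + spacing[:, None] * (g2 - g1)
    bg_w = 0.05
    weights = (1 - bg_w) * np.array(
        [0.30, 0.02, 0.02, 0.03, 0.03, 0.02, 0.27, 0.31])
    cov = np.diag([18.0**2, 0.06**2])
    comp = rng.choice(9, size=n, p=np.concatenate([weights, [bg_w]]))
    X = np.empty((n, 2))
    for j in range(8):
        sel = comp == j
        X[sel] = rng.multivariate_normal(means[j], cov, size=sel.sum())
    sel = comp == 8
    X[sel, 0] = rng.uniform(80, 420, sel.sum())
    X[sel, 1] = rng.uniform(0.5, 2.8, sel.sum())
    df = pd.DataFrame(X, columns=["area_um2", "i_dapi_corr"])
    model = cellcycle.fit_interphase_mog(df, seed=seed)
    return {
        "model": model,
        "true_g1": g1, "true_g2": g2, "true_weights": weights,
        "true_bg_weight": bg_w,
        "g1_dapi_err_pct": 100 * abs(model.g1_center[1] - g1[1]) / g1[1],
        "g2_dapi_err_pct": 100 * abs(model.g2_center[1] - g2[1]) / g2[1],
        "max_weight_err": float(np.abs(model.weights - weights).max()),
    }
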