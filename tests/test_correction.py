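import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from nucmap import correction as corr
from nucmap.correction import (InsufficientBackgroundError,
                               UnimodalIntensityError)
from nucmap.types import SlideImage

from .conftest import kde_mode


# -- background surface -----------------------------------------------------

class TestBackgroundSurface:
    def test_constant_background_recovered(self):
        rng = np.random.default_rng(0)
        img = SlideImage(np.maximum(rng.normal(100, 3, (512, 512)), 0.0),
                         pixel_size=1.0)
        surf = corr.estimate_background_surface(img, np.ones((512, 512), bool))
        assert surf.min() > 98.0 and surf.max() < 102.0

    def test_planar_background_coefficients(self):
        """[DERIVED] least-squares fit of the known plane is the oracle."""
        rng = np.random.default_rng(1)
        rr, cc = np.meshgrid(np.arange(512), np.arange(512), indexing="ij")
        truth = 50.0 + 0.01 * cc
        img = SlideImage(np.maximum(truth + rng.normal(0, 1, truth.shape), 0),
                         pixel_size=1.0)
        surf = corr.estimate_background_surface(img, np.ones_like(truth, bool))
        A = np.stack([np.ones(truth.size), rr.ravel(), cc.ravel()], axis=1)
        coef, *_ = np.linalg.lstsq(A, surf.ravel(), rcond=None)
        assert coef[0] == pytest.approx(50.0, rel=0.05)
        assert coef[2] == pytest.approx(0.01, rel=0.05)
        assert abs(coef[1]) < 0.002

    def test_zero_background(self):
        img = SlideImage(np.zeros((256, 256)), pixel_size=1.0)
        surf = corr.estimate_background_surface(img, np.ones((256, 256), bool))
        assert np.abs(surf).max() < 1e-9

    def test_insufficient_coverage_errors(self):
        img = SlideImage(np.ones((256, 256)), pixel_size=1.0)
        mask = np.zeros((256, 256), bool)
        mask[:10, :10] = True
        with pytest.raises(InsufficientBackgroundError):
            corr.estimate_background_surface(img, mask)

    def test_subtraction_centers_background_at_zero(self):
        rng = np.random.default_rng(2)
        rr = np.arange(512)[:, None] * 0.05
        img = SlideImage(np.maximum(80 + rr + rng.normal(0, 2, (512, 512)), 0),
                         pixel_size=1.0)
        mask = np.ones((512, 512), bool)
        surf = corr.estimate_background_surface(img, mask)
        flat = corr.subtract_background(img, surf)
        # median is pushed slightly above 0 by the >= 0 clip; stay near noise
        assert abs(np.median(flat.pixels) - 0.0) < 2.0


# -- stripes ----------------------------------------------------------------

def _striped_image(factor=1.2, period=64, noise=1.0, bg=100.0, seed=3,
                   shape=(1024, 1024)):
    rng = np.random.default_rng(seed)
    f = np.ones(shape[0])
    f[::period] = factor
    px = bg * f[:, None] + rng.normal(0, noise, shape)
    return SlideImage(np.maximum(px, 0), pixel_size=1.0, fast_axis="rows"), f


class TestRemoveStripes:
    def test_known_multipliers_recovered(self):
        """[DERIVED] the injected multipliers are the oracle."""
        img, f_true = _striped_image()
        mask = np.ones(img.shape, bool)
        surf = corr.estimate_background_surface(img, mask)
        flat = corr.subtract_background(img, surf)
        out, factors = corr.remove_stripes(flat, mask, surf)
        striped = f_true == 1.2
        assert np.abs(factors[striped] - 1.2).max() < 0.012
        assert np.abs(factors[~striped] - 1.0).max() < 0.012
        # residual line-to-line variation back to noise level
        line_med = np.median(out.pixels + surf, axis=1)
        assert line_med[striped].mean() == pytest.approx(
            line_med[~striped].mean(), rel=0.01)

    def test_stripe_free_image_identity(self):
        img, _ = _striped_image(factor=1.0)
        mask = np.ones(img.shape, bool)
        surf = corr.estimate_background_surface(img, mask)
        flat = corr.subtract_background(img, surf)
        out, factors = corr.remove_stripes(flat, mask, surf)
        assert np.abs(factors - 1.0).max() < 0.01
        assert np.abs(out.pixels - flat.pixels).max() < 1.5

    def test_wrong_axis_untouched(self):
        # stripes along columns but fast_axis=rows: the column artifact stays
        rng = np.random.default_rng(4)
        f = np.ones(512)
        f[::64] = 1.3
        px = np.maximum(100 * f[None, :] + rng.normal(0, 1, (512, 512)), 0)
        img = SlideImage(px, pixel_size=1.0, fast_axis="rows")
        mask = np.ones((512, 512), bool)
        surf = corr.estimate_background_surface(img, mask)
        flat = corr.subtract_background(img, surf)
        out, _ = corr.remove_stripes(flat, mask, surf)
        col_med = np.median(out.pixels + surf, axis=0)
        assert col_med[::64].mean() / np.median(col_med) > 1.2

    def test_cols_fast_axis_supported(self):
        rng = np.random.default_rng(5)
        f = np.ones(512)
        f[::64] = 1.25
        px = np.maximum(100 * f[None, :] + rng.normal(0, 1, (512, 512)), 0)
        img = SlideImage(px, pixel_size=1.0, fast_axis="cols")
        mask = np.ones((512, 512), bool)
        surf = corr.estimate_background_surface(img, mask)
        flat = corr.subtract_background(img, surf)
        out, factors = corr.remove_stripes(flat, mask, surf)
        assert np.abs(factors[::64] - 1.25).max() < 0.012


# -- DAPI band anchoring ----------------------------------------------------

def make_band_records(n=6000, drift_amp=0.0, drift_len=700.0, base=540.0,
                      seed=0, extent=4000.0, g1=0.5, s=0.1, g2=0.4):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, extent, n)
    phase = rng.choice(["G1", "S", "G2"], size=n, p=[g1, s, g2])
    dna = np.where(phase == "G1", rng.normal(1.0, 0.035, n),
                   np.where(phase == "G2", rng.normal(2.0, 0.07, n),
                            rng.uniform(1.05, 1.95, n)))
    gain = base * (1.0 + drift_amp * np.sin(x / drift_len))
    y = dna * gain * rng.lognormal(0.0, 0.02, n)
    return pd.DataFrame({"slow_um": x, "i_dapi": y, "phase": phase})


class TestNormalizeDapi:
    def test_sinusoidal_drift_anchored_at_1_and_2(self):
        """[PAPER] bands positioned at DAPI intensity values of 1 and 2."""
        rec = make_band_records(drift_amp=0.3, seed=1)
        out, _ = corr.normalize_dapi_foreground(rec)
        g1 = out.loc[out["phase"] == "G1", "i_dapi_corr"]
        g2 = out.loc[out["phase"] == "G2", "i_dapi_corr"]
        assert kde_mode(g1.to_numpy()) == pytest.approx(1.0, abs=0.03)
        assert kde_mode(g2.to_numpy()) == pytest.approx(2.0, abs=0.06)

    def test_idempotent_within_1e6(self):
        rec = make_band_records(drift_amp=0.3, seed=2)
        out, _ = corr.normalize_dapi_foreground(rec)
        again = out.copy()
        again["i_dapi"] = again["i_dapi_corr"]
        out2, _ = corr.normalize_dapi_foreground(again)
        assert np.abs(out2["i_dapi_corr"].to_numpy()
                      - out["i_dapi_corr"].to_numpy()).max() < 1e-6

    def test_drift_free_global_scale(self):
        """[DERIVED] direct mode computation of the raw bands is the oracle."""
        rec = make_band_records(drift_amp=0.0, base=540.0, seed=3)
        out, _ = corr.normalize_dapi_foreground(rec)
        raw_mode = kde_mode(rec.loc[rec["phase"] == "G1", "i_dapi"].to_numpy())
        assert raw_mode == pytest.approx(540.0, rel=0.02)
        g2 = out.loc[out["phase"] == "G2", "i_dapi_corr"]
        assert kde_mode(g2.to_numpy()) == pytest.approx(2.0, abs=0.06)
        # the applied map is equivalent to a ~1/540 global rescale
        ratio = out["i_dapi_corr"] / (rec["i_dapi"] / raw_mode)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.03)

    def test_unimodal_distribution_errors(self):
        rec = make_band_records(g1=1.0, s=0.0, g2=0.0, seed=4)
        with pytest.raises(UnimodalIntensityError):
            corr.normalize_dapi_foreground(rec)

    def test_too_few_records_errors(self):
        rec = make_band_records(n=120, seed=5)
        with pytest.raises(ValueError, match="500"):
            corr.normalize_dapi_foreground(rec)

    def test_affine_per_position(self):
        # the applied map is affine at each slow-axis position: probe
        # triplets y, 2y, 3y at identical positions stay equispaced
        rec = make_band_records(drift_amp=0.2, seed=6)
        probes = rec.iloc[:30].copy()
        triples = pd.concat([probes.assign(i_dapi=probes["i_dapi"] * k)
                             for k in (1.0, 2.0, 3.0)], ignore_index=True)
        rec2 = pd.concat([rec, triples], ignore_index=True)
        out, _ = corr.normalize_dapi_foreground(rec2)
        c = out["i_dapi_corr"].to_numpy()[len(rec):].reshape(3, 30)
        assert np.abs((c[1] - c[0]) - (c[2] - c[1])).max() < 1e-9


# -- gamma-H2AX flattening --------------------------------------------------

def make_gh2ax_records(n=8000, offset_fn=None, seed=0, extent=3000.0,
                       damage=None):
    rng = np.random.default_rng(seed)
    r = rng.uniform(0, extent, n)
    c = rng.uniform(0, extent, n)
    dapi = np.concatenate([rng.normal(1.0, 0.06, n // 2),
                           rng.normal(2.0, 0.1, n - n // 2)])
    rng.shuffle(dapi)
    offset = offset_fn(r, c) if offset_fn else np.zeros(n)
    g = offset * rng.lognormal(0, 0.05, n)
    dmg = np.zeros(n)
    if damage is not None:
        dmg = damage(rng, r, c)
        g = g + dmg
    return pd.DataFrame({"row_um": r, "col_um": c, "i_dapi_corr": dapi,
                         "i_gh2ax": g, "_true_damage": dmg,
                         "_offset": offset})


class TestFlattenGh2ax:
    def test_zero_damage_median_near_zero(self):
        rec = make_gh2ax_records(
            offset_fn=lambda r, c: 50 + 15 * np.sin(r / 900) + 10 * (c / 3000),
            seed=1)
        out, _ = corr.flatten_gh2ax_foreground(rec, block_um=750.0)
        med = out["i_gh2ax_corr"].median()
        assert med < 0.15 * rec["_offset"].mean()
        # no residual spatial trend: block medians all small
        bi = (out["row_um"] // 750).astype(int)
        bj = (out["col_um"] // 750).astype(int)
        block_med = out.groupby([bi, bj])["i_gh2ax_corr"].median()
        assert block_med.max() < 0.25 * rec["_offset"].mean()

    def test_uniform_offset_recovered(self):
        rec = make_gh2ax_records(offset_fn=lambda r, c: np.full(len(r), 40.0),
                                 seed=2)
        _, surface = corr.flatten_gh2ax_foreground(rec, block_um=750.0)
        assert np.abs(surface["values"] - 40.0).max() < 6.0

    def test_damaged_cells_keep_signal(self):
        """[DERIVED] the zero-damage subset defines the oracle baseline."""
        def damage(rng, r, c):
            d = np.hypot(r - 1500, c - 1500)
            hit = (rng.random(len(r)) < 0.4) & (d < 900)
            return np.where(hit, rng.uniform(80, 160, len(r)), 0.0)

        rec = make_gh2ax_records(
            offset_fn=lambda r, c: 30 + 10 * np.sin(c / 700), seed=3,
            damage=damage)
        out, _ = corr.flatten_gh2ax_foreground(rec, block_um=750.0)
        hit = rec["_true_damage"] > 0
        resid = out.loc[hit, "i_gh2ax_corr"] - rec.loc[hit, "_true_damage"]
        # corrected values track true damage up to the small offset residue
        assert np.abs(resid).median() < 0.2 * rec.loc[hit, "_true_damage"].mean()
        r_corr = np.corrcoef(out.loc[hit, "i_gh2ax_corr"],
                             rec.loc[hit, "_true_damage"])[0, 1]
        assert r_corr > 0.95

    def test_baseline_never_above_local_g1_median(self):
        def damage(rng, r, c):   # half the cells heavily damaged everywhere
            return np.where(rng.random(len(r)) < 0.5,
                            rng.uniform(100, 200, len(r)), 0.0)

        rec = make_gh2ax_records(offset_fn=lambda r, c: np.full(len(r), 20.0),
                                 seed=4, damage=damage)
        out, surface = corr.flatten_gh2ax_foreground(rec, block_um=1500.0)
        g1 = rec["i_dapi_corr"].between(0.7, 1.3)
        global_median = rec.loc[g1, "i_gh2ax"].median()
        assert (surface["values"] <= global_median + 1e-9).all()

    def test_requires_corrected_dapi(self):
        rec = make_gh2ax_records(seed=5).drop(columns=["i_dapi_corr"])
        with pytest.raises(ValueError, match="normalize_dapi_foreground"):
            corr.flatten_gh2ax_foreground(rec)

    def test_all_blocks_deficient_errors(self):
        rec = make_gh2ax_records(n=30, seed=6)
        rec["i_dapi_corr"] = 5.0        # no G1 cells at all
        with pytest.raises(ValueError, match="G1"):
            corr.flatten_gh2ax_foreground(rec, block_um=500.0)

    def test_negative_results_clipped_to_zero(self):
        rec = make_gh2ax_records(offset_fn=lambda r, c: np.full(len(r), 30.0),
                                 seed=7)
        out, _ = corr.flatten_gh2ax_foreground(rec, block_um=1000.0)
        assert (out["i_gh2ax_corr"] >= 0).all()
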