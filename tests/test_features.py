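import numpy as np
import pytest
from scipy import ndimage
from skimage import draw
from skimage.feature import graycomatrix, graycoprops

from nucmap import features as feat
from nucmap.synthetic import generate_slide
from nucmap.types import SlideImage

from . import oracles
from .conftest import scanner_artifacts


def disk_mask(radius, pad=3):
    size = 2 * (radius + pad) + 1
    m = np.zeros((size, size), bool)
    rr, cc = draw.disk((radius + pad, radius + pad), radius, shape=m.shape)
    m[rr, cc] = True
    return m


class TestShapeFeatures:
    def test_disk_area_analytic(self):
        m = disk_mask(20)
        out = feat.shape_features(m, pixel_size=0.5)
        assert out["area_um2"] == pytest.approx(np.pi * 10.0**2, rel=0.02)

    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        out = feat.shape_features(m, pixel_size=0.5)
        assert out["area_um2"] == pytest.approx(0.25)
        assert out["eccentricity"] == 0.0

    def test_ellipse_eccentricity_analytic(self):
        """[DERIVED] analytic ellipse: e = sqrt(1 - (b/a)^2)."""
        m = np.zeros((120, 120), bool)
        rr, cc = draw.ellipse(60, 60, 20, 40)
        m[rr, cc] = True
        out = feat.shape_features(m, pixel_size=1.0)
        assert out["eccentricity"] == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            feat.shape_features(np.zeros((5, 5), bool), 1.0)


def circle_contour(n=400, r=50.0, center=(0.0, 0.0), phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)], 1)


def ellipse_contour(a, b, n=400, theta=0.0, scale=1.0, phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    x = a * np.cos(t) * scale
    y = b * np.sin(t) * scale
    c, s = np.cos(theta), np.sin(theta)
    return np.stack([x * c - y * s, x * s + y * c], 1)


class TestFourierDescriptors:
    def test_circle_higher_harmonics_vanish(self):
        fd = feat.fourier_descriptors(circle_contour(), k=16)
        assert fd.max() < 0.01

    def test_rotation_scale_startpoint_invariance(self):
        base = feat.fourier_descriptors(ellipse_contour(40, 20, n=2000), k=16)
        for theta, scale, phase in ((0.7, 1.0, 0.0), (2.1, 3.5, 1.3),
                                    (0.0, 0.2, 2.9)):
            other = feat.fourier_descriptors(
                ellipse_contour(40, 20, n=2000, theta=theta, scale=scale,
                                phase=phase), k=16)
            assert np.abs(other - base).max() < 1e-6

    def test_translation_invariance(self):
        a = feat.fourier_descriptors(circle_contour(center=(0, 0)), k=8)
        b = feat.fourier_descriptors(circle_contour(center=(123, -77)), k=8)
        assert np.abs(a - b).max() < 1e-9

    def test_matches_direct_dft_oracle(self):
        """[DERIVED] explicit DFT-sum oracle on a 2:1 ellipse."""
        contour = ellipse_contour(40, 20, theta=0.5)
        ours = feat.fourier_descriptors(contour, k=16)
        ref = oracles.direct_dft_descriptors(contour, k=16)
        assert np.abs(ours - ref).max() < 1e-9

    def test_short_contour_errors(self):
        with pytest.raises(ValueError):
            feat.fourier_descriptors(circle_contour(n=10), k=16)


class TestShellIntensities:
    def test_uniform_disk_equal_shells(self):
        m = disk_mask(20)
        out = feat.shell_intensities(m, np.full(m.shape, 7.0), 4)
        assert np.abs(out - 7.0).max() < 0.02 * 7.0

    def test_distance_image_increases_inward(self):
        m = disk_mask(20)
        dist = ndimage.distance_transform_edt(m)
        out = feat.shell_intensities(m, dist, 4)
        assert (np.diff(out) > 0).all()      # shell 0 = boundary, last = core

    def test_bright_rim_matches_brute_force(self):
        """[DERIVED] per-pixel brute-force distance binning oracle."""
        m = disk_mask(15)
        dist = ndimage.distance_transform_edt(m)
        rim = np.where(m & (dist <= 3), 100.0, 10.0) * m
        ours = feat.shell_intensities(m, rim, 4)
        ref = oracles.brute_force_shells(m, rim, 4)
        assert np.abs(ours - ref).max() < 1e-9
        assert ours[0] == ours.max()

    def test_tiny_region_errors(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = True
        with pytest.raises(ValueError):
            feat.shell_intensities(m, np.ones((4, 4)), 4)

    def test_needs_two_shells(self):
        with pytest.raises(ValueError):
            feat.shell_intensities(disk_mask(5), np.ones((17, 17)), 1)


class TestHaralick:
    def test_constant_region_limits(self):
        m = np.ones((10, 10), bool)
        out = feat.haralick_features(m, np.full((10, 10), 5.0), levels=8)
        stats = dict(zip(feat._HARALICK_NAMES, out))
        assert stats["contrast"] == pytest.approx(0.0, abs=1e-12)
        assert stats["asm"] == pytest.approx(1.0, abs=1e-12)
        assert stats["correlation"] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_hand_enumerated(self):
        """[DERIVED] hand-enumerated GLCM of a 2-level checkerboard, 0 deg."""
        board = np.indices((8, 8)).sum(axis=0) % 2
        q = feat.quantize(board.astype(float), np.ones((8, 8), bool), levels=2)
        p = feat.glcm(q, (0, 1), levels=2)
        stats = dict(zip(feat._HARALICK_NAMES, feat.haralick_from_glcm(p)))
        contrast_ref, asm_ref = oracles.checkerboard_glcm_stats()
        assert stats["contrast"] == pytest.approx(contrast_ref, abs=1e-12)
        assert stats["asm"] == pytest.approx(asm_ref, abs=1e-12)

    def test_matches_reference_implementation(self):
        """[DERIVED] scikit-image graycomatrix/graycoprops as the reference,
        after matching quantization."""
        rng = np.random.default_rng(0)
        patch = rng.random((32, 32)) * 100
        mask = np.ones((32, 32), bool)
        levels = 16
        q = feat.quantize(patch, mask, levels)
        for off, angle in (((0, 1), 0.0), ((-1, 0), np.pi / 2)):
            ours = dict(zip(feat._HARALICK_NAMES,
                            feat.haralick_from_glcm(feat.glcm(q, off, levels))))
            ref = graycomatrix(q.astype(np.uint8), [1], [angle], levels=levels,
                               symmetric=True, normed=True)
            assert ours["contrast"] == pytest.approx(
                graycoprops(ref, "contrast")[0, 0], abs=1e-6)
            assert ours["asm"] == pytest.approx(
                graycoprops(ref, "ASM")[0, 0], abs=1e-6)
            assert ours["correlation"] == pytest.approx(
                graycoprops(ref, "correlation")[0, 0], abs=1e-6)

    def test_region_mask_excludes_outside_pairs(self):
        patch = np.zeros((6, 6))
        patch[:, 3:] = 1000.0          # bright half outside the region
        mask = np.zeros((6, 6), bool)
        mask[:, :3] = True
        out = feat.haralick_features(mask, patch, levels=8)
        stats = dict(zip(feat._HARALICK_NAMES, out))
        assert stats["contrast"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            feat.haralick_features(np.ones((8, 8), bool), np.ones((8, 8)),
                                   levels=4)


class TestGranularity:
    def test_disks_mass_at_their_radius(self):
        """[DERIVED] brute-force opening-by-reconstruction oracle."""
        img = np.zeros((64, 64))
        for center in ((15, 15), (15, 45), (45, 30)):
            rr, cc = draw.disk(center, 4, shape=img.shape)
            img[rr, cc] = 10.0
        mask = np.ones((64, 64), bool)
        ours = feat.granularity_spectrum(mask, img, 8)
        ref = oracles.brute_force_granularity(mask, img, 8)
        assert np.abs(ours - ref).max() < 1e-9
        assert ours[:5].sum() > 99.0        # all mass at scales <= radius + 1
        assert ours[5:].max() < 1e-9        # nothing at radius + 2 and beyond

    def test_constant_zero_image(self):
        out = feat.granularity_spectrum(np.ones((16, 16), bool),
                                        np.zeros((16, 16)), 8)
        assert np.array_equal(out, np.zeros(8))

    def test_intensity_scale_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32)) * 50
        mask = np.ones((32, 32), bool)
        a = feat.granularity_spectrum(mask, img, 8)
        b = feat.granularity_spectrum(mask, img * 2.0, 8)
        assert np.abs(a - b).max() < 1e-9

    def test_spectrum_sums_below_100(self):
        rng = np.random.default_rng(2)
        img = rng.random((32, 32))
        out = feat.granularity_spectrum(np.ones((32, 32), bool), img, 16)
        assert out.sum() <= 100.0 + 1e-9

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            feat.granularity_spectrum(np.zeros((8, 8), bool), np.ones((8, 8)), 4)


class TestIntensityFeatures:
    def test_ten_pixels_of_two(self):
        m = np.zeros((5, 5), bool)
        m.ravel()[:10] = True
        out = feat.intensity_features(m, np.full((5, 5), 2.0))
        assert out["integrated"] == pytest.approx(20.0)
        assert out["mean"] == pytest.approx(2.0)
        assert out["std"] == pytest.approx(0.0)

    def test_gh2ax_ratio_tracks_damage(self):
        """[DERIVED] generator ground truth (500 nuclei, radial field)."""
        from scipy.stats import spearmanr
        art = scanner_artifacts(damage_mode="plain", damage_amplitude=0.8,
                                damage_decay_um=700.0)
        dapi, gh2ax, truth = generate_slide(
            500, phase_mix={"G1": 0.5, "G2": 0.5}, artifacts=art, seed=8,
            shape=(2000, 2000), pixel_size=1.0, spacing=1.2)
        ids = truth.table["nucleus_id"].to_numpy()
        gs = ndimage.sum(gh2ax.pixels, truth.labels, ids)
        ds = ndimage.sum(dapi.pixels, truth.labels, ids)
        rho = spearmanr(gs / ds, truth.table["true_damage_fraction"]).statistic
        assert rho > 0.95


@pytest.fixture(scope="module")
def scene():
    art = scanner_artifacts()
    dapi, gh2ax, truth = generate_slide(
        40, seed=17, shape=(800, 800), pixel_size=1.0, spacing=1.25,
        artifacts=art)
    return dapi, gh2ax, truth


class TestExtractFeatures:

    def test_deterministic(self, scene):
        dapi, gh2ax, truth = scene
        a = feat.extract_features(truth.labels, dapi, gh2ax)
        b = feat.extract_features(truth.labels, dapi, gh2ax)
        assert a.equals(b)

    def test_column_order_stable(self, scene):
        dapi, gh2ax, truth = scene
        tab = feat.extract_features(truth.labels, dapi, gh2ax)
        base = ["nucleus_id", "centroid_row", "centroid_col", "row_um",
                "col_um", "qc_pass"]
        assert list(tab.columns) == base + feat.feature_columns()

    def test_intensity_equivariance_shape_invariance(self, scene):
        dapi, gh2ax, truth = scene
        a = feat.extract_features(truth.labels, dapi, gh2ax,
                                  families=("shape", "fourier", "intensity"))
        scaled = dapi.with_pixels(dapi.pixels * 3.0)
        b = feat.extract_features(truth.labels, scaled, gh2ax,
                                  families=("shape", "fourier", "intensity"))
        assert np.allclose(b["dapi_integrated"], 3.0 * a["dapi_integrated"])
        for col in ("area_um2", "eccentricity", "fd_01", "fd_08"):
            assert np.allclose(a[col], b[col], equal_nan=True)

    def test_qc_masked_records_flagged_nan(self, scene):
        from nucmap.types import QCMask, QC_NO_CELLS
        dapi, gh2ax, truth = scene
        reasons = np.zeros((2, 2), dtype=np.int8)
        reasons[0, 0] = QC_NO_CELLS
        qc = QCMask(reasons=reasons, tile=400, image_shape=dapi.shape)
        tab = feat.extract_features(truth.labels, dapi, gh2ax, qc=qc)
        flagged = ~tab["qc_pass"]
        assert flagged.any()
        assert tab.loc[flagged, "area_um2"].isna().all()
        assert tab.loc[~flagged, "area_um2"].notna().all()

    def test_tiled_equals_serial(self, scene):
        # extraction over a crop equals the matching subset of the full run
        dapi, gh2ax, truth = scene
        full = feat.extract_features(truth.labels, dapi, gh2ax,
                                     families=("shape", "intensity"))
        crop = (slice(0, 400), slice(0, 400))
        sub_labels = truth.labels[crop].copy()
        edge_ids = set(np.unique(truth.labels[crop][0, :])) \
            | set(np.unique(truth.labels[:, 0]))
        inner = feat.extract_features(
            sub_labels, dapi.with_pixels(dapi.pixels[crop]),
            gh2ax.with_pixels(gh2ax.pixels[crop]),
            families=("shape", "intensity"))
        full_idx = full.set_index("nucleus_id")
        for _, row in inner.iterrows():
            nid = row["nucleus_id"]
            # only compare nuclei fully inside the crop
            rr = truth.labels == nid
            if rr[:, 400:].any() or rr[400:, :].any():
                continue
            assert row["dapi_integrated"] == pytest.approx(
                full_idx.loc[nid, "dapi_integrated"], rel=1e-12)
            assert row["area_um2"] == pytest.approx(
                full_idx.loc[nid, "area_um2"], rel=1e-12)
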