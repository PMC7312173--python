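import numpy as np
import pytest

from nucmap.synthetic import ArtifactSpec, generate_slide


def scanner_artifacts(**kw) -> ArtifactSpec:
    """Baseline acquisition artifacts every real scan shows: a flat camera
    offset plus read noise.  Tests build on top of this."""
    base = dict(background_coeffs=[[80.0]], gaussian_sigma=2.0)
    base.update(kw)
    return ArtifactSpec(**base)


@pytest.fixture(scope="session")
def g1_slide():
    """200 non-touching G1 nuclei on a realistic background."""
    return generate_slide(200, phase_mix={"G1": 1.0}, seed=7,
                          shape=(1500, 1500), pixel_size=1.0, spacing=1.25,
                          artifacts=scanner_artifacts())


@pytest.fixture(scope="session")
def mixed_slide():
    """Mixed-phase slide with mild confluence, no damage."""
    return generate_slide(800, seed=12, shape=(2000, 2000), pixel_size=1.0,
                          spacing=1.05, artifacts=scanner_artifacts())


@pytest.fixture(scope="session")
def clean_slide():
    """Artifact-free slide (no background, no noise) for identity checks."""
    return generate_slide(600, seed=21, shape=(1800, 1800), pixel_size=1.0,
                          spacing=1.2)


def match_truth_phase(table, truth):
    """Phase of the ground-truth nucleus under each record's centroid."""
    cr = table["centroid_row"].round().astype(int).to_numpy()
    cc = table["centroid_col"].round().astype(int).to_numpy()
    gtl = truth.labels[cr, cc]
    tt = truth.table.set_index("nucleus_id")
    phases = np.array(["?"] * len(table), dtype=object)
    ok = gtl > 0
    phases[ok] = tt.loc[gtl[ok], "phase"].to_numpy()
    return phases, gtl


def jaccard_per_nucleus(pred, truth_labels, ids):
    out = []
    for i in ids:
        g = truth_labels == i
        vals, cnts = np.unique(pred[g], return_counts=True)
        m = vals > 0
        if not m.any():
            out.append(0.0)
            continue
        best = vals[m][np.argmax(cnts[m])]
        p = pred == best
        out.append((g & p).sum() / (g | p).sum())
    return np.asarray(out)


def kde_mode(values: np.ndarray, n_grid: int = 1000) -> float:
    from scipy.stats import gaussian_kde
    v = np.asarray(values, dtype=float)
    kde = gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])
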