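"""Two-stage cell-cycle phase assignment from DAPI-derived features.

Stage 1: a shallow neural network (hidden layers 30 and 10, softmax
output) separates interphase (class 1) from four mitotic morphologies
(classes 2-5: prometaphase, metaphase, early anaphase, late
anaphase/telophase/early G1), trained on a balanced labelled set with a
0.7/0.15/0.15 stratified split and validation-based early stopping.

Stage 2: interphase cells are assigned G1/S/G2 in (area, integrated DAPI)
space by a constrained mixture model — seven Gaussians equally spaced on
the segment joining the G1 and G2 peaks (endpoints included), an eighth
Gaussian on the G1 peak, and a uniform background component.  Components
1 and 8 map to G1, 2-6 to S, 7 to G2.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

CLASS_NAMES = {1: "interphase", 2: "prometaphase", 3: "metaphase",
               4: "early_anaphase", 5: "late_anaphase_telophase"}

#: Gaussian component -> interphase phase mapping (configurable at predict).
DEFAULT_COMPONENT_PHASES = {1: "G1", 2: "S", 3: "S", 4: "S", 5: "S", 6: "S",
                            7: "G2", 8: "G1"}

_SPACING = np.array([0, 1, 2, 3, 4, 5, 6, 0], dtype=float) / 6.0  # comp 8 on G1


class SchemaMismatchError(ValueError):
    pass


# ===========================================================================
# Stage 1: mitosis classifier
# ===========================================================================

@dataclass
class MitosisClassifierModel:
    """Trained shallow network plus its input schema and normalization."""
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    mlp: MLPClassifier
    metadata: dict = field(default_factory=dict)
    confusion: np.ndarray | None = None
    test_accuracy: float | None = None

    def _design(self, records: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in records.columns]
        if missing:
            raise SchemaMismatchError(
                f"records are missing {len(missing)} training feature column(s): "
                f"{missing[:8]}")
        X = records[self.feature_names].to_numpy(dtype=float)
        X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
        return (X - self.scaler_mean) / self.scaler_scale

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "feature_names": self.feature_names,
            "metadata": self.metadata,
            "test_accuracy": self.test_accuracy,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
            "hidden_layer_sizes": list(self.mlp.hidden_layer_sizes),
            "activation": self.mlp.activation,
            "classes": self.mlp.classes_.tolist(),
        }
        path.write_text(json.dumps(meta, indent=2))
        arrays = {"scaler_mean": self.scaler_mean, "scaler_scale": self.scaler_scale}
        for i, (w, b) in enumerate(zip(self.mlp.coefs_, self.mlp.intercepts_)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, path) -> "MitosisClassifierModel":
        path = Path(path)
        meta = json.loads(path.read_text())
        arrays = np.load(path.with_suffix(".npz"))
        mlp = MLPClassifier(hidden_layer_sizes=tuple(meta["hidden_layer_sizes"]),
                            activation=meta["activation"])
        n_layers = sum(1 for k in arrays.files if k.startswith("w"))
        mlp.coefs_ = [arrays[f"w{i}"] for i in range(n_layers)]
        mlp.intercepts_ = [arrays[f"b{i}"] for i in range(n_layers)]
        mlp.n_layers_ = n_layers + 1
        mlp.n_outputs_ = mlp.coefs_[-1].shape[1]
        mlp.classes_ = np.array(meta["classes"])
        mlp.out_activation_ = "softmax"
        mlp._label_binarizer = None
        model = cls(feature_names=meta["feature_names"],
                    scaler_mean=arrays["scaler_mean"],
                    scaler_scale=arrays["scaler_scale"],
                    mlp=mlp, metadata=meta["metadata"],
                    test_accuracy=meta["test_accuracy"])
        if meta["confusion"] is not None:
            model.confusion = np.array(meta["confusion"])
        return model


def _forward_proba(model: MitosisClassifierModel, X: np.ndarray) -> np.ndarray:
    """Explicit forward pass (keeps loaded models usable without refitting)."""
    a = X
    mlp = model.mlp
    for i, (w, b) in enumerate(zip(mlp.coefs_, mlp.intercepts_)):
        a = a @ w + b
        if i < len(mlp.coefs_) - 1:
            a = np.tanh(a) if mlp.activation == "tanh" else np.maximum(a, 0)
    a -= a.max(axis=1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=1, keepdims=True)


def train_mitosis_classifier(records: pd.DataFrame, labels,
                             feature_names: list[str] | None = None,
                             split: tuple[float, float, float] = (0.7, 0.15, 0.15),
                             seed: int = 0,
                             hidden: tuple[int, int] = (30, 10),
                             activation: str = "tanh",
                             patience: int = 6,
                             max_epochs: int = 1000,
                             min_delta: float = 1e-4
                             ) -> MitosisClassifierModel:
    """Train the 5-class shallow network with early stopping.

    ``labels`` are integers 1..5.  The data is stratified into
    train/validation/test at ``split``; training runs epoch-by-epoch and
    stops once the validation log-loss has not improved by at least
    ``min_delta`` for ``patience`` consecutive epochs, restoring the best
    weights.  The returned model
    carries the held-out confusion matrix and overall accuracy.
    """
    y = np.asarray(labels)
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls_, cnt in zip(classes, counts):
        if cnt < 10:
            raise ValueError(
                f"class {cls_} ({CLASS_NAMES.get(int(cls_), '?')}) has only "
                f"{cnt} examples (minimum 10)")
    if feature_names is None:
        num = records.select_dtypes(include=[np.number])
        feature_names = [c for c in num.columns
                         if c not in ("nucleus_id", "centroid_row", "centroid_col",
                                      "row_um", "col_um")]
    X = records[feature_names].to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)

    idx = np.arange(len(y))
    tr, rest = train_test_split(idx, train_size=split[0], stratify=y,
                                random_state=seed)
    val_frac = split[1] / (split[1] + split[2])
    va, te = train_test_split(rest, train_size=val_frac, stratify=y[rest],
                              random_state=seed)

    mean = X[tr].mean(axis=0)
    scale = X[tr].std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    mlp = MLPClassifier(hidden_layer_sizes=hidden, activation=activation,
                        solver="adam", random_state=seed, max_iter=1,
                        warm_start=False)
    best_loss = np.inf
    best_state = None
    best_epoch = 0
    since_best = 0
    for epoch in range(max_epochs):
        mlp.partial_fit(Xs[tr], y[tr], classes=classes)
        val_loss = log_loss(y[va], mlp.predict_proba(Xs[va]), labels=classes)
        if val_loss < best_loss - min_delta:
            best_loss = val_loss
            best_state = (copy.deepcopy(mlp.coefs_), copy.deepcopy(mlp.intercepts_))
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_state is not None:
        mlp.coefs_, mlp.intercepts_ = best_state

    model = MitosisClassifierModel(
        feature_names=list(feature_names), scaler_mean=mean, scaler_scale=scale,
        mlp=mlp,
        metadata={"seed": seed, "epochs_run": epoch + 1, "best_epoch": best_epoch,
                  "best_val_loss": float(best_loss), "patience": patience,
                  "split": list(split),
                  "split_indices": {"train": tr.tolist(), "val": va.tolist(),
                                    "test": te.tolist()}})
    proba = _forward_proba(model, Xs[te])
    pred = classes[np.argmax(proba, axis=1)]
    model.confusion = confusion_matrix(y[te], pred, labels=classes)
    model.test_accuracy = float((pred == y[te]).mean())
    return model


def classify_mitosis(model: MitosisClassifierModel, records: pd.DataFrame
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Predict ``nn_class`` (1..5) and softmax probabilities per record."""
    Xs = model._design(records)
    proba = _forward_proba(model, Xs)
    classes = model.mlp.classes_
    return classes[np.argmax(proba, axis=1)], proba


# ===========================================================================
# Stage 2: constrained interphase mixture
# ===========================================================================

class UnresolvedPeaksError(ValueError):
    pass


@dataclass
class InterphaseMoGModel:
    """Constrained 8-Gaussian + uniform background mixture in
    (area_um2, corrected integrated DAPI) space.

    ``means[j] = g1_center + spacing_j * (g2_center - g1_center)`` with
    spacing 0, 1/6 ... 1 for components 1-7 and 0 for component 8.
    """
    g1_center: np.ndarray
    g2_center: np.ndarray
    covariances: np.ndarray            # (8, 2, 2)
    weights: np.ndarray                # (8,)
    background_weight: float
    support_box: np.ndarray            # [[r_lo, r_hi], [c_lo, c_hi]]
    log_likelihoods: np.ndarray
    component_phases: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENT_PHASES))
    feature_names: tuple = ("area_um2", "i_dapi_corr")

    @property
    def means(self) -> np.ndarray:
        d = self.g2_center - self.g1_center
        return self.g1_center[None, :] + _SPACING[:, None] * d[None, :]

    def save(self, path) -> None:
        d = {
            "g1_center": self.g1_center.tolist(),
            "g2_center": self.g2_center.tolist(),
            "covariances": self.covariances.tolist(),
            "weights": self.weights.tolist(),
            "background_weight": self.background_weight,
            "support_box": self.support_box.tolist(),
            "log_likelihoods": np.asarray(self.log_likelihoods).tolist(),
            "component_phases": {str(k): v for k, v in self.component_phases.items()},
            "feature_names": list(self.feature_names),
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "InterphaseMoGModel":
        d = json.loads(Path(path).read_text())
        return cls(g1_center=np.array(d["g1_center"]),
                   g2_center=np.array(d["g2_center"]),
                   covariances=np.array(d["covariances"]),
                   weights=np.array(d["weights"]),
                   background_weight=d["background_weight"],
                   support_box=np.array(d["support_box"]),
                   log_likelihoods=np.array(d["log_likelihoods"]),
                   component_phases={int(k): v for k, v in d["component_phases"].items()},
                   feature_names=tuple(d["feature_names"]))


def _gauss_logpdf(X, mean, cov):
    d = X - mean
    cov = cov + 1e-12 * np.eye(2)
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, d.T)
    maha = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (maha + logdet + 2 * np.log(2 * np.pi))


def _detect_peaks(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Locate the G1 and G2 peaks of the 2D histogram near DAPI 1 and 2."""
    area, dapi = X[:, 0], X[:, 1]
    found = []
    for lo, hi in ((0.7, 1.3), (1.7, 2.4)):
        sel = (dapi >= lo) & (dapi <= hi)
        if sel.sum() < 50:
            found.append(None)
            continue
        h, ae, de = np.histogram2d(area[sel], dapi[sel], bins=(40, 30))
        i, j = np.unravel_index(np.argmax(h), h.shape)
        found.append(np.array([0.5 * (ae[i] + ae[i + 1]),
                               0.5 * (de[j] + de[j + 1])]))
    if found[0] is None or found[1] is None:
        raise UnresolvedPeaksError(
            "could not locate both the G1 and G2 peaks; DAPI distribution "
            "appears unimodal or uncorrected")
    return found[0], found[1]


def fit_interphase_mog(records: pd.DataFrame,
                       area_col: str = "area_um2",
                       dapi_col: str = "i_dapi_corr",
                       seed: int = 0,
                       max_iter: int = 500,
                       tol: float = 1e-8,
                       background_weight_init: float = 0.02,
                       min_records: int = 2000
                       ) -> InterphaseMoGModel:
    """Fit the constrained mixture by expectation-maximization.

    The M-step maximizes the expected complete-data log-likelihood over
    the two free mean parameters (G1 and G2 centers) by weighted least
    squares under the equal-spacing constraint, then updates the full 2x2
    covariances and weights; the uniform background density is fixed at
    1/area of the data bounding box.  The per-iteration log-likelihood is
    recorded and is non-decreasing.
    """
    if len(records) < min_records:
        raise ValueError(f"need >= {min_records} interphase records, got {len(records)}")
    X = records[[area_col, dapi_col]].to_numpy(dtype=float)
    X = X[np.all(np.isfinite(X), axis=1)]
    if np.any(X.std(axis=0) <= 0):
        raise ValueError("degenerate input: zero variance in a feature")

    box = np.stack([X.min(axis=0), X.max(axis=0)], axis=1)
    pad = 0.01 * (box[:, 1] - box[:, 0])
    box[:, 0] -= pad
    box[:, 1] += pad
    log_u = -np.log(np.prod(box[:, 1] - box[:, 0]))

    g1, g2 = _detect_peaks(X)
    d = g2 - g1
    covs = np.tile(np.diag((0.08 * np.abs(d) + 0.02 * X.std(axis=0)) ** 2),
                   (8, 1, 1))
    weights = np.full(8, (1.0 - background_weight_init) / 8.0)
    bg_w = background_weight_init

    n = len(X)
    lls = []
    for it in range(max_iter):
        means = g1[None, :] + _SPACING[:, None] * (g2 - g1)[None, :]
        logp = np.empty((n, 9))
        for j in range(8):
            logp[:, j] = np.log(weights[j] + 1e-300) + _gauss_logpdf(X, means[j], covs[j])
        logp[:, 8] = np.log(bg_w + 1e-300) + log_u
        mx = logp.max(axis=1, keepdims=True)
        norm = np.exp(logp - mx)
        tot = norm.sum(axis=1, keepdims=True)
        ll = float(np.sum(mx[:, 0] + np.log(tot[:, 0])))
        lls.append(ll)
        resp = norm / tot

        nk = resp.sum(axis=0)
        weights = nk[:8] / n
        bg_w = nk[8] / n

        # constrained mean update: solve for (a, d) in mean_j = a + t_j d
        A = np.zeros((4, 4))
        b = np.zeros(4)
        for j in range(8):
            Sinv = np.linalg.inv(covs[j] + 1e-12 * np.eye(2))
            Nj = nk[j]
            if Nj <= 1e-12:
                continue
            mj = (resp[:, j][:, None] * X).sum(axis=0) / Nj
            t = _SPACING[j]
            blk = Nj * Sinv
            A[:2, :2] += blk
            A[:2, 2:] += t * blk
            A[2:, :2] += t * blk
            A[2:, 2:] += t * t * blk
            b[:2] += blk @ mj
            b[2:] += t * (blk @ mj)
        sol = np.linalg.solve(A + 1e-9 * np.eye(4), b)
        g1, dvec = sol[:2], sol[2:]
        g2 = g1 + dvec

        means = g1[None, :] + _SPACING[:, None] * dvec[None, :]
        for j in range(8):
            if nk[j] <= 1e-12:
                continue
            diff = X - means[j]
            covs[j] = (resp[:, j][:, None, None] *
                       (diff[:, :, None] * diff[:, None, :])).sum(axis=0) / nk[j]
            covs[j] += 1e-9 * np.eye(2)

        if it > 0 and lls[-1] - lls[-2] < tol * max(abs(lls[-1]), 1.0):
            break

    return InterphaseMoGModel(
        g1_center=g1, g2_center=g2, covariances=covs, weights=weights,
        background_weight=float(bg_w), support_box=box,
        log_likelihoods=np.array(lls))


def interphase_posterior(model: InterphaseMoGModel, X: np.ndarray) -> np.ndarray:
    """Posterior over the 8 Gaussians plus background (columns 0-7, 8)."""
    means = model.means
    box = model.support_box
    log_u = -np.log(np.prod(box[:, 1] - box[:, 0]))
    logp = np.empty((len(X), 9))
    for j in range(8):
        logp[:, j] = (np.log(model.weights[j] + 1e-300) +
                      _gauss_logpdf(X, means[j], model.covariances[j]))
    logp[:, 8] = np.log(model.background_weight + 1e-300) + log_u
    mx = logp.max(axis=1, keepdims=True)
    p = np.exp(logp - mx)
    return p / p.sum(axis=1, keepdims=True)


def classify_interphase(model: InterphaseMoGModel, records: pd.DataFrame,
                        area_col: str = "area_um2",
                        dapi_col: str = "i_dapi_corr"
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Assign G1/S/G2 per record; background-dominated records get
    ``"unclassified"``.  Returns (phases, posterior)."""
    X = records[[area_col, dapi_col]].to_numpy(dtype=float)
    post = interphase_posterior(model, X)
    comp = np.argmax(post, axis=1)
    phases = np.array([
        "unclassified" if k == 8 else model.component_phases[k + 1]
        for k in comp], dtype=object)
    bad = ~np.all(np.isfinite(X), axis=1)
    phases[bad] = "unclassified"
    return phases, post
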