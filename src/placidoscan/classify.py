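"""Keratoconus classification: Gaussian-kernel SVM trained from its dual.

Eyes are encoded as y = +1 (healthy) / y = −1 (diseased) and separated by the
kernel decision function f(x) = Σ_i α_i y_i K(x_i, x) + b, where the
multipliers solve the dual quadratic program

    min_α  ½ Σ_ij α_i α_j y_i y_j K(x_i, x_j) − Σ_i α_i
    s.t.   0 ≤ α_i ≤ C,   Σ_i α_i y_i = 0.

The solver is a maximal-violating-pair SMO: at each step the KKT-violating
pair is updated analytically along the feasible direction, so the equality
constraint holds exactly throughout.  The Gaussian kernel is
K(x_i, x_j) = exp(−‖x_i − x_j‖² / σ²).

Although the positive *training* label is healthy, the positive class of the
screening metrics (sensitivity, specificity, NPV, PPV) is diseased: a true
positive is a diseased eye flagged as diseased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HEALTHY_Y, DISEASED_Y = 1, -1
LABEL_TO_Y = {"healthy": HEALTHY_Y, "diseased": DISEASED_Y}


# ---------------------------------------------------------------------------
# parameters and containers


@dataclass(frozen=True)
class SvmParams:
    C: float = 1.0
    sigma: float | None = None  # None -> median pairwise-distance heuristic
    kernel: str = "gaussian"

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel not in ("gaussian", "linear"):
            raise ValueError("kernel must be 'gaussian' or 'linear'")


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.6
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class SvmModel:
    """Trained kernel machine: support vectors, multipliers, bias, scaler."""

    support_vectors: np.ndarray  # standardized, (n_sv, d)
    alpha: np.ndarray  # (n_sv,), 0 < alpha <= C
    y: np.ndarray  # (n_sv,) in {+1, -1}
    b: float
    params: SvmParams
    sigma: float  # resolved kernel width
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    n_train: int

    def to_json(self, path) -> None:
        payload = {
            "support_vectors": self.support_vectors.tolist(),
            "alpha": self.alpha.tolist(),
            "y": self.y.tolist(),
            "b": self.b,
            "C": self.params.C,
            "kernel": self.params.kernel,
            "sigma": self.sigma,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "n_train": self.n_train,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "SvmModel":
        d = json.loads(Path(path).read_text())
        params = SvmParams(C=d["C"], sigma=d["sigma"], kernel=d["kernel"])
        return cls(
            support_vectors=np.asarray(d["support_vectors"], float),
            alpha=np.asarray(d["alpha"], float),
            y=np.asarray(d["y"], float),
            b=float(d["b"]),
            params=params,
            sigma=float(d["sigma"]),
            feature_mean=np.asarray(d["feature_mean"], float),
            feature_sd=np.asarray(d["feature_sd"], float),
            n_train=int(d["n_train"]),
        )


@dataclass
class EvalReport:
    """Confusion-matrix counts and screening metrics (diseased = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    npv: float = field(init=False)
    ppv: float = field(init=False)

    def __post_init__(self):
        def pct(num, den):
            return 100.0 * num / den if den else float("nan")

        self.sensitivity = pct(self.tp, self.tp + self.fn)
        self.specificity = pct(self.tn, self.tn + self.fp)
        self.accuracy = pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)
        self.npv = pct(self.tn, self.tn + self.fn)
        self.ppv = pct(self.tp, self.tp + self.fp)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "NPV_pct": self.npv,
            "PPV_pct": self.ppv,
        }

    def __str__(self) -> str:
        d = self.to_dict()
        lines = [f"TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn}"]
        lines += [
            f"sensitivity: {self.sensitivity:.2f}%",
            f"specificity: {self.specificity:.2f}%",
            f"accuracy:    {self.accuracy:.2f}%",
            f"NPV:         {self.npv:.2f}%",
            f"PPV:         {self.ppv:.2f}%",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# features


def build_features(
    radius_map_px: np.ndarray,
    diopter_map_: np.ndarray,
    eye_id: str,
    label: str,
    r_mm_map: np.ndarray | None = None,
    distance_mm_map: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Long-form per-(ring, sector) records plus the eye-level summary vector.

    The eye vector concatenates the per-ring mean diopter and the per-ring
    inter-sector diopter SD (length 2K); a cone raises both in the rings it
    crosses, while a healthy dome keeps means near 43 D and SDs near zero.
    """
    d = np.asarray(diopter_map_, dtype=float)
    if not np.any(np.isfinite(d)):
        raise ValueError("diopter map has no present entries")
    if np.asarray(radius_map_px).shape != d.shape:
        raise ValueError("radius and diopter maps must share shape")
    k, s = d.shape
    from .geometry import sector_centers

    centers = sector_centers(s)
    rings, sectors = np.meshgrid(np.arange(1, k + 1), centers, indexing="ij")
    records = pd.DataFrame(
        {
            "eye_id": eye_id,
            "ring": rings.ravel(),
            "sector_deg": sectors.ravel(),
            "radius_px": np.asarray(radius_map_px, float).ravel(),
            "distance_mm": (np.asarray(distance_mm_map, float).ravel() if distance_mm_map is not None else np.nan),
            "r_c_mm": (np.asarray(r_mm_map, float).ravel() if r_mm_map is not None else np.nan),
            "diopter": d.ravel(),
            "label": label,
        }
    )
    with np.errstate(invalid="ignore"):
        means = np.nanmean(d, axis=1)
        sds = np.nanstd(d, axis=1)
    vector = np.concatenate([means, sds])
    return records, vector


# ---------------------------------------------------------------------------
# kernels


def gaussian_kernel(x: np.ndarray, x_i: np.ndarray, sigma: float) -> float:
    """K(x, x_i) = exp(−‖x − x_i‖² / σ²)."""
    x = np.asarray(x, float)
    x_i = np.asarray(x_i, float)
    if x.shape != x_i.shape:
        raise ValueError("vectors must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-np.sum((x - x_i) ** 2) / sigma**2))


def _gram(X: np.ndarray, Z: np.ndarray, params_kernel: str, sigma: float) -> np.ndarray:
    if params_kernel == "linear":
        return X @ Z.T
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * (X @ Z.T)
    )
    return np.exp(-np.maximum(sq, 0.0) / sigma**2)


def median_heuristic(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance; fallback to 1 if degenerate."""
    X = np.asarray(X, float)
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * (X @ X.T)
    )
    d = np.sqrt(np.maximum(sq[np.triu_indices(len(X), k=1)], 0.0))
    med = float(np.median(d)) if d.size else 0.0
    return med if med > 0 else 1.0


# ---------------------------------------------------------------------------
# dual solver


def _smo(K: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-6, max_iter: int = 100_000):
    """Maximal-violating-pair SMO on the dual QP; returns (alpha, b)."""
    n = len(y)
    alpha = np.zeros(n)
    # gradient of the dual objective: G = Q alpha - 1, Q_ij = y_i y_j K_ij
    Q = K * np.outer(y, y)
    G = -np.ones(n)
    eps = 1e-12
    for _ in range(max_iter):
        yG = -y * G
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y > 0) & (alpha > eps)) | ((y < 0) & (alpha < C - eps))
        if not up.any() or not low.any():
            break
        i = int(np.flatnonzero(up)[np.argmax(yG[up])])
        j = int(np.flatnonzero(low)[np.argmin(yG[low])])
        m, M = yG[i], yG[j]
        if m - M < tol:
            break
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        t = (m - M) / max(quad, eps)
        # clip step so both multipliers stay in the box
        t = min(t, C - alpha[i] if y[i] > 0 else alpha[i])
        t = min(t, alpha[j] if y[j] > 0 else C - alpha[j])
        if t <= 0:
            break
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        # ΔG = Q[:, i] Δα_i + Q[:, j] Δα_j
        G += Q[:, i] * (y[i] * t) + Q[:, j] * (-y[j] * t)
    alpha = np.clip(alpha, 0.0, C)
    f_no_b = (alpha * y) @ K
    free = (alpha > 1e-8) & (alpha < C - 1e-8)
    if free.any():
        b = float(np.mean(y[free] - f_no_b[free]))
    else:
        sv = alpha > 1e-8
        b = float(np.mean(y[sv] - f_no_b[sv])) if sv.any() else 0.0
    return alpha, b


def train_svm(X: np.ndarray, y: np.ndarray, params: SvmParams | None = None) -> SvmModel:
    """Fit the dual SVM; features are standardized with training statistics."""
    params = params or SvmParams()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("training set must contain both classes (+1 and -1)")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Xs = (X - mean) / sd
    sigma = params.sigma if params.sigma is not None else median_heuristic(Xs)
    K = _gram(Xs, Xs, params.kernel, sigma)
    alpha, b = _smo(K, y, params.C)
    sv = alpha > 1e-8
    return SvmModel(
        support_vectors=Xs[sv],
        alpha=alpha[sv],
        y=y[sv],
        b=b,
        params=params,
        sigma=sigma,
        feature_mean=mean,
        feature_sd=sd,
        n_train=len(y),
    )


def decision_function(model: SvmModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("feature dimension mismatch")
    Xs = (X - model.feature_mean) / model.feature_sd
    K = _gram(Xs, model.support_vectors, model.params.kernel, model.sigma)
    return K @ (model.alpha * model.y) + model.b


def predict(model: SvmModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (+1 healthy / −1 diseased; ties → healthy) and decision values."""
    f = decision_function(model, X)
    labels = np.where(f >= 0, HEALTHY_Y, DISEASED_Y)
    return labels, f


# ---------------------------------------------------------------------------
# splitting, cross-validation, metrics


def split_data(eye_ids, labels, spec: SplitSpec | None = None):
    """Stratified eye-level train/test split plus fold assignment.

    Returns ``(train_ids, test_ids, folds)`` where ``folds`` is a list of
    ``n_folds`` disjoint arrays partitioning the training portion, stratified
    by label.  Deterministic given ``spec.seed``.
    """
    spec = spec or SplitSpec()
    eye_ids = np.asarray(eye_ids)
    labels = np.asarray(labels)
    if len(eye_ids) != len(np.unique(eye_ids)):
        raise ValueError("eye_ids must be unique at the eye level")
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts = [], []
    per_class_train = {}
    for cls in np.unique(labels):
        ids = eye_ids[labels == cls]
        ids = ids[rng.permutation(len(ids))]
        n_train = int(round(spec.train_frac * len(ids)))
        per_class_train[cls] = ids[:n_train]
        train_parts.append(ids[:n_train])
        test_parts.append(ids[n_train:])
    for cls, ids in per_class_train.items():
        if len(ids) < spec.n_folds:
            raise ValueError(
                f"too few eyes: class {cls!r} has {len(ids)} training eyes for {spec.n_folds} folds"
            )
    folds = [[] for _ in range(spec.n_folds)]
    for ids in per_class_train.values():
        for pos, eid in enumerate(ids):
            folds[pos % spec.n_folds].append(eid)
    return (
        np.concatenate(train_parts),
        np.concatenate(test_parts),
        [np.asarray(f) for f in folds],
    )


@dataclass
class CvResult:
    best_params: SvmParams
    mean_scores: dict  # (C, sigma) -> mean validation accuracy (%)
    fold_scores: list  # per-fold accuracy of the selected params


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    eye_ids,
    folds,
    C_grid=(0.1, 1.0, 10.0),
    sigma_factors=(0.5, 1.0, 2.0),
    kernel: str = "gaussian",
) -> CvResult:
    """Grid search by k-fold CV on the training portion.

    Each fold is held out once; standardization and the model are fit on the
    remaining folds only.  σ candidates are multiples of the median-distance
    heuristic.  Ties are broken toward smaller C, then larger σ.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    eye_ids = np.asarray(eye_ids)
    id_to_idx = {e: i for i, e in enumerate(eye_ids)}
    fold_idx = [np.asarray([id_to_idx[e] for e in f], dtype=int) for f in folds]

    base_sigma = median_heuristic((X - X.mean(axis=0)) / np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0))
    if kernel == "linear":
        sigma_grid = [None]
    else:
        sigma_grid = [f * base_sigma for f in sigma_factors]

    results = {}
    fold_detail = {}
    for C in C_grid:
        for sigma in sigma_grid:
            scores = []
            for held in fold_idx:
                mask = np.ones(len(y), dtype=bool)
                mask[held] = False
                model = train_svm(X[mask], y[mask], SvmParams(C=C, sigma=sigma, kernel=kernel))
                pred, _ = predict(model, X[held])
                scores.append(100.0 * np.mean(pred == y[held]))
            key = (C, sigma)
            results[key] = float(np.mean(scores))
            fold_detail[key] = scores

    def sort_key(key):
        C, sigma = key
        return (-results[key], C, -(sigma if sigma is not None else 0.0))

    best = min(results, key=sort_key)
    return CvResult(
        best_params=SvmParams(C=best[0], sigma=best[1], kernel=kernel),
        mean_scores=results,
        fold_scores=fold_detail[best],
    )


def evaluate_metrics(predictions, truth) -> EvalReport:
    """Confusion counts and metrics with diseased (−1) as the positive class."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0:
        raise ValueError("empty input")
    if predictions.shape != truth.shape:
        raise ValueError("prediction and truth vectors must have equal length")
    pos = DISEASED_Y
    tp = int(np.sum((predictions == pos) & (truth == pos)))
    tn = int(np.sum((predictions != pos) & (truth != pos)))
    fp = int(np.sum((predictions == pos) & (truth != pos)))
    fn = int(np.sum((predictions != pos) & (truth == pos)))
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn)
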