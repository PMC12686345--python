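"""PLS-DA by NIPALS, with VIP scores and discriminant-band selection.

Partial least squares discriminant analysis regresses a mean-centered
spectral matrix ``X`` (n x p) on one-hot class indicators ``Y`` (n x K) and
classifies by the argmax of the continuous predicted response.  Components
are extracted by the NIPALS PLS2 algorithm with sequential deflation.

Variable importance in projection (VIP) follows Wold's formulation,

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),

where ``SSY_a = ||t_a||^2 * sum_k q_ka^2`` is the Y sum of squares explained
by component ``a``.  The squares of the VIP scores average to 1, so VIP > 1
marks bands contributing more than an average band; the discriminant-band
set is the strict-threshold selection at 1.0 by default.

Design choices: bands are mean-centered but not autoscaled (spectra share a
physical intensity scale after internal-standard normalization; autoscaling
would inflate noise bands — an ``autoscale`` flag exists), NIPALS starts from
the first response column so fits are deterministic, and each weight
column's sign is fixed so its largest-magnitude entry is positive.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .spectral import SpectralDataset

__all__ = [
    "PLSDAModel",
    "VIPResult",
    "encode_onehot",
    "fit_plsda",
    "fit_plsda_dataset",
    "predict_response",
    "classify",
    "compute_vip",
    "select_bands",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclasses.dataclass
class PLSDAModel:
    """Fitted PLS-DA regression (weights, loadings, scores, coefficients)."""

    class_order: tuple[str, ...]
    n_components: int
    x_mean: np.ndarray  # (p,)
    y_mean: np.ndarray  # (K,)
    x_weights: np.ndarray  # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # Q, (K, A)
    x_scores: np.ndarray  # T, (n, A)
    coef: np.ndarray  # B, (p, K)
    explained_y_variance: np.ndarray  # SSY_a, (A,)
    x_scale: Optional[np.ndarray] = None  # per-band SD when autoscaled

    @property
    def n_features(self) -> int:
        return int(self.x_mean.size)

    def save(self, path) -> None:
        """Serialize to a single JSON archive."""
        payload = {
            "class_order": list(self.class_order),
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "coef": self.coef.tolist(),
            "explained_y_variance": self.explained_y_variance.tolist(),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path) -> "PLSDAModel":
        payload = json.loads(Path(path).read_text())
        return PLSDAModel(
            class_order=tuple(payload["class_order"]),
            n_components=int(payload["n_components"]),
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            y_mean=np.asarray(payload["y_mean"], dtype=float),
            x_weights=np.asarray(payload["x_weights"], dtype=float),
            x_loadings=np.asarray(payload["x_loadings"], dtype=float),
            y_loadings=np.asarray(payload["y_loadings"], dtype=float),
            x_scores=np.asarray(payload["x_scores"], dtype=float),
            coef=np.asarray(payload["coef"], dtype=float),
            explained_y_variance=np.asarray(
                payload["explained_y_variance"], dtype=float
            ),
            x_scale=(
                None
                if payload["x_scale"] is None
                else np.asarray(payload["x_scale"], dtype=float)
            ),
        )


@dataclasses.dataclass
class VIPResult:
    """Per-band VIP scores and the thresholded discriminant-band set."""

    wavenumbers: np.ndarray
    vip: np.ndarray
    threshold: float = 1.0

    @property
    def selected_bands(self) -> np.ndarray:
        """Wavenumbers with VIP strictly above threshold, descending by VIP."""
        return select_bands(self, self.threshold)


def encode_onehot(labels: Sequence[str], class_order: Sequence[str]) -> np.ndarray:
    """n x K indicator matrix; exactly one 1 per row."""
    index = {c: k for k, c in enumerate(class_order)}
    unknown = [lab for lab in labels if lab not in index]
    if unknown:
        raise ValueError(f"labels outside class_order: {sorted(set(map(str, unknown)))}")
    Y = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y


def fit_plsda(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int = 2,
    class_order: Optional[Sequence[str]] = None,
    autoscale: bool = False,
) -> PLSDAModel:
    """Fit NIPALS PLS2 of one-hot ``Y`` on ``X`` with ``n_components`` factors."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X (n x p) and Y (n x K) must share their first dimension")
    n, p = X.shape
    K = Y.shape[1]
    if n < 2:
        raise ValueError("need at least two observations")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must be finite")
    if class_order is None:
        class_order = tuple(f"class_{k}" for k in range(K))

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    x_scale = None
    if autoscale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0.0] = 1.0
        Xc = Xc / x_scale
    Yc = Y - y_mean
    if not np.any(Xc):
        raise ValueError("X has zero variance; cannot fit")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((K, n_components))
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)

    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(n_components):
        # deterministic start: the first response column (largest-SS residual
        # column if that one has been fully deflated)
        u = Yd[:, 0].copy()
        if not np.any(u):
            u = Yd[:, int(np.argmax((Yd**2).sum(axis=0)))].copy()
        if not np.any(u):
            u = Xd[:, int(np.argmax((Xd**2).sum(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(_NIPALS_MAX_ITER):
            w = Xd.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0.0:
                raise ValueError("degenerate component: zero X weight vector")
            w /= norm_w
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            norm_q = np.linalg.norm(q)
            if norm_q == 0.0:
                break  # Y residual orthogonal to t; component is X-only
            u = Yd @ q / (q @ q)
            if np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        # sign convention: largest-|w| entry positive
        flip = np.sign(w[int(np.argmax(np.abs(w)))]) or 1.0
        w, t, q = w * flip, t * flip, q * flip
        p_load = Xd.T @ t / (t @ t)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q, t
        ssy[a] = (t @ t) * float(q @ q)
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q)

    # B = W (P'W)^-1 Q'  maps centered X directly to centered Y-hat
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    if x_scale is not None:
        coef = coef / x_scale[:, None]
    return PLSDAModel(
        class_order=tuple(class_order),
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        coef=coef,
        explained_y_variance=ssy,
        x_scale=x_scale,
    )


def fit_plsda_dataset(
    dataset: SpectralDataset, n_components: int = 2, autoscale: bool = False
) -> PLSDAModel:
    """Fit PLS-DA to a labelled spectral dataset (one-hot response coding)."""
    Y = encode_onehot(list(dataset.labels), dataset.class_order)
    return fit_plsda(
        dataset.matrix,
        Y,
        n_components=n_components,
        class_order=dataset.class_order,
        autoscale=autoscale,
    )


def predict_response(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Continuous m x K predicted responses ``(X - x_mean) B + y_mean``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} bands; model expects {model.n_features}"
        )
    return (X - model.x_mean) @ model.coef + model.y_mean


def classify(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax decision on the predicted response; ties go to the earliest class."""
    scores = predict_response(model, X)
    idx = np.argmax(scores, axis=1)  # np.argmax returns the first maximum
    return np.asarray([model.class_order[k] for k in idx], dtype=object)


def compute_vip(model: PLSDAModel, wavenumbers: Optional[np.ndarray] = None,
                threshold: float = 1.0) -> VIPResult:
    """Wold VIP scores of a fitted model (sum of squared scores equals p)."""
    ssy = model.explained_y_variance
    if np.all(ssy == 0.0):
        raise ValueError("model explains no Y variance; VIP undefined")
    W = model.x_weights
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0.0] = 1.0
    vip = np.sqrt(p * ((W**2 / wnorm2) @ ssy) / ssy.sum())
    if wavenumbers is None:
        wavenumbers = np.arange(p, dtype=float)
    return VIPResult(wavenumbers=np.asarray(wavenumbers, dtype=float), vip=vip,
                     threshold=threshold)


def select_bands(vip: VIPResult, threshold: Optional[float] = None) -> np.ndarray:
    """Wavenumbers with VIP strictly greater than threshold, descending by VIP."""
    thr = vip.threshold if threshold is None else threshold
    if thr < 0:
        raise ValueError("threshold must be >= 0")
    mask = vip.vip > thr
    order = np.argsort(-vip.vip[mask], kind="stable")
    return vip.wavenumbers[mask][order]
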