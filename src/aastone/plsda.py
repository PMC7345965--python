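"""Partial Least Squares Discriminant Analysis (PLS1 / NIPALS), from scratch.

The classifier is PLS regression of a 0/1-coded class response on the
(scaled) concentration matrix, followed by a threshold rule: predict stone
former when the continuous response exceeds 0.5.  A single response column
(PLS1) is used rather than two-column dummy coding; for binary problems the
two are equivalent and PLS1 admits a direct, auditable NIPALS recursion:

    for each latent variable a = 1..A on the deflated (X, y):
        w_a  proportional to  X' y          (normalised to unit length)
        t_a  =  X w_a
        p_a  =  X' t_a / (t_a' t_a)
        q_a  =  y' t_a / (t_a' t_a)
        X   <-  X - t_a p_a';   y <- y - q_a t_a

Regression coefficients are accumulated via r_a = w_a - sum_b (p_b' w_a) r_b
so that predictions for every truncated model 1..A come from one fit; the
full-model coefficients satisfy B = W (P' W)^{-1} q.  There is no random
initialisation anywhere: identical inputs give bit-identical models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocessing import ScalingParams, apply_scaler, fit_scaler

__all__ = [
    "PLSModel",
    "fit_plsda",
    "predict_scores",
    "transform",
    "classify",
    "compute_vip",
]

_EPS = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 discriminant model.

    Attributes
    ----------
    n_lv
        Number of latent variables actually extracted (may be fewer than
        requested if the training matrix runs out of rank).
    W, P, T
        Weights (p x A, unit-norm columns), X-loadings (p x A) and training
        scores (n x A); score columns are mutually orthogonal.
    q
        y-loadings (length A).
    B, coef_path
        Regression coefficients of the full model and of every truncated
        model (p x A; column a-1 = coefficients using a latent variables).
    x_scaling, y_mean
        Training preprocessing; predictions are y_mean + scale(X) @ B.
    threshold
        Decision cutoff on the continuous response (default 0.5).
    """

    n_lv: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    B: np.ndarray
    coef_path: np.ndarray
    x_scaling: ScalingParams
    y_mean: float
    threshold: float = 0.5

    def to_json(self, path: str | Path) -> None:
        """Serialize all matrices (flattened, shapes recorded) for audits."""
        payload = {
            "n_lv": self.n_lv,
            "y_mean": self.y_mean,
            "threshold": self.threshold,
            "scaling_method": self.x_scaling.method,
            "scaling_means": self.x_scaling.means.tolist(),
            "scaling_sds": self.x_scaling.sds.tolist(),
        }
        for name in ("W", "P", "q", "T", "B", "coef_path"):
            arr = getattr(self, name)
            payload[name] = {"shape": list(arr.shape), "data": arr.ravel().tolist()}
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    scaling: str = "auto",
    threshold: float = 0.5,
) -> PLSModel:
    """Fit a PLS1 discriminant model on raw concentrations.

    Scaling is fitted here, on exactly the rows passed in, which makes this
    function the single entry point cross-validation loops call on each
    training partition.  ``y`` must be 0/1 with both classes present;
    ``n_lv`` is capped at min(n_samples - 1, n_analytes) and truncated
    further (with a warning) if the deflated matrix runs out of rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) < 2:
        raise ValueError("y must contain both classes coded 0/1")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    max_feasible = min(n - 1, p)
    if n_lv > max_feasible:
        warnings.warn(
            f"n_lv={n_lv} exceeds min(n-1, p)={max_feasible}; truncating",
            stacklevel=2,
        )
        n_lv = max_feasible

    scaler = fit_scaler(X, method=scaling)
    Xd = apply_scaler(X, scaler)
    y_mean = float(y.mean())
    yd = y - y_mean
    x_norm0 = float(np.linalg.norm(Xd))

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    R = np.zeros((p, n_lv))
    coef_path = np.zeros((p, n_lv))

    a = 0
    B = np.zeros(p)
    while a < n_lv:
        w = Xd.T @ yd
        w_norm = np.linalg.norm(w)
        if w_norm <= _EPS * max(x_norm0, 1.0):
            warnings.warn(
                f"rank exhausted after {a} latent variables (requested {n_lv})",
                stacklevel=2,
            )
            break
        w /= w_norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS * max(x_norm0, 1.0) ** 2:
            warnings.warn(
                f"rank exhausted after {a} latent variables (requested {n_lv})",
                stacklevel=2,
            )
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t

        r = w - R[:, :a] @ (P[:, :a].T @ w)
        W[:, a], P[:, a], T[:, a], q[a], R[:, a] = w, pvec, t, qa, r
        B = B + qa * r
        coef_path[:, a] = B
        a += 1

    if a == 0:
        raise ValueError("degenerate training matrix: no latent variable extractable")

    return PLSModel(
        n_lv=a,
        W=W[:, :a],
        P=P[:, :a],
        q=q[:a],
        T=T[:, :a],
        B=coef_path[:, a - 1].copy(),
        coef_path=coef_path[:, :a],
        x_scaling=scaler,
        y_mean=y_mean,
        threshold=threshold,
    )


def predict_scores(
    model: PLSModel, X_new: np.ndarray, n_lv: int | None = None
) -> np.ndarray:
    """Continuous class response for new samples (unbounded reals).

    Applies the stored training scaler, then the linear predictor of the
    ``n_lv``-component truncation (full model by default).
    """
    Xs = apply_scaler(X_new, model.x_scaling)
    if n_lv is None:
        beta = model.B
    else:
        if not 1 <= n_lv <= model.n_lv:
            raise ValueError(f"n_lv must be in 1..{model.n_lv}")
        beta = model.coef_path[:, n_lv - 1]
    return model.y_mean + Xs @ beta


def transform(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project new samples onto the latent-variable score space (n x A)."""
    Xs = apply_scaler(X_new, model.x_scaling)
    R = _rotation(model)
    return Xs @ R


def _rotation(model: PLSModel) -> np.ndarray:
    """W (P'W)^{-1}: maps scaled X to scores in one shot."""
    return model.W @ np.linalg.inv(model.P.T @ model.W)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: stone former (1) iff score strictly above threshold.

    A score exactly at the threshold goes to the control class.
    """
    return (np.asarray(scores) > threshold).astype(int)


def compute_vip(model: PLSModel) -> np.ndarray:
    """Variable Importance in Projection, one value per analyte.

    VIP_j = sqrt( p * sum_a [ SSY_a * w_ja^2 ] / sum_a SSY_a ) with
    SSY_a = q_a^2 (t_a' t_a), the response variance captured by component a.
    The weights are unit-norm, so mean(VIP^2) = 1 identically.
    """
    ssy = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("degenerate model: no captured response variance")
    p = model.W.shape[0]
    return np.sqrt(p * (model.W**2 @ ssy) / total)
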