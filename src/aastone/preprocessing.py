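"""Column-wise scaling fitted on training data only.

This is the leakage boundary of every cross-validation loop: scaler
parameters are estimated on a fold's training rows and applied unchanged to
its held-out rows.  Autoscaling (mean-centre, unit variance) is the default
because the amino-acid panel spans two orders of magnitude in abundance and
an unscaled projection model would be dominated by the high-abundance
analytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalingParams", "fit_scaler", "apply_scaler", "SCALING_METHODS"]

SCALING_METHODS = ("auto", "pareto", "center", "none")


@dataclass(frozen=True)
class ScalingParams:
    """Per-column location/scale estimated from a training matrix.

    ``divisor`` is the effective per-column denominator after the method is
    applied (1 for "center"/"none", SD for "auto", sqrt(SD) for "pareto");
    zero-variance columns get divisor 0 and are mapped to zero on apply.
    """

    means: np.ndarray
    sds: np.ndarray
    method: str = "auto"

    def __post_init__(self) -> None:
        if self.method not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")
        if self.means.shape != self.sds.shape:
            raise ValueError("means and sds must have equal length")

    @property
    def zero_variance_mask(self) -> np.ndarray:
        return self.sds == 0.0

    @property
    def divisor(self) -> np.ndarray:
        if self.method == "auto":
            return self.sds
        if self.method == "pareto":
            return np.sqrt(self.sds)
        return np.ones_like(self.sds)


def fit_scaler(X_train: np.ndarray, method: str = "auto") -> ScalingParams:
    """Estimate per-column mean and SD (ddof=1) from training rows."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("fit_scaler requires a 2-D matrix with >= 2 rows")
    means = X_train.mean(axis=0)
    sds = X_train.std(axis=0, ddof=1)
    return ScalingParams(means=means, sds=sds, method=method)


def apply_scaler(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Apply stored scaling: (x - mean) / divisor per column.

    For "auto" and "pareto", columns that were constant in training scale
    to zero (they then carry no weight in any downstream projection).
    For "none", X is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[np.newaxis, :]
    if X.shape[1] != params.means.shape[0]:
        raise ValueError(
            f"column count {X.shape[1]} does not match scaler ({params.means.shape[0]})"
        )
    if params.method == "none":
        return X.copy()
    centered = X - params.means
    div = params.divisor
    out = np.divide(centered, div, out=np.zeros_like(centered), where=div != 0)
    return out
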