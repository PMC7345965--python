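"""Permutation-based significance of the cross-validated classifier.

A validated classification statistic can still look good by chance on a
small cohort.  The null distribution of each figure of merit — number of
misclassifications (NMC), AUROC, and discriminant Q2 — is built by
shuffling the class labels and re-running the *entire* double
cross-validation (scaling, latent-variable selection, outer prediction) on
the permuted labels, once per permutation.  The observed statistic is
computed by the identical single-pass procedure on the unpermuted labels,
so observed and null values are exchangeable under the null hypothesis.

Empirical p-values use the add-one estimator
``p = (#{null at least as extreme} + 1) / (n_permutations + 1)``,
which never returns zero and is valid under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dcv import (
    DCVConfig,
    metric_auroc,
    metric_dq2,
    metric_nmc,
    single_pass_scores,
)
from .io import CohortTable
from .plsda import classify

__all__ = ["PermutationResult", "permutation_null", "empirical_pvalue"]


@dataclass
class PermutationResult:
    """Null distributions and empirical p-values for NMC, AUROC, DQ2."""

    n_permutations: int
    null_nmc: np.ndarray
    null_auroc: np.ndarray
    null_dq2: np.ndarray
    observed_nmc: int
    observed_auroc: float
    observed_dq2: float
    p_nmc: float
    p_auroc: float
    p_dq2: float

    def null_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "permutation": np.arange(1, self.n_permutations + 1),
                "nmc": self.null_nmc,
                "auroc": self.null_auroc,
                "dq2": self.null_dq2,
            }
        )

    def summary(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "observed": {
                "nmc": self.observed_nmc,
                "auroc": self.observed_auroc,
                "dq2": self.observed_dq2,
            },
            "p_values": {"nmc": self.p_nmc, "auroc": self.p_auroc, "dq2": self.p_dq2},
        }


def empirical_pvalue(
    null: np.ndarray, observed: float, direction: str
) -> float:
    """Add-one empirical p-value.

    ``direction`` states which tail is evidence against the null:
    ``"greater-is-extreme"`` (AUROC, DQ2) or ``"smaller-is-extreme"`` (NMC).
    Null values exactly equal to the observed statistic count as extreme.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if direction == "greater-is-extreme":
        n_extreme = int((null >= observed).sum())
    elif direction == "smaller-is-extreme":
        n_extreme = int((null <= observed).sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return (n_extreme + 1) / (null.size + 1)


def _statistics(
    table: CohortTable, config: DCVConfig, rng: np.random.Generator
) -> tuple[int, float, float]:
    scores = single_pass_scores(table, config, rng)
    labels = classify(scores, config.threshold)
    return (
        metric_nmc(table.y, labels),
        metric_auroc(table.y, scores),
        metric_dq2(table.y, scores),
    )


def permutation_null(
    table: CohortTable,
    dcv_config: DCVConfig,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Build the permutation null of NMC/AUROC/DQ2 and the observed values.

    Labels only are shuffled (rows of X untouched), preserving the analyte
    correlation structure.  Each permutation re-runs one complete DCV pass
    with a fresh fold assignment drawn from the same seeded stream.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))

    observed_nmc, observed_auroc, observed_dq2 = _statistics(table, dcv_config, rng)

    null_nmc = np.empty(n_permutations, dtype=int)
    null_auroc = np.empty(n_permutations)
    null_dq2 = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(table.y)
        while len(np.unique(y_perm)) < 2:  # pragma: no cover - needs n tiny
            y_perm = rng.permutation(table.y)
        nmc, auroc, dq2 = _statistics(table.with_labels(y_perm), dcv_config, rng)
        null_nmc[i] = nmc
        null_auroc[i] = auroc
        null_dq2[i] = dq2

    return PermutationResult(
        n_permutations=n_permutations,
        null_nmc=null_nmc,
        null_auroc=null_auroc,
        null_dq2=null_dq2,
        observed_nmc=observed_nmc,
        observed_auroc=observed_auroc,
        observed_dq2=observed_dq2,
        p_nmc=empirical_pvalue(null_nmc, observed_nmc, "smaller-is-extreme"),
        p_auroc=empirical_pvalue(null_auroc, observed_auroc, "greater-is-extreme"),
        p_dq2=empirical_pvalue(null_dq2, observed_dq2, "greater-is-extreme"),
    )
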