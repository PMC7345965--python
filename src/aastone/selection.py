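"""Biomarker selection: VIP and rank product, and their consensus.

Two complementary selectors are reported.  VIP (variable importance in
projection) is model-based: it comes from the single final model refit on
all samples.  The rank product is resampling-based: within every outer-fold
submodel of the cross-validation, analytes are ranked by the magnitude of
their regression coefficient (rank 1 = largest), and RP is the geometric
mean of an analyte's ranks across submodels — an analyte must matter in
*every* resample to earn a small RP.  An analyte flagged by both selectors
is a robust candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dcv import DCVResult
from .plsda import compute_vip

__all__ = ["SelectionResult", "rank_product", "consensus_selection", "select_biomarkers"]


@dataclass
class SelectionResult:
    """Per-analyte importance values and the consensus of both rankings."""

    analyte_names: list[str]
    vip: np.ndarray
    rp: np.ndarray
    vip_rank: np.ndarray      # 1 = most important (largest VIP)
    rp_rank: np.ndarray       # 1 = most important (smallest RP)
    consensus_top_k: list[str]
    k: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": self.analyte_names,
                "vip": self.vip,
                "vip_rank": self.vip_rank,
                "rank_product": self.rp,
                "rp_rank": self.rp_rank,
                "consensus": [a in set(self.consensus_top_k) for a in self.analyte_names],
            }
        )


def _dense_ranks(keys: list[tuple]) -> np.ndarray:
    """Rank 1..p by sort order of ``keys`` (already tie-broken)."""
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    ranks = np.empty(len(keys), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def rank_product(importances: np.ndarray) -> np.ndarray:
    """Geometric mean of per-submodel importance ranks, per analyte.

    ``importances`` is a (submodels x analytes) matrix; within each
    submodel analytes are ranked by descending absolute importance (rank 1
    = largest; ties share their mid-rank).  RP is always >= 1 and equals 1
    only for an analyte ranked first in every submodel.
    """
    imp = np.abs(np.asarray(importances, dtype=float))
    if imp.ndim != 2 or imp.shape[0] < 2:
        raise ValueError("rank_product needs >= 2 submodels (rows)")
    if (imp.sum(axis=1) == 0).any():
        raise ValueError("a submodel has all-zero importances")
    ranks = np.vstack([rankdata(-row) for row in imp])
    return np.exp(np.log(ranks).mean(axis=0))


def consensus_selection(
    vip: np.ndarray,
    rp: np.ndarray,
    k: int,
    analyte_names: list[str],
) -> list[str]:
    """Analytes in the top-k of BOTH rankings (VIP descending, RP ascending).

    Ties are broken alphabetically so the selection is reproducible.
    Returned sorted alphabetically.
    """
    p = len(analyte_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}")
    vip_keys = [(-vip[i], analyte_names[i]) for i in range(p)]
    rp_keys = [(rp[i], analyte_names[i]) for i in range(p)]
    vip_rank = _dense_ranks(vip_keys)
    rp_rank = _dense_ranks(rp_keys)
    top_vip = {analyte_names[i] for i in range(p) if vip_rank[i] <= k}
    top_rp = {analyte_names[i] for i in range(p) if rp_rank[i] <= k}
    return sorted(top_vip & top_rp)


def select_biomarkers(
    dcv_result: DCVResult,
    analyte_names: list[str],
    k: int = 9,
) -> SelectionResult:
    """Assemble the full selection report from a DCV run.

    VIP comes from the final all-data model; RP from the absolute
    regression coefficients of every outer-fold submodel.
    """
    vip = compute_vip(dcv_result.final_model)
    rp = rank_product(dcv_result.outer_coefficients)
    p = len(analyte_names)
    vip_rank = _dense_ranks([(-vip[i], analyte_names[i]) for i in range(p)])
    rp_rank = _dense_ranks([(rp[i], analyte_names[i]) for i in range(p)])
    consensus = consensus_selection(vip, rp, k, analyte_names)
    return SelectionResult(
        analyte_names=list(analyte_names),
        vip=vip,
        rp=rp,
        vip_rank=vip_rank,
        rp_rank=rp_rank,
        consensus_top_k=consensus,
        k=k,
    )
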