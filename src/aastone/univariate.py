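"""Per-analyte two-group comparisons (the classical companion table).

Alongside the multivariate classifier, each analyte is compared between
stone formers and controls on its own.  The default protocol applies the
Mann-Whitney U test to every analyte; an optional normality-gated mode
runs Shapiro-Wilk per group (alpha = 0.05) and uses Welch's t-test when
both groups look normal, Mann-Whitney otherwise.

Raw p-values are reported; a Benjamini-Hochberg adjusted column is emitted
as a supplementary extension (clearly labelled) since the analyst may want
multiplicity control over the 35-analyte panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable

__all__ = [
    "UnivariateRow",
    "mann_whitney_u",
    "welch_t_test",
    "welch_t_from_summary",
    "univariate_table",
]

_EXACT_MAX_N = 12  # exact U-distribution enumeration below this combined n


@dataclass(frozen=True)
class UnivariateRow:
    analyte: str
    mean_cnt: float
    sd_cnt: float
    mean_sf: float
    sd_sf: float
    p_value: float
    statistic: float
    test_used: str


def mann_whitney_u(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U statistic, p-value).

    The exact null distribution is enumerated when the combined sample size
    is at most 12 and there are no ties; otherwise the tie-corrected normal
    approximation (with continuity correction) is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    if a.size + b.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t statistic, p-value).

    Both groups constant and equal is reported as (0, 1) — no evidence of
    a difference rather than an undefined statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def welch_t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Welch's t from group summary statistics (no raw data required).

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with Satterthwaite
    degrees of freedom; useful for checking published summary tables.
    """
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se = np.sqrt(va + vb)
    if se == 0:
        return (0.0, 1.0) if mean_a == mean_b else (float(np.inf), 0.0)
    t = (mean_a - mean_b) / se
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def univariate_table(
    table: CohortTable,
    mode: str = "mann-whitney",
    bh_column: bool = True,
) -> pd.DataFrame:
    """One comparison row per analyte: group means +/- SD and a p-value.

    ``mode`` is ``"mann-whitney"`` (default: U test for every analyte) or
    ``"normality-gated"`` (Shapiro-Wilk per group at alpha=0.05; Welch's
    t-test only when both groups pass).  ``bh_column`` appends a
    Benjamini-Hochberg adjusted p-value column (supplementary extension).
    """
    if mode not in ("mann-whitney", "normality-gated"):
        raise ValueError(f"unknown mode {mode!r}")
    table.require_both_classes()
    sf = table.y == 1
    cnt = table.y == 0
    rows: list[UnivariateRow] = []
    for j, name in enumerate(table.analyte_names):
        a_sf = table.X[sf, j]
        a_cnt = table.X[cnt, j]
        use_t = False
        if mode == "normality-gated" and len(a_sf) >= 3 and len(a_cnt) >= 3:
            if a_sf.var(ddof=1) > 0 and a_cnt.var(ddof=1) > 0:
                p_sw_sf = stats.shapiro(a_sf).pvalue
                p_sw_cnt = stats.shapiro(a_cnt).pvalue
                use_t = p_sw_sf > 0.05 and p_sw_cnt > 0.05
        if use_t:
            stat, p = welch_t_test(a_cnt, a_sf)
            test = "t-test"
        else:
            stat, p = mann_whitney_u(a_cnt, a_sf)
            test = "Mann-Whitney"
        rows.append(
            UnivariateRow(
                analyte=name,
                mean_cnt=float(a_cnt.mean()),
                sd_cnt=float(a_cnt.std(ddof=1)),
                mean_sf=float(a_sf.mean()),
                sd_sf=float(a_sf.std(ddof=1)),
                p_value=p,
                statistic=stat,
                test_used=test,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if bh_column:
        df["p_bh_supplementary"] = stats.false_discovery_control(
            df["p_value"].to_numpy(), method="bh"
        )
    return df
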