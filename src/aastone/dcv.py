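"""Repeated stratified double cross-validation (DCV) for PLS-DA.

Model complexity (the number of latent variables, LV) must be chosen on
data that never touches the performance estimate, or the estimate is
optimistic.  DCV nests two loops: for each outer fold, an inner
cross-validation over the outer-training samples picks the LV count that
minimises the inner misclassification count (ties broken towards fewer
LVs); the model is then refit on the whole outer-training set at that LV
and scored on the held-out outer fold.  Scaling is refit inside every
training partition, inner and outer, so no statistic leaks across folds.

The procedure is repeated over independent random fold assignments;
classification rates are summarised as mean +/- SEM over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CohortTable
from .plsda import PLSModel, classify, fit_plsda, predict_scores

__all__ = [
    "DCVConfig",
    "DCVResult",
    "double_cross_validate",
    "single_pass_scores",
    "metric_nmc",
    "metric_auroc",
    "metric_dq2",
    "metric_q2",
    "stratified_folds",
]


# ---------------------------------------------------------------------------
# Figures of merit
# ---------------------------------------------------------------------------

def metric_nmc(true: np.ndarray, predicted: np.ndarray) -> int:
    """Number of misclassifications: count of label disagreements."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise ValueError("true and predicted labels must have equal length")
    return int((true != predicted).sum())


def metric_auroc(true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    The probability that a randomly chosen stone former scores above a
    randomly chosen control, with tied scores counted one half.
    """
    true = np.asarray(true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((true == 1).sum())
    n_neg = int((true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)  # mid-ranks handle ties as 0.5 per pair
    u = ranks[true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _class_residuals(true: np.ndarray, scores: np.ndarray, truncate: bool) -> np.ndarray:
    e = np.asarray(true, dtype=float) - np.asarray(scores, dtype=float)
    if truncate:
        e = e.copy()
        # predictions beyond their own class label count as perfect
        e[(true == 1) & (scores > 1)] = 0.0
        e[(true == 0) & (scores < 0)] = 0.0
    return e


def _q2_like(true: np.ndarray, scores: np.ndarray, truncate: bool) -> float:
    true = np.asarray(true, dtype=float)
    tss = float(((true - true.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("zero total sum of squares: labels are constant")
    e = _class_residuals(true, scores, truncate)
    return 1.0 - float((e**2).sum()) / tss


def metric_dq2(true: np.ndarray, scores: np.ndarray) -> float:
    """Discriminant Q2: cross-validated explained class variance where
    residuals of predictions overshooting their own class label (y=1 with
    score>1, or y=0 with score<0) are set to zero — a classifier should not
    be penalised for predicting a class "too confidently"."""
    return _q2_like(true, scores, truncate=True)


def metric_q2(true: np.ndarray, scores: np.ndarray) -> float:
    """Plain predictive Q2 (no residual truncation); DQ2 >= Q2 always."""
    return _q2_like(true, scores, truncate=False)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random stratified fold assignment; every fold gets >=1 of each class.

    Within each class, indices are shuffled and dealt round-robin.  If the
    rarer class has fewer members than ``n_folds``, the fold count is
    reduced to that size (with a warning); fewer than 2 members of either
    class is an error.
    """
    y = np.asarray(y)
    counts = {c: int((y == c).sum()) for c in (0, 1)}
    limiting = min(counts, key=counts.get)
    if counts[limiting] < 2:
        name = "CNT" if limiting == 0 else "SF"
        raise ValueError(
            f"stratification infeasible: class {name} has {counts[limiting]} sample(s)"
        )
    if counts[limiting] < n_folds:
        name = "CNT" if limiting == 0 else "SF"
        warn(
            f"reducing folds from {n_folds} to {counts[limiting]} "
            f"(limiting class {name})",
            stacklevel=2,
        )
        n_folds = counts[limiting]
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in (0, 1):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for i, sample in enumerate(idx):
            folds[i % n_folds].append(int(sample))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


# ---------------------------------------------------------------------------
# DCV proper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DCVConfig:
    """Settings for repeated double cross-validation.

    Defaults (5 outer folds, 5 inner folds, 20 repetitions, up to 10 LVs)
    are sized for cohorts of a few dozen samples: each outer fold then
    holds 5-6 of 27 samples and the SEM over 20 repetitions is a stable
    +/- summary.
    """

    n_outer_folds: int = 5
    n_inner_folds: int = 5
    n_repetitions: int = 20
    max_lv: int = 10
    seed: int = 0
    scaling: str = "auto"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.n_repetitions < 1 or self.max_lv < 1:
            raise ValueError("n_repetitions and max_lv must be >= 1")


@dataclass
class DCVResult:
    """Outputs of repeated DCV.

    Rates are percentages.  ``outer_scores`` has one row per repetition and
    one column per sample: each sample's continuous response, predicted by
    the one outer model that held it out in that repetition.
    """

    config: DCVConfig
    sample_ids: list[str]
    y: np.ndarray
    outer_scores: np.ndarray          # (n_repetitions, n_samples)
    outer_labels: np.ndarray          # (n_repetitions, n_samples)
    chosen_lv: np.ndarray             # (n_repetitions, n_outer_folds)
    inner_accuracy: np.ndarray        # per repetition, %
    outer_accuracy: np.ndarray        # per repetition, %
    outer_accuracy_sf: np.ndarray     # per repetition, % of cases correct
    outer_accuracy_cnt: np.ndarray    # per repetition, % of controls correct
    outer_coefficients: np.ndarray    # (n_rep * n_outer_folds, n_analytes)
    final_model: PLSModel
    final_lv: int

    def _mean_sem(self, values: np.ndarray) -> tuple[float, float]:
        m = float(values.mean())
        if len(values) > 1:
            sem = float(values.std(ddof=1) / np.sqrt(len(values)))
        else:
            sem = 0.0
        return m, sem

    @property
    def summary(self) -> dict[str, float]:
        """Mean +/- SEM (over repetitions) of every rate, in percent."""
        out: dict[str, float] = {}
        for key, vals in [
            ("outer_accuracy", self.outer_accuracy),
            ("outer_accuracy_sf", self.outer_accuracy_sf),
            ("outer_accuracy_cnt", self.outer_accuracy_cnt),
            ("inner_accuracy", self.inner_accuracy),
        ]:
            m, s = self._mean_sem(vals)
            out[f"{key}_mean"] = m
            out[f"{key}_sem"] = s
        out["final_lv"] = float(self.final_lv)
        return out

    def summary_frame(self) -> pd.DataFrame:
        s = self.summary
        rows = []
        for key in ("outer_accuracy", "outer_accuracy_sf", "outer_accuracy_cnt",
                    "inner_accuracy"):
            rows.append(
                {"rate": key, "mean_pct": s[f"{key}_mean"], "sem_pct": s[f"{key}_sem"]}
            )
        return pd.DataFrame(rows)

    def repetitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repetition": np.arange(1, len(self.outer_accuracy) + 1),
                "outer_accuracy_pct": self.outer_accuracy,
                "outer_accuracy_sf_pct": self.outer_accuracy_sf,
                "outer_accuracy_cnt_pct": self.outer_accuracy_cnt,
                "inner_accuracy_pct": self.inner_accuracy,
                "modal_chosen_lv": [
                    int(np.bincount(row).argmax()) for row in self.chosen_lv
                ],
            }
        )

    def scores_frame(self) -> pd.DataFrame:
        """Sample coordinates on the final model's first two LVs."""
        T = self.final_model.T
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "class": np.where(self.y == 1, "SF", "CNT"),
                "LV1": T[:, 0],
            }
        )
        df["LV2"] = T[:, 1] if T.shape[1] > 1 else 0.0
        return df


def _select_lv_inner(
    X: np.ndarray,
    y: np.ndarray,
    config: DCVConfig,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Inner CV over the outer-training set: choose the LV count with the
    fewest pooled inner misclassifications (tie -> fewer LVs).  Returns the
    chosen LV and the inner accuracy (%) at that LV."""
    n = len(y)
    folds = stratified_folds(y, config.n_inner_folds, rng)
    lv_cap = min(config.max_lv, n - max(len(f) for f in folds) - 1, X.shape[1])
    lv_cap = max(lv_cap, 1)
    scores = np.full((n, lv_cap), np.nan)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = fit_plsda(
            X[train_idx], y[train_idx], lv_cap,
            scaling=config.scaling, threshold=config.threshold,
        )
        for a in range(1, model.n_lv + 1):
            scores[test_idx, a - 1] = predict_scores(model, X[test_idx], n_lv=a)
        # folds whose training set ran out of rank reuse the deepest model
        for a in range(model.n_lv + 1, lv_cap + 1):
            scores[test_idx, a - 1] = scores[test_idx, model.n_lv - 1]
    nmc_by_lv = np.array(
        [
            metric_nmc(y, classify(scores[:, a], config.threshold))
            for a in range(lv_cap)
        ]
    )
    best = int(np.argmin(nmc_by_lv))  # argmin takes the first = fewest LVs
    inner_acc = 100.0 * (1.0 - nmc_by_lv[best] / n)
    return best + 1, float(inner_acc)


def _one_pass(
    table: CohortTable, config: DCVConfig, rng: np.random.Generator
) -> dict:
    """One full DCV repetition: returns per-sample outer scores, chosen LVs,
    inner accuracies and outer-fold coefficient vectors."""
    X, y = table.X, table.y
    n = table.n_samples
    outer_scores = np.empty(n)
    chosen: list[int] = []
    inner_accs: list[float] = []
    coefs: list[np.ndarray] = []
    for test_idx in stratified_folds(y, config.n_outer_folds, rng):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        lv, inner_acc = _select_lv_inner(X[train_idx], y[train_idx], config, rng)
        model = fit_plsda(
            X[train_idx], y[train_idx], lv,
            scaling=config.scaling, threshold=config.threshold,
        )
        outer_scores[test_idx] = predict_scores(model, X[test_idx])
        chosen.append(model.n_lv)
        inner_accs.append(inner_acc)
        coefs.append(model.B.copy())
    return {
        "scores": outer_scores,
        "chosen_lv": chosen,
        "inner_accuracy": float(np.mean(inner_accs)),
        "coefficients": coefs,
    }


def double_cross_validate(table: CohortTable, config: DCVConfig) -> DCVResult:
    """Run repeated stratified DCV on a cohort.

    Every sample is predicted exactly once per repetition, by the outer
    model that held it out.  The final interpretable model (for score plots
    and VIP) is refit on all samples at the modal chosen LV count.
    """
    table.require_both_classes()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))
    n_rep = config.n_repetitions
    n = table.n_samples

    outer_scores = np.empty((n_rep, n))
    outer_labels = np.empty((n_rep, n), dtype=int)
    chosen_lv = np.empty((n_rep, config.n_outer_folds), dtype=int)
    inner_acc = np.empty(n_rep)
    outer_acc = np.empty(n_rep)
    outer_acc_sf = np.empty(n_rep)
    outer_acc_cnt = np.empty(n_rep)
    all_coefs: list[np.ndarray] = []

    y = table.y
    sf, cnt = y == 1, y == 0
    for r in range(n_rep):
        res = _one_pass(table, config, rng)
        outer_scores[r] = res["scores"]
        labels = classify(res["scores"], config.threshold)
        outer_labels[r] = labels
        chosen_lv[r] = res["chosen_lv"]
        inner_acc[r] = res["inner_accuracy"]
        outer_acc[r] = 100.0 * (labels == y).mean()
        outer_acc_sf[r] = 100.0 * (labels[sf] == 1).mean()
        outer_acc_cnt[r] = 100.0 * (labels[cnt] == 0).mean()
        all_coefs.extend(res["coefficients"])

    final_lv = int(np.bincount(chosen_lv.ravel()).argmax())
    final_model = fit_plsda(
        table.X, y, final_lv, scaling=config.scaling, threshold=config.threshold
    )
    return DCVResult(
        config=config,
        sample_ids=list(table.sample_ids),
        y=y.copy(),
        outer_scores=outer_scores,
        outer_labels=outer_labels,
        chosen_lv=chosen_lv,
        inner_accuracy=inner_acc,
        outer_accuracy=outer_acc,
        outer_accuracy_sf=outer_acc_sf,
        outer_accuracy_cnt=outer_acc_cnt,
        outer_coefficients=np.vstack(all_coefs),
        final_model=final_model,
        final_lv=final_lv,
    )


def single_pass_scores(
    table: CohortTable, config: DCVConfig, rng: np.random.Generator
) -> np.ndarray:
    """Pooled outer-loop scores from one DCV pass (one fold assignment).

    This is the unit of work of the permutation test: cheap enough to run
    a thousand times, yet fully nested (scaling, LV selection and outer
    prediction all happen inside), so permuted and observed statistics are
    exchangeable.
    """
    table.require_both_classes()
    return _one_pass(table, config, rng)["scores"]
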