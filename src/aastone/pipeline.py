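"""End-to-end orchestration: simulate -> DCV -> selection -> permutation -> report.

A :class:`RunConfig` plus a root seed fully determines every numeric output.
The root seed is fanned out to the stages through fixed offsets (cohort
generation, DCV fold assignment, permutation shuffling), so each stage can
be re-run in isolation with the seed recorded in the manifest.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import cohort as cohort_mod
from .dcv import DCVConfig, double_cross_validate
from .io import CohortTable, read_cohort_csv, write_cohort_csv, write_results_bundle
from .permutation import permutation_null
from .selection import select_biomarkers
from .univariate import univariate_table

__all__ = ["RunConfig", "run_full_analysis", "stage_seed"]

_STAGE_OFFSETS = {"cohort": 1, "dcv": 2, "permutation": 3}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    ss = np.random.SeedSequence([root_seed, _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    cohort_csv: str | None = None          # if None, simulate the default cohort
    seed: int = 0
    dcv: DCVConfig | None = None
    n_permutations: int = 1000
    top_k: int = 9
    scaling: str = "auto"
    univariate_mode: str = "mann-whitney"
    outdir: str = "results"

    def resolved_dcv(self) -> DCVConfig:
        if self.dcv is not None:
            return self.dcv
        return DCVConfig(seed=stage_seed(self.seed, "dcv"), scaling=self.scaling)

    def to_dict(self) -> dict:
        d = self.resolved_dcv()
        return {
            "cohort_csv": self.cohort_csv,
            "seed": self.seed,
            "dcv": {
                "n_outer_folds": d.n_outer_folds,
                "n_inner_folds": d.n_inner_folds,
                "n_repetitions": d.n_repetitions,
                "max_lv": d.max_lv,
                "seed": d.seed,
                "scaling": d.scaling,
            },
            "n_permutations": self.n_permutations,
            "top_k": self.top_k,
            "scaling": self.scaling,
            "univariate_mode": self.univariate_mode,
        }


def _load_or_simulate(config: RunConfig, outdir: Path) -> CohortTable:
    if config.cohort_csv is not None:
        return read_cohort_csv(config.cohort_csv)
    spec = cohort_mod.default_cohort_spec(seed=stage_seed(config.seed, "cohort"))
    table = cohort_mod.generate_cohort(spec)
    write_cohort_csv(table, outdir / "simulated_cohort.csv")
    return table


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full strategy in order and write all artifacts.

    Stages: cohort (load or simulate), univariate table, repeated DCV,
    biomarker selection, permutation test (skipped when n_permutations=0),
    results bundle.  Returns the JSON manifest dict; per-stage wall times
    are recorded in it.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    table = _load_or_simulate(config, outdir)
    timings["cohort"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    uni = univariate_table(table, mode=config.univariate_mode)
    timings["univariate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dcv_result = double_cross_validate(table, config.resolved_dcv())
    timings["dcv"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    selection = select_biomarkers(dcv_result, table.analyte_names, k=config.top_k)
    sel_df = selection.frame().merge(
        uni[["analyte", "mean_cnt", "sd_cnt", "mean_sf", "sd_sf", "p_value"]],
        on="analyte",
    )
    timings["selection"] = time.perf_counter() - t0

    results: dict[str, object] = {
        "selection_table": sel_df,
        "dcv_summary": dcv_result.summary_frame(),
        "dcv_repetitions": dcv_result.repetitions_frame(),
        "scores": dcv_result.scores_frame(),
        "config": config.to_dict(),
        "seed": config.seed,
    }

    if config.n_permutations > 0:
        t0 = time.perf_counter()
        perm = permutation_null(
            table,
            config.resolved_dcv(),
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "permutation"),
        )
        timings["permutation"] = time.perf_counter() - t0
        results["permutation_null"] = perm.null_frame()
        results["permutation_summary"] = perm.summary()
    else:
        results["permutation_summary"] = {"skipped": True}

    manifest = write_results_bundle(results, outdir)
    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    return manifest
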