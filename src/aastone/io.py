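"""Cohort table container and CSV/JSON input-output.

The in-memory unit of the whole pipeline is :class:`CohortTable`: a samples x
analytes concentration matrix with binary class labels.  The label encoding
is fixed throughout the package: controls (CNT) = 0, stone formers (SF) = 1,
and every metric treats SF as the positive class.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_results_bundle",
    "LABEL_MAP",
]

LABEL_MAP: dict[str, int] = {"CNT": 0, "SF": 1}


@dataclass
class CohortTable:
    """Samples x analytes concentration table with binary labels.

    Attributes
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``X``.
    X
        Concentration matrix (non-negative), shape (n_samples, n_analytes).
    analyte_names
        Ordered, unique analyte names (columns of ``X``).
    y
        Integer class labels: 0 = control, 1 = stone former.
    """

    sample_ids: list[str]
    X: np.ndarray
    analyte_names: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.y) != n:
            raise ValueError("sample_ids, X rows and y must have equal length")
        if len(self.analyte_names) != p:
            raise ValueError("analyte_names must match X columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids")
        if len(set(self.analyte_names)) != p:
            raise ValueError("duplicated analyte names")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite concentration values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0 (CNT) or 1 (SF)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.X.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_sf, n_cnt)."""
        return int((self.y == 1).sum()), int((self.y == 0).sum())

    def require_both_classes(self) -> None:
        n_sf, n_cnt = self.class_counts
        if n_sf == 0 or n_cnt == 0:
            raise ValueError(
                f"both classes required for analysis (got {n_sf} SF, {n_cnt} CNT)"
            )

    def with_labels(self, y: np.ndarray) -> "CohortTable":
        """Same table with replaced labels (used by permutation tests)."""
        return CohortTable(
            sample_ids=list(self.sample_ids),
            X=self.X,
            analyte_names=list(self.analyte_names),
            y=np.asarray(y, dtype=int),
        )

    def to_dataframe(self, label_column: str = "class") -> pd.DataFrame:
        inverse = {v: k for k, v in LABEL_MAP.items()}
        df = pd.DataFrame(self.X, columns=self.analyte_names)
        df.insert(0, label_column, [inverse[v] for v in self.y])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def read_cohort_csv(
    path: str | Path,
    label_column: str = "class",
    label_map: Mapping[str, int] = LABEL_MAP,
) -> CohortTable:
    """Read a tidy cohort CSV (sample_id, class, one column per analyte).

    The label column must contain exactly the two levels of ``label_map``
    (at least one sample each); any non-numeric concentration cell is
    reported with its row/column coordinates.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "sample_id" not in df.columns or label_column not in df.columns:
        raise ValueError(f"CSV must contain 'sample_id' and {label_column!r} columns")
    labels = df[label_column].astype(str)
    unknown = sorted(set(labels) - set(label_map))
    if unknown:
        raise ValueError(f"unknown class labels {unknown}; expected {sorted(label_map)}")
    y = labels.map(label_map).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("cohort file contains a single class; two are required")

    analyte_cols = [c for c in df.columns if c not in ("sample_id", label_column)]
    X = np.empty((len(df), len(analyte_cols)))
    for j, col in enumerate(analyte_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ValueError(
                f"non-numeric concentration at row {bad[0] + 2}, column {col!r}"
            )
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"missing concentration at row {row + 2}, column {col!r}")
        X[:, j] = vals.to_numpy()
    return CohortTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        X=X,
        analyte_names=analyte_cols,
        y=y,
    )


def write_cohort_csv(table: CohortTable, path: str | Path, units: str = "umol/L") -> None:
    """Write a cohort as tidy CSV with a units header comment."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# concentrations in {units}; class: CNT=control, SF=stone former\n")
        # %.17g guarantees exact float round-trips through the CSV
        table.to_dataframe().to_csv(
            fh, index=False, lineterminator="\n", float_format="%.17g"
        )


def _write_csv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def write_results_bundle(results: Mapping[str, object], outdir: str | Path) -> dict:
    """Write all analysis artifacts as CSV plus a JSON run manifest.

    ``results`` may contain (all optional): ``selection_table`` (the
    discriminant-analyte table), ``dcv_summary`` and ``dcv_repetitions``,
    ``scores`` (latent-variable coordinates of the final model),
    ``permutation_null`` and ``permutation_summary``, plus ``config`` and
    ``seed`` for the manifest.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    csv_specs = {
        "selection_table.csv": (
            "per-analyte selection results; group summaries in umol/L; "
            "VIP from final model, RP across outer-fold submodels"
        ),
        "dcv_summary.csv": (
            "double cross-validation summary; rates in %, mean +/- SEM over repetitions"
        ),
        "dcv_repetitions.csv": "per-repetition DCV classification rates (%)",
        "scores.csv": "latent-variable score coordinates of the final all-data model",
        "permutation_null.csv": "per-permutation null statistics (NMC count, AUROC, DQ2)",
    }
    key_map = {
        "selection_table.csv": "selection_table",
        "dcv_summary.csv": "dcv_summary",
        "dcv_repetitions.csv": "dcv_repetitions",
        "scores.csv": "scores",
        "permutation_null.csv": "permutation_null",
    }
    for fname, comment in csv_specs.items():
        obj = results.get(key_map[fname])
        if obj is None:
            continue
        df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(obj)
        _write_csv(df, outdir / fname, comment)
        artifacts.append(fname)

    perm_summary = results.get("permutation_summary")
    if perm_summary is not None:
        with open(outdir / "permutation_summary.json", "w") as fh:
            json.dump(perm_summary, fh, indent=2, sort_keys=True)
        artifacts.append("permutation_summary.json")

    manifest = {
        "artifacts": artifacts,
        "config": results.get("config"),
        "seed": results.get("seed"),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
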