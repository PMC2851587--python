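"""Shared data model: run-design tables and log2 intensity matrices.

The design table lists one LC-MS run per row with its run order, sample id,
the three experimental factors (age in {ed12, ed17}, sex in {M, F}, treatment
in {C, E}), the randomization block and a reference-replicate flag (repeated
injections of one reference sample interspersed through the run sequence).

The intensity matrix is peptides x runs of log2 ion intensities with explicit
missing values (empty TSV cell / NaN); missingness is never silently imputed.
A set of state flags records which pipeline stages have been applied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AGES", "SEXES", "TREATMENTS", "GROUP_LABELS",
    "DesignError", "MatrixError",
    "IntensityMatrix",
    "read_design", "write_design", "validate_design",
    "read_matrix", "write_matrix",
    "drop_runs", "group_labels", "bundled_design_path",
]

AGES = ("ed12", "ed17")
SEXES = ("M", "F")
TREATMENTS = ("C", "E")
GROUP_LABELS = tuple(f"{a}{s}{t}" for a in AGES for s in SEXES for t in TREATMENTS)

_DESIGN_COLUMNS = ["run_order", "run_id", "sample_id", "age", "sex",
                   "treatment", "block", "is_reference"]

_STATE_ORDER = ("raw", "log2", "calibrated", "drift_corrected",
                "filtered", "collapsed")


class DesignError(ValueError):
    """Invalid or inconsistent design table."""


class MatrixError(ValueError):
    """Invalid or inconsistent intensity matrix."""


@dataclass
class IntensityMatrix:
    """Peptides x runs grid of log2 ion intensities with a missingness mask."""

    values: pd.DataFrame            # index = peptide ids, columns = run ids
    state: tuple[str, ...] = ("log2",)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        for flag in self.state:
            if flag not in _STATE_ORDER:
                raise MatrixError(f"unknown state flag {flag!r}")

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where a value is observed."""
        return self.values.notna()

    def has_state(self, flag: str) -> bool:
        return flag in self.state

    def with_state(self, flag: str, values: pd.DataFrame | None = None) -> "IntensityMatrix":
        """Copy with ``flag`` appended (state flags are monotone)."""
        if flag not in _STATE_ORDER:
            raise MatrixError(f"unknown state flag {flag!r}")
        new_vals = self.values if values is None else values
        new_state = self.state if flag in self.state else self.state + (flag,)
        return IntensityMatrix(values=new_vals.copy(), state=new_state)

    def require_state(self, flag: str) -> None:
        if flag not in self.state:
            raise MatrixError(
                f"matrix must be {flag!r} for this operation; state={self.state}"
            )


def validate_design(design: pd.DataFrame) -> None:
    """Fail fast on a malformed design table; aggregates all problems."""
    errors: list[str] = []
    for col in _DESIGN_COLUMNS:
        if col not in design.columns:
            errors.append(f"missing column {col!r}")
    if errors:
        raise DesignError("; ".join(errors))
    if len(design) == 0:
        raise DesignError("no runs")
    order = design["run_order"].to_numpy()
    if sorted(order) != list(range(1, len(design) + 1)):
        errors.append("run_order is not a permutation of 1..N")
    if design["run_id"].duplicated().any():
        dup = design.loc[design["run_id"].duplicated(), "run_id"].tolist()
        errors.append(f"duplicate run ids {dup}")
    for col, levels in [("age", AGES), ("sex", SEXES), ("treatment", TREATMENTS)]:
        bad = sorted(set(design[col]) - set(levels))
        if bad:
            errors.append(f"unknown {col} level(s) {bad}; expected {levels}")
    ref = design["is_reference"].astype(bool)
    nonref = design.loc[~ref]
    if nonref["sample_id"].duplicated().any():
        dup = nonref.loc[nonref["sample_id"].duplicated(), "sample_id"].tolist()
        errors.append(f"non-reference sample id(s) appear more than once: {dup}")
    if ref.any() and design.loc[ref, "sample_id"].nunique() != 1:
        errors.append("reference runs must share a single sample_id")
    if errors:
        raise DesignError("; ".join(errors))


def read_design(source) -> pd.DataFrame:
    """Read and validate a design TSV."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    if len(df) == 0:
        raise DesignError("no runs")
    if "run_order" in df.columns:
        df["run_order"] = df["run_order"].astype(int)
    if "is_reference" in df.columns:
        df["is_reference"] = df["is_reference"].astype(int).astype(bool)
    validate_design(df)
    return df.reset_index(drop=True)


def write_design(design: pd.DataFrame, path) -> None:
    validate_design(design)
    out = design.copy()
    out["is_reference"] = out["is_reference"].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def bundled_design_path():
    from importlib import resources

    return resources.files("pepquant.data").joinpath("run_design.tsv")


def load_bundled_design() -> pd.DataFrame:
    from importlib import resources

    with resources.as_file(bundled_design_path()) as path:
        return read_design(path)


def read_matrix(source, design: pd.DataFrame | None = None,
                state: tuple[str, ...] = ("log2",)) -> IntensityMatrix:
    """Read a peptides x runs TSV (first column = peptide id, blank = missing)."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if design is not None:
        orphans = [c for c in df.columns if c not in set(design["run_id"])]
        missing = [r for r in design["run_id"] if r not in set(df.columns)]
        if orphans or missing:
            raise MatrixError(
                f"matrix/design mismatch: orphan matrix runs {orphans}, "
                f"design runs absent from matrix {missing}"
            )
    return IntensityMatrix(values=df.astype(float), state=state)


def write_matrix(matrix: IntensityMatrix, path) -> None:
    """Serialize with 10 significant digits, tab-separated, LF endings."""
    matrix.values.to_csv(path, sep="\t", float_format="%.10g",
                         index_label="peptide", lineterminator="\n")


def matrix_to_text(matrix: IntensityMatrix) -> str:
    buf = io.StringIO()
    write_matrix(matrix, buf)
    return buf.getvalue()


def drop_runs(matrix: IntensityMatrix, design: pd.DataFrame,
              run_ids) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Remove runs (outliers) from both the matrix and the design.

    ``run_ids`` may name run ids or underlying sample ids.  Run order is
    re-packed to stay a contiguous 1..N permutation.
    """
    run_ids = list(run_ids)
    known = set(design["run_id"]) | set(design["sample_id"])
    unknown = [r for r in run_ids if r not in known]
    if unknown:
        raise DesignError(f"unknown run id(s): {unknown}")
    keep = ~(design["run_id"].isin(run_ids) | design["sample_id"].isin(run_ids))
    new_design = design.loc[keep].copy()
    new_design = new_design.sort_values("run_order").reset_index(drop=True)
    new_design["run_order"] = np.arange(1, len(new_design) + 1)
    new_vals = matrix.values.loc[:, list(new_design["run_id"])]
    return IntensityMatrix(values=new_vals, state=matrix.state), new_design


def group_labels(design: pd.DataFrame) -> pd.Series:
    """Derive the 8 group labels (age x sex x treatment) per run, run_id-indexed."""
    labels = design["age"].str.cat([design["sex"], design["treatment"]])
    return pd.Series(labels.to_numpy(), index=design["run_id"].to_numpy(),
                     name="group")
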