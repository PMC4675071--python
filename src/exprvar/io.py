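"""Reading, validating and writing expression matrices, sample metadata and
qPCR Ct tables.

All tabular interchange is plain TSV. An expression matrix is features x
samples with the first column holding feature IDs and the header row holding
sample IDs; a metadata file has columns ``sample_id``, ``group`` and
optionally ``subject_id`` / ``timepoint``; a Ct table is long-format with
columns ``subject_id``, ``timepoint``, ``gene``, ``ct``.

The "valid features" rule: a feature is retained only if it has no missing
value in any sample and (when group labels are available) a strictly positive
mean in every group — the coefficient of variation is undefined otherwise.
Filtering drops features; nothing is imputed.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleGroups",
    "CtTable",
    "FilterReport",
    "read_matrix",
    "write_matrix",
    "read_sample_groups",
    "read_ct_table",
    "write_ct_table",
    "filter_valid_features",
    "unlog",
    "log2_transform",
]

#: strings treated as a missing cell in matrix files
_NA_TOKENS = {"", "na", "nan", "null", "n/a", "none"}


@dataclass
class ExpressionMatrix:
    """Feature x sample matrix of positive expression values.

    ``data`` is a DataFrame indexed by feature ID with sample IDs as columns;
    ``scale`` records whether values are linear intensities or log2 of them.
    Missing cells are NaN until :func:`filter_valid_features` removes the
    affected features.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in {"linear", "log2"}:
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        dup_f = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_f):
            raise ValueError(f"duplicate feature ID(s): {list(dup_f)[:5]}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_s):
            raise ValueError(f"duplicate sample ID(s): {list(dup_s)[:5]}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SampleGroups:
    """Sample -> group assignment, optionally with subject pairing.

    For paired designs ``paired_ids`` maps each sample to a subject; a subject
    must then appear exactly once per group.
    """

    assignment: dict[str, str]
    paired_ids: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.paired_ids is not None:
            per_group: dict[str, list[str]] = {}
            for sample, subject in self.paired_ids.items():
                if sample not in self.assignment:
                    raise ValueError(f"paired sample {sample!r} has no group label")
                per_group.setdefault(self.assignment[sample], []).append(subject)
            for group, subjects in per_group.items():
                if len(subjects) != len(set(subjects)):
                    raise ValueError(
                        f"a subject occurs more than once in group {group!r}"
                    )

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g, None)
        return list(seen)

    def validate_against(self, m: ExpressionMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold table.

    Columns: subject_id, timepoint, gene, ct. Ct values must be finite and
    positive (PCR cycles).
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "timepoint", "gene", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing column(s): {missing}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)):
            raise ValueError("Ct table contains non-finite Ct values")
        if np.any(ct <= 0):
            raise ValueError("Ct values must be positive (PCR cycles)")
        dup = self.data.duplicated(subset=["subject_id", "timepoint", "gene"])
        if dup.any():
            bad = self.data.loc[dup, ["subject_id", "timepoint", "gene"]].iloc[0]
            raise ValueError(
                f"duplicate Ct entry for subject={bad.subject_id!r} "
                f"timepoint={bad.timepoint!r} gene={bad.gene!r}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    @property
    def timepoints(self) -> list[str]:
        return sorted(self.data["timepoint"].unique())


@dataclass
class FilterReport:
    """Accounting of features removed by the validity filter."""

    n_input: int
    n_missing_dropped: int = 0
    n_nonpositive_dropped: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_missing_dropped + self.n_nonpositive_dropped

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_dropped


def _extract_table_text(path: Path) -> str:
    """Return the tabular portion of a matrix file.

    Plain TSV files pass through unchanged. GEO series-matrix-style layouts
    (metadata lines starting with ``!``, the table delimited by
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end``) are reduced
    to the table lines.
    """
    text = Path(path).read_text()
    if not text.lstrip().startswith("!"):
        return text
    lines = []
    inside = False
    for line in text.splitlines():
        low = line.strip().lower()
        if low.startswith("!series_matrix_table_begin"):
            inside = True
            continue
        if low.startswith("!series_matrix_table_end"):
            inside = False
            continue
        if inside and line.strip():
            lines.append(line.strip('"').replace('"', ""))
    if not lines:
        raise ValueError(f"no series-matrix table found in {path}")
    return "\n".join(lines) + "\n"


def read_matrix(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = feature IDs, header = sample IDs).

    Empty cells and NA tokens become missing entries (NaN) for downstream
    filtering; any other non-numeric cell is a hard error naming the offending
    row and column. ``scale`` is recorded verbatim.
    """
    raw = pd.read_csv(
        _io.StringIO(_extract_table_text(Path(path))),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    def parse_cell(cell: str, row: str, col: str) -> float:
        s = cell.strip()
        if s.lower() in _NA_TOKENS:
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ValueError(
                f"non-numeric value {cell!r} at feature {row!r}, sample {col!r}"
            ) from None

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        column = raw[col].to_numpy()
        for i, cell in enumerate(column):
            values[i, j] = parse_cell(cell, raw.index[i], col)

    return ExpressionMatrix(pd.DataFrame(values, index=raw.index, columns=raw.columns), scale)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with >= 6 significant digits (round-trip safe)."""
    m.data.to_csv(path, sep="\t", float_format="%.17g", index_label="feature_id")


def read_sample_groups(path: str | Path) -> SampleGroups:
    """Read a sample-metadata TSV: sample_id, group[, subject_id][, timepoint]."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata file missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in metadata")
    assignment = dict(zip(meta["sample_id"], meta["group"]))
    paired = None
    if "subject_id" in meta.columns:
        paired = dict(zip(meta["sample_id"], meta["subject_id"]))
    return SampleGroups(assignment=assignment, paired_ids=paired)


def read_ct_table(path: str | Path) -> CtTable:
    """Read a long-format Ct TSV with columns subject_id, timepoint, gene, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"ct": float})
    for col in ("subject_id", "timepoint", "gene"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return CtTable(df)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


def filter_valid_features(
    m: ExpressionMatrix, groups: SampleGroups | None = None
) -> tuple[ExpressionMatrix, FilterReport]:
    """Restrict to valid features; report how many were dropped.

    A feature survives if it has no missing value in any sample and, when
    ``groups`` is given, a strictly positive mean in every group. The
    operation is idempotent.
    """
    report = FilterReport(n_input=m.n_features)
    keep = ~m.data.isna().any(axis=1)
    report.n_missing_dropped = int((~keep).sum())
    data = m.data.loc[keep]

    if groups is not None:
        groups.validate_against(m)
        positive = pd.Series(True, index=data.index)
        for group in groups.groups:
            samples = [s for s in groups.samples_in(group) if s in data.columns]
            if samples:
                positive &= data[samples].mean(axis=1) > 0
        report.n_nonpositive_dropped = int((~positive).sum())
        data = data.loc[positive]

    if data.shape[0] == 0:
        raise ValueError("validity filtering removed every feature")
    return ExpressionMatrix(data, m.scale), report


def unlog(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a log2-scale matrix to linear scale (values -> 2**values).

    Calling on an already-linear matrix is a warned no-op: CV must be computed
    on linear intensities, and this guard keeps the transform idempotent.
    """
    if m.scale == "linear":
        warnings.warn("matrix is already linear-scale; unlog is a no-op", UserWarning)
        return m
    return ExpressionMatrix(np.exp2(m.data), "linear")


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`unlog` for positive matrices."""
    if m.scale == "log2":
        warnings.warn("matrix is already log2-scale; no-op", UserWarning)
        return m
    if (m.data.to_numpy() <= 0).any():
        raise ValueError("log2 transform requires strictly positive values")
    return ExpressionMatrix(np.log2(m.data), "log2")
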