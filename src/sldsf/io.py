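"""Delimited-text I/O for expression matrices and ranked-gene tables.

Expression matrices travel as TSV/CSV with one identifier row and one
identifier column.  On disk the common public convention is genes in rows;
in memory the package always holds samples x genes (rows are samples), so
the loader transposes when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORIENTATIONS = ("genes_in_rows", "samples_in_rows")


@dataclass
class ExpressionMatrix:
    """A gene-expression matrix B, samples x genes, with identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_samples, m_genes)
        Expression levels in arbitrary platform units.
    gene_ids : list of str
        Unique gene identifiers, one per column.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"G{j + 1:04d}" for j in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if n < 2 or m < 2:
            raise ValueError(f"need at least 2 samples and 2 genes, got {n}x{m}")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Samples-x-genes DataFrame with identifier index/columns."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, orientation: str = "samples_in_rows") -> "ExpressionMatrix":
        if orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if orientation == "genes_in_rows":
            frame = frame.T
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(c) for c in frame.columns],
            sample_ids=[str(i) for i in frame.index],
        )


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate {kind} identifier: {name!r}")
        seen.add(name)


def read_expression(
    path,
    orientation: str = "genes_in_rows",
    delimiter: str = "\t",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load a delimited expression matrix.

    Parameters
    ----------
    path : path-like
        Text file with one identifier column (first) and one identifier row
        (header).
    orientation : {"genes_in_rows", "samples_in_rows"}
        How the file is laid out.  The returned matrix is always samples x
        genes regardless.
    delimiter : str
        Field separator.
    impute_missing : bool
        If True, missing cells are replaced by their row mean (file rows).
        Default is to reject files with missing values.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        bad = _locate_non_numeric(frame)
        raise ValueError(
            f"non-numeric cell at row {bad[0]!r}, column {bad[1]!r} in {path}"
        ) from exc
    if frame.isna().any().any():
        if impute_missing:
            frame = frame.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            na_rows = frame.index[frame.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in rows {na_rows[:5]} of {path}")
    return ExpressionMatrix.from_frame(frame, orientation=orientation)


def _locate_non_numeric(frame: pd.DataFrame) -> tuple[str, str]:
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            return str(frame.index[bad.argmax()]), str(col)
    return "?", "?"


def write_expression(
    matrix: ExpressionMatrix,
    path,
    orientation: str = "genes_in_rows",
    delimiter: str = "\t",
) -> None:
    """Write an expression matrix as delimited text (full float precision)."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    frame = matrix.to_frame()
    if orientation == "genes_in_rows":
        frame = frame.T
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def validate_ranking(table: pd.DataFrame) -> pd.DataFrame:
    """Check a ranked-gene table: columns, consecutive ranks, sorted scores."""
    required = ["rank", "gene_id", "score"]
    if list(table.columns) != required:
        raise ValueError(f"ranking table must have columns {required}")
    h = len(table)
    if h and not np.array_equal(table["rank"].to_numpy(), np.arange(1, h + 1)):
        raise ValueError("ranks must be consecutive 1..h")
    scores = table["score"].to_numpy(dtype=float)
    if h and (np.diff(scores) > 1e-12).any():
        raise ValueError("scores must be non-increasing with rank")
    if h and (scores < 0).any():
        raise ValueError("scores must be nonnegative")
    return table


def write_ranking(table: pd.DataFrame, path) -> None:
    """Write a ranked-gene table as TSV: rank, gene_id, score.

    Scores are serialized with 6 significant digits so reruns diff cleanly.
    """
    validate_ranking(table)
    out = table.copy()
    out["score"] = [f"{s:.6g}" for s in out["score"].to_numpy(dtype=float)]
    out.to_csv(path, sep="\t", index=False)


def read_ranking(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return validate_ranking(table)
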