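"""Reading, validation and normalization of expression matrices and group labels.

Expression files are delimited text with a header row of sample ids and a
first column of gene ids.  Label files are two-column ``sample_id, group``
tables with binary group codes (0 = control, 1 = case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GroupLabels",
    "ExpressionParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_group_labels",
    "write_group_labels",
    "normalize_log2",
]


class ExpressionParseError(ValueError):
    """Raised when an expression or label file cannot be parsed or validated."""


@dataclass
class ExpressionMatrix:
    """Gene × sample numeric matrix with identifiers.

    Values are assumed to be on the log2 scale after normalization
    (see :func:`normalize_log2`).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionParseError("values must be a 2-D array")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids) or n_s != len(self.sample_ids):
            raise ExpressionParseError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ExpressionParseError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ExpressionParseError(f"duplicate sample ids: {sorted(dup_s)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionParseError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Row-subset in the given order; unknown ids raise ``KeyError``."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])


@dataclass
class GroupLabels:
    """Sample → group assignment for a binary comparison (0 = control, 1 = case)."""

    assignment: dict[str, int]
    level_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.assignment.items() if g not in (0, 1)}
        if bad:
            raise ExpressionParseError(f"group codes outside {{0,1}}: {bad}")
        sizes = self.group_sizes()
        if sizes[0] == 0 or sizes[1] == 0:
            raise ExpressionParseError(f"both groups must be non-empty, got sizes {sizes}")

    def group_sizes(self) -> dict[int, int]:
        sizes = {0: 0, 1: 0}
        for g in self.assignment.values():
            sizes[g] += 1
        return sizes

    def samples_in_group(self, group: int) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignment]
        if missing:
            raise ExpressionParseError(f"samples without labels: {missing}")

    def vector_for(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[s] for s in sample_ids], dtype=int)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    # single-column header (one sample); fall back to tab
    return "\t"


def read_expression_matrix(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a delimited gene × sample table.

    First row holds sample ids, first column gene ids.  The delimiter is
    auto-detected among tab/comma when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ExpressionParseError(f"empty file: {path}")
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ExpressionParseError(f"malformed table in {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionParseError(f"no data rows/columns in {path}")
    # ragged rows: pandas pads short rows with NaN instead of erroring
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ExpressionParseError(
                    f"missing value at line {i + 2} (gene {gene_ids[i]!r}), "
                    f"column {sample_ids[j]!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ExpressionParseError(
                    f"non-numeric cell {cell!r} at line {i + 2} "
                    f"(gene {gene_ids[i]!r}), column {sample_ids[j]!r}"
                ) from exc
    logger.info("read expression matrix %s: %d genes x %d samples", path, *values.shape)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def read_group_labels(path: str | Path) -> GroupLabels:
    """Read a two-column ``sample_id, group`` file.

    Numeric codes must be 0/1; otherwise exactly two string levels are
    accepted and coerced (first level alphabetically → 0), with the mapping
    recorded on the result and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionParseError(f"label file {path} needs two columns")
    # tolerate an optional header line
    first = str(df.iloc[0, 0]).lower()
    if first in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    samples = [str(s).strip() for s in df.iloc[:, 0]]
    codes_raw = [str(c).strip() for c in df.iloc[:, 1]]
    dup = _duplicates(samples)
    if dup:
        raise ExpressionParseError(f"duplicate samples in label file: {sorted(dup)}")
    level_map: dict[str, int] = {}
    levels = sorted(set(codes_raw), key=str.lower)
    if set(levels) <= {"0", "1"}:
        codes = [int(c) for c in codes_raw]
    elif len(levels) == 2:
        control_words = {"control", "ctrl", "healthy", "normal", "wt", "reference"}
        if levels[1].lower() in control_words and levels[0].lower() not in control_words:
            levels = [levels[1], levels[0]]
        level_map = {levels[0]: 0, levels[1]: 1}
        logger.info("coerced group levels: %s", level_map)
        codes = [level_map[c] for c in codes_raw]
    else:
        raise ExpressionParseError(
            f"group codes must be 0/1 or exactly two string levels, got {levels}"
        )
    labels = GroupLabels(dict(zip(samples, codes)), level_map)
    logger.info("group sizes: %s", labels.group_sizes())
    return labels


def write_group_labels(labels: GroupLabels, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for s, g in labels.assignment.items():
            fh.write(f"{s}{delimiter}{g}\n")


#: matrices whose maximum exceeds this are assumed to be raw (unlogged) intensities
UNLOGGED_MAX = 50.0


def normalize_log2(matrix: ExpressionMatrix, mode: str = "auto") -> ExpressionMatrix:
    """Apply ``x -> log2(x + 1)`` depending on *mode*.

    ``auto`` transforms only when ``max(values) > 50`` (log2 microarray data
    rarely exceed ~20); ``force`` always transforms; ``off`` never does.
    """
    if mode not in ("auto", "force", "off"):
        raise ValueError(f"mode must be auto|force|off, got {mode!r}")
    if mode == "off":
        logger.info("normalize_log2: mode=off, values unchanged")
        return matrix
    if mode == "auto" and matrix.values.max() <= UNLOGGED_MAX:
        logger.info(
            "normalize_log2: max %.3g <= %.0f, treating data as already log2",
            matrix.values.max(), UNLOGGED_MAX,
        )
        return matrix
    if matrix.values.min() <= -1:
        raise ValueError(
            f"log2(x+1) undefined: minimum value {matrix.values.min():.4g} <= -1"
        )
    logger.info("normalize_log2: applying log2(x+1) (mode=%s)", mode)
    # log1p keeps the map strictly monotone even for values near zero
    return ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids),
        np.log1p(matrix.values) / np.log(2.0),
    )
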