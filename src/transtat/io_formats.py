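"""CSV readers/writers and the typed containers they produce.

File conventions:

* expression matrix — genes in rows, samples in columns, header row holds
  sample names, first column holds gene names;
* gene lengths — two columns (gene, length in bp), header optional;
* control genes — one gene name per line, optional header;
* metadata — two columns (sample, condition), header optional;
* DE table — three columns (gene, log2 fold change, p-value), header optional.

Gene and sample names are whitespace-trimmed and matched case-sensitively.
Parsing is locale-independent: decimal point only, no thousands separators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from transtat.exceptions import ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneLengthTable",
    "ControlGeneSet",
    "SampleMetadata",
    "DETable",
    "read_expression_matrix",
    "read_gene_lengths",
    "read_control_genes",
    "read_metadata",
    "read_de_table",
    "write_matrix",
    "write_table",
]


def _find_duplicates(labels) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in labels:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative expression values.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene labels (one per row).
    sample_ids
        Ordered, unique sample labels (one per column).
    values
        Non-negative, finite float array of shape ``(len(gene_ids),
        len(sample_ids))``.
    is_raw_counts
        True when the matrix holds raw (integer) read counts.  Auto-detected
        at read time but overridable, because normalized data can be
        integer-valued by coincidence.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    is_raw_counts: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must form a 2-D matrix")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids):
            raise ValidationError(
                f"row count {n_g} does not match {len(self.gene_ids)} gene ids"
            )
        if n_s != len(self.sample_ids):
            raise ValidationError(
                f"column count {n_s} does not match {len(self.sample_ids)} sample ids"
            )
        dup_g = _find_duplicates(self.gene_ids)
        if dup_g:
            raise ValidationError(f"duplicate gene names: {', '.join(dup_g)}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample names: {', '.join(dup_s)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, is_raw_counts: bool = False) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            is_raw_counts=is_raw_counts,
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id: {sample_id!r}") from None

    def sample_values(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample_id)]


@dataclass
class GeneLengthTable:
    """Mapping from gene id to transcript length in base pairs (> 0)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for gene, length in self.lengths.items():
            gene = str(gene).strip()
            if float(length) != int(length) or int(length) <= 0:
                raise ValidationError(
                    f"gene length must be a positive integer; got {length!r} for {gene!r}"
                )
            clean[gene] = int(length)
        self.lengths = clean

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths

    def __getitem__(self, gene: str) -> int:
        try:
            return self.lengths[gene]
        except KeyError:
            raise ValidationError(f"gene {gene!r} absent from length table") from None

    def lengths_for(self, gene_ids: list[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.lengths]
        if missing:
            shown = ", ".join(missing[:10])
            more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
            raise ValidationError(f"genes missing from length table: {shown}{more}")
        return np.array([self.lengths[g] for g in gene_ids], dtype=float)


@dataclass
class ControlGeneSet:
    """Negative-control genes assumed stably expressed across conditions."""

    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = {str(g).strip() for g in self.genes}
        if not self.genes:
            raise ValidationError("control gene set must be non-empty")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = sorted(self.genes - set(matrix.gene_ids))
        if missing:
            raise ValidationError(
                f"control genes absent from matrix: {', '.join(missing[:10])}"
            )


@dataclass
class SampleMetadata:
    """Mapping from sample id to experimental-condition label."""

    conditions: dict[str, str]

    def __post_init__(self) -> None:
        self.conditions = {
            str(k).strip(): str(v).strip() for k, v in self.conditions.items()
        }
        if not self.conditions:
            raise ValidationError("metadata must contain at least one sample")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.conditions]
        if missing:
            raise ValidationError(
                f"metadata missing samples present in matrix: {', '.join(missing)}"
            )

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]


@dataclass
class DETable:
    """Externally produced differential-expression results.

    One record per gene: log2 fold change (any real) and p-value in [0, 1].
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        expected = ["gene", "log2fc", "pvalue"]
        if list(df.columns) != expected:
            raise ValidationError(f"DE table columns must be {expected}")
        df["gene"] = df["gene"].astype(str).str.strip()
        dups = _find_duplicates(df["gene"])
        if dups:
            raise ValidationError(f"duplicate genes in DE table: {', '.join(dups)}")
        pv = df["pvalue"].to_numpy(dtype=float)
        if np.any(~np.isfinite(pv)) or np.any(pv < 0) or np.any(pv > 1):
            raise ValidationError("DE table p-values must lie within [0, 1]")
        if np.any(~np.isfinite(df["log2fc"].to_numpy(dtype=float))):
            raise ValidationError("DE table log2 fold changes must be finite")
        self.table = df.reset_index(drop=True)


def _is_number(text: str) -> bool:
    try:
        float(text)
    except (TypeError, ValueError):
        return False
    return True


def read_expression_matrix(
    path: str | Path,
    delimiter: str = ",",
    is_raw_counts: bool | None = None,
) -> ExpressionMatrix:
    """Read a genes-by-samples CSV matrix.

    ``is_raw_counts=None`` infers the flag: True iff every value is a
    non-negative integer.  Pass an explicit boolean to override.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValidationError(f"no sample columns found in {path}")
    gene_ids = [str(g).strip() for g in df.index]
    sample_ids = [str(c).strip() for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValidationError(
                    f"empty cell at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            text = str(cell).strip()
            if not _is_number(text):
                raise ValidationError(
                    f"non-numeric value {text!r} at gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            values[i, j] = float(text)
    if is_raw_counts is None:
        is_raw_counts = bool(
            np.all(values >= 0) and np.all(values == np.floor(values))
        )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        is_raw_counts=is_raw_counts,
    )


def read_gene_lengths(path: str | Path, delimiter: str = ",") -> GeneLengthTable:
    """Read a two-column (gene, length-in-bp) CSV; header row optional.

    A header is detected by a non-numeric second field on the first row.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"gene length file must have 2 columns, got {df.shape[1]}")
    if len(df) and not _is_number(str(df.iloc[0, 1]).strip()):
        df = df.iloc[1:]
    if df.empty:
        raise ValidationError("gene length file contains no data rows")
    lengths: dict[str, int] = {}
    for _, (gene, raw_len) in df.iterrows():
        gene = str(gene).strip()
        text = str(raw_len).strip()
        if not _is_number(text):
            raise ValidationError(f"non-numeric length {text!r} for gene {gene!r}")
        if gene in lengths:
            raise ValidationError(f"duplicate gene in length table: {gene!r}")
        lengths[gene] = float(text)  # type: ignore[assignment]
    return GeneLengthTable(lengths=lengths)


_CONTROL_HEADERS = {"gene", "genes", "gene_id", "control", "controls", "control_genes"}


def read_control_genes(path: str | Path) -> ControlGeneSet:
    """Read a one-column file of negative-control gene names.

    A first line matching a common header word (``gene``, ``controls``, ...)
    is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and lines[0].lower() in _CONTROL_HEADERS:
        lines = lines[1:]
    if not lines:
        raise ValidationError("control gene file contains no gene names")
    return ControlGeneSet(genes=set(lines))


def read_metadata(path: str | Path, delimiter: str = ",") -> SampleMetadata:
    """Read a two-column (sample, condition) CSV; header row optional."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"metadata file must have 2 columns, got {df.shape[1]}")
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if first == ["sample", "condition"]:
        df = df.iloc[1:]
    if df.empty:
        raise ValidationError("metadata file contains no data rows")
    conditions: dict[str, str] = {}
    for _, (sample, cond) in df.iterrows():
        sample = str(sample).strip()
        if sample in conditions:
            raise ValidationError(f"duplicate sample in metadata: {sample!r}")
        conditions[sample] = str(cond).strip()
    return SampleMetadata(conditions=conditions)


def read_de_table(path: str | Path, delimiter: str = ",") -> DETable:
    """Read a three-column (gene, log2fc, pvalue) CSV; header row optional."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if df.shape[1] != 3:
        raise ValidationError(f"DE table must have 3 columns, got {df.shape[1]}")
    row0 = [str(x).strip() for x in df.iloc[0]]
    if not (_is_number(row0[1]) and _is_number(row0[2])):
        df = df.iloc[1:]
    if df.empty:
        raise ValidationError("DE table contains no data rows")
    out = pd.DataFrame(
        {
            "gene": df.iloc[:, 0].astype(str).str.strip(),
            "log2fc": pd.to_numeric(df.iloc[:, 1], errors="coerce"),
            "pvalue": pd.to_numeric(df.iloc[:, 2], errors="coerce"),
        }
    )
    if out[["log2fc", "pvalue"]].isna().any().any():
        bad = out[out[["log2fc", "pvalue"]].isna().any(axis=1)]["gene"].iloc[0]
        raise ValidationError(f"non-numeric DE value for gene {bad!r}")
    return DETable(table=out)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write an expression matrix to CSV (round-trips with the reader)."""
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValidationError("refusing to write an empty matrix")
    path = Path(path)
    try:
        matrix.to_frame().to_csv(path, sep=delimiter, index_label="gene")
    except OSError as exc:
        raise ValidationError(f"cannot write to {path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a result table to CSV without the index."""
    if df.empty:
        raise ValidationError("refusing to write an empty table")
    path = Path(path)
    try:
        df.to_csv(path, sep=delimiter, index=False)
    except OSError as exc:
        raise ValidationError(f"cannot write to {path}: {exc}") from exc
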