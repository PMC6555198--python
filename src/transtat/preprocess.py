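"""Low-expression filtering, normalization schemes, and RLE QC profiles.

Normalization methods operating on raw counts:

* FPKM / RPKM — counts scaled by gene length (kb) and library size (millions);
* TPM — length-normalized rates rescaled so every column sums to 1e6;
* upper quartile — each column divided by its 75th percentile over genes that
  are not zero in every sample, then rescaled by the mean of those
  percentiles so magnitudes stay count-like;
* RUV — control-gene factor analysis on log counts; the top-k singular
  factors of the row-centered control submatrix are regressed out of every
  gene.

Percentiles use linear interpolation between order statistics throughout, so
results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from transtat.exceptions import ValidationError
from transtat.io_formats import ControlGeneSet, ExpressionMatrix, GeneLengthTable

__all__ = [
    "FilterSpec",
    "FilterResult",
    "RLEProfile",
    "filter_low_expression",
    "normalize_fpkm",
    "normalize_rpkm",
    "normalize_tpm",
    "normalize_upper_quartile",
    "normalize_ruv",
    "rle_profile",
]


@dataclass(frozen=True)
class FilterSpec:
    """Keep genes with value strictly above ``min_value`` in at least
    ``min_samples`` samples."""

    min_value: float
    min_samples: int

    def __post_init__(self) -> None:
        if self.min_value < 0:
            raise ValidationError("min_value must be >= 0")
        if self.min_samples < 1:
            raise ValidationError("min_samples must be >= 1")


@dataclass
class FilterResult:
    matrix: ExpressionMatrix
    n_removed: int
    removed_genes: list[str]


@dataclass
class RLEProfile:
    """Per-sample relative-log-expression values for QC boxplots.

    ``values[g, s]`` is log(x[g, s] + pseudocount) minus the across-sample
    median of that gene's log values; ``summary`` holds per-sample quartiles.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray = field(repr=False)
    summary: pd.DataFrame = field(repr=False)
    pseudocount: float = 1.0


def filter_low_expression(matrix: ExpressionMatrix, spec: FilterSpec) -> FilterResult:
    """Drop genes not strictly exceeding the threshold in enough samples."""
    if spec.min_samples > matrix.n_samples:
        raise ValidationError(
            f"min_samples={spec.min_samples} exceeds sample count {matrix.n_samples}"
        )
    keep = (matrix.values > spec.min_value).sum(axis=1) >= spec.min_samples
    if not keep.any():
        raise ValidationError("filter removed all genes")
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    out = ExpressionMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[keep],
        is_raw_counts=matrix.is_raw_counts,
    )
    return FilterResult(matrix=out, n_removed=len(removed), removed_genes=removed)


def _require_raw(matrix: ExpressionMatrix, method: str) -> None:
    if not matrix.is_raw_counts:
        raise ValidationError(f"{method} normalization requires raw counts")


def normalize_fpkm(matrix: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """FPKM: count * 1e9 / (column_sum * gene_length_bp)."""
    _require_raw(matrix, "FPKM")
    length_bp = lengths.lengths_for(matrix.gene_ids)
    colsum = matrix.values.sum(axis=0)
    if np.any(colsum == 0):
        bad = [s for s, c in zip(matrix.sample_ids, colsum) if c == 0]
        raise ValidationError(f"zero column sum for samples: {', '.join(bad)}")
    fpkm = matrix.values * 1e9 / (colsum[None, :] * length_bp[:, None])
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=fpkm,
        is_raw_counts=False,
    )


# RPKM is arithmetically identical to FPKM for the count matrices handled here.
normalize_rpkm = normalize_fpkm


def normalize_tpm(matrix: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """TPM: length-normalized rates rescaled so each column sums to 1e6."""
    _require_raw(matrix, "TPM")
    length_bp = lengths.lengths_for(matrix.gene_ids)
    rates = matrix.values / length_bp[:, None]
    rate_sum = rates.sum(axis=0)
    if np.any(rate_sum == 0):
        bad = [s for s, c in zip(matrix.sample_ids, rate_sum) if c == 0]
        raise ValidationError(f"all-zero column(s), TPM undefined: {', '.join(bad)}")
    tpm = 1e6 * rates / rate_sum[None, :]
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=tpm,
        is_raw_counts=False,
    )


def normalize_upper_quartile(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Bullard-style upper-quartile scaling.

    Genes that are zero in every sample are excluded from the quartile
    computation (but kept in the output as zeros).  Each column is divided by
    its 75th percentile of remaining counts, then multiplied by the mean of
    the per-column 75th percentiles.
    """
    _require_raw(matrix, "upper quartile")
    nonzero = matrix.values.sum(axis=1) > 0
    if not nonzero.any():
        raise ValidationError("matrix has no nonzero genes")
    q75 = np.percentile(matrix.values[nonzero], 75, axis=0)
    if np.any(q75 == 0):
        bad = [s for s, q in zip(matrix.sample_ids, q75) if q == 0]
        raise ValidationError(f"75th percentile is 0 for samples: {', '.join(bad)}")
    scaled = matrix.values / q75[None, :] * q75.mean()
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=scaled,
        is_raw_counts=False,
    )


def normalize_ruv(
    matrix: ExpressionMatrix,
    controls: ControlGeneSet,
    k: int = 1,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Remove unwanted variation using negative-control genes (RUVg-style).

    On log(count + pseudocount): the top-``k`` right singular vectors of the
    row-centered control-gene submatrix estimate sample-wise unwanted
    factors; every gene's (row-centered) log profile is projected onto those
    factors and the fitted component subtracted.  Values are exponentiated
    back, the pseudocount removed, and floored at 0.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= matrix.n_samples:
        raise ValidationError(
            f"k={k} must be smaller than the number of samples ({matrix.n_samples})"
        )
    controls.validate_against(matrix)
    control_idx = [i for i, g in enumerate(matrix.gene_ids) if g in controls.genes]
    if len(control_idx) < k:
        raise ValidationError(
            f"need at least k={k} control genes, got {len(control_idx)}"
        )
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")

    log_all = np.log(matrix.values + pseudocount)
    log_ctrl = log_all[control_idx]
    ctrl_centered = log_ctrl - log_ctrl.mean(axis=1, keepdims=True)
    # Right singular vectors span sample space: columns of W are the factors.
    _, s, vt = np.linalg.svd(ctrl_centered, full_matrices=False)
    # A vanishing singular value means no detectable unwanted variation along
    # that direction (e.g. perfectly stable controls); removing an arbitrary
    # null direction would corrupt the data, so such factors are skipped.
    tol = s[0] * max(ctrl_centered.shape) * np.finfo(float).eps if s.size else 0.0
    effective_k = min(k, int(np.sum(s > tol)))
    w = vt[:effective_k].T  # samples x k_eff, orthonormal columns
    if effective_k == 0:
        return ExpressionMatrix(
            gene_ids=list(matrix.gene_ids),
            sample_ids=list(matrix.sample_ids),
            values=matrix.values.copy(),
            is_raw_counts=False,
        )

    centered = log_all - log_all.mean(axis=1, keepdims=True)
    beta = centered @ w  # genes x k
    cleaned_log = log_all - beta @ w.T
    cleaned = np.maximum(np.exp(cleaned_log) - pseudocount, 0.0)
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=cleaned,
        is_raw_counts=False,
    )


def rle_profile(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> RLEProfile:
    """Relative log expression: per-gene log ratios to the gene's median."""
    if matrix.n_samples < 2:
        raise ValidationError("RLE requires at least 2 samples")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    logs = np.log(matrix.values + pseudocount)
    rle = logs - np.median(logs, axis=1, keepdims=True)
    qs = np.percentile(rle, [0, 25, 50, 75, 100], axis=0)
    summary = pd.DataFrame(
        {
            "sample": matrix.sample_ids,
            "min": qs[0],
            "q25": qs[1],
            "median": qs[2],
            "q75": qs[3],
            "max": qs[4],
        }
    )
    return RLEProfile(
        sample_ids=list(matrix.sample_ids),
        gene_ids=list(matrix.gene_ids),
        values=rle,
        summary=summary,
        pseudocount=pseudocount,
    )
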