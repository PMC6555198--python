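"""Pairwise scatter tables and Pearson/Spearman correlation matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from transtat.exceptions import ValidationError
from transtat.io_formats import ExpressionMatrix

__all__ = ["CorrelationMatrix", "scatter_pairs", "correlation_matrix"]


@dataclass
class CorrelationMatrix:
    """Symmetric sample-by-sample matrix of correlation coefficients.

    Entries involving a zero-variance sample under Pearson are NaN (recorded
    as missing, never silently zero); the diagonal is exactly 1 elsewhere.
    """

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)
    method: str = "pearson"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def scatter_pairs(
    matrix: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    log_transform: bool = False,
) -> pd.DataFrame:
    """One row per gene with the two samples' values; optional log10(x+1).

    Columns are ``gene``, ``value_a``, ``value_b``; the requested sample ids
    are stored in ``DataFrame.attrs`` (a sample may be paired with itself).
    """
    a = matrix.sample_values(sample_a)
    b = matrix.sample_values(sample_b)
    if log_transform:
        a = np.log10(a + 1.0)
        b = np.log10(b + 1.0)
    df = pd.DataFrame({"gene": matrix.gene_ids, "value_a": a, "value_b": b})
    df.attrs["sample_a"] = sample_a
    df.attrs["sample_b"] = sample_b
    return df


def correlation_matrix(matrix: ExpressionMatrix, method: str = "pearson") -> CorrelationMatrix:
    """All pairwise sample correlations.

    Spearman is computed on mid-ranks (average ranks for ties), i.e. it
    equals Pearson applied to the rank-transformed columns.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method: {method!r}")
    if matrix.n_samples < 2:
        raise ValidationError("correlation requires at least 2 samples")
    if matrix.n_genes < 3:
        raise ValidationError("correlation requires at least 3 genes")
    data = matrix.values
    if method == "spearman":
        data = np.apply_along_axis(stats.rankdata, 0, data)

    n = matrix.n_samples
    centered = data - data.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0, ddof=0)
    out = np.full((n, n), np.nan)
    zero_var = sd == 0
    if zero_var.any():
        bad = [s for s, z in zip(matrix.sample_ids, zero_var) if z]
        warnings.warn(
            f"zero-variance sample(s) {', '.join(bad)}: correlation undefined, "
            "recorded as missing",
            stacklevel=2,
        )
    ok = ~zero_var
    sub = centered[:, ok] / sd[ok]
    corr = (sub.T @ sub) / matrix.n_genes
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    out[np.ix_(ok, ok)] = corr
    return CorrelationMatrix(sample_ids=list(matrix.sample_ids), values=out, method=method)
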