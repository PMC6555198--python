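"""Shannon entropy via Doane-rule binning and the CV-squared noise matrix.

Noise between a pair of samples is the squared coefficient of variation of
each gene's two values — population variance over squared mean — averaged
over genes.  The population (divide-by-2) convention makes CV^2 of the pair
(x, 3x) exactly 0.25; the sample convention would double every value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from transtat.exceptions import ValidationError
from transtat.io_formats import ExpressionMatrix

__all__ = [
    "EntropyResult",
    "NoiseMatrix",
    "doane_bins",
    "shannon_entropy",
    "noise_matrix",
    "pair_cv2",
]


@dataclass
class EntropyResult:
    sample_id: str
    entropy_bits: float
    n_bins: int
    bin_edges: np.ndarray = field(repr=False)
    log_transform: bool = True


@dataclass
class NoiseMatrix:
    """Symmetric sample-pair matrix of mean per-gene CV^2.

    ``genes_used[i, j]`` counts genes included for the pair (genes whose two
    values are both zero are excluded).  An entry with no usable genes is NaN.
    """

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)
    genes_used: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def doane_bins(values) -> int:
    """Doane's histogram bin-count rule.

    ceil(1 + log2(n) + log2(1 + |g1| / sigma_g1)) where g1 is the sample
    skewness and sigma_g1 = sqrt(6(n-2) / ((n+1)(n+3))).
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValidationError("Doane's rule requires n >= 3 (skewness undefined)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        g1 = stats.skew(x, bias=True)
    if not np.isfinite(g1):  # constant input has undefined skewness
        g1 = 0.0
    sigma_g1 = math.sqrt(6.0 * (n - 2) / ((n + 1) * (n + 3)))
    return int(math.ceil(1.0 + math.log2(n) + math.log2(1.0 + abs(g1) / sigma_g1)))


def shannon_entropy(
    matrix: ExpressionMatrix,
    sample_id: str,
    log_transform: bool = True,
) -> EntropyResult:
    """Entropy (bits) of one sample's expression histogram over Doane bins.

    Bin edges span [min, max] with equal widths (right-closed last bin);
    H = -sum p_i log2 p_i over non-empty bins.  Defaults to log10(x+1)
    transformation first, since raw expression spans decades.
    """
    if matrix.n_genes < 3:
        raise ValidationError("entropy requires at least 3 genes")
    x = matrix.sample_values(sample_id).astype(float)
    if log_transform:
        x = np.log10(x + 1.0)
    if np.all(x == x[0]):
        warnings.warn(
            f"sample {sample_id!r} is constant; entropy is 0 over a single bin",
            stacklevel=2,
        )
        return EntropyResult(
            sample_id=sample_id,
            entropy_bits=0.0,
            n_bins=1,
            bin_edges=np.array([x[0], x[0]]),
            log_transform=log_transform,
        )
    n_bins = doane_bins(x)
    counts, edges = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return EntropyResult(
        sample_id=sample_id,
        entropy_bits=entropy,
        n_bins=n_bins,
        bin_edges=edges,
        log_transform=log_transform,
    )


def pair_cv2(matrix: ExpressionMatrix, sample_a: str, sample_b: str):
    """Per-gene CV^2 between two samples.

    Returns (gene_ids_included, cv2_values); genes whose pair mean is zero
    are excluded.  For values (a, b): CV^2 = (a - b)^2 / (a + b)^2.
    """
    a = matrix.sample_values(sample_a)
    b = matrix.sample_values(sample_b)
    mean = (a + b) / 2.0
    include = mean > 0
    genes = [g for g, inc in zip(matrix.gene_ids, include) if inc]
    a, b = a[include], b[include]
    # population variance of two points: ((a-m)^2 + (b-m)^2)/2 = (a-b)^2/4
    cv2 = (a - b) ** 2 / (a + b) ** 2
    return genes, cv2


def noise_matrix(matrix: ExpressionMatrix) -> NoiseMatrix:
    """Mean per-gene CV^2 for every unordered sample pair; diagonal 0."""
    if matrix.n_samples < 2:
        raise ValidationError("noise matrix requires at least 2 samples")
    n = matrix.n_samples
    values = np.zeros((n, n))
    genes_used = np.zeros((n, n), dtype=int)
    np.fill_diagonal(genes_used, matrix.n_genes)
    for i in range(n):
        for j in range(i + 1, n):
            genes, cv2 = pair_cv2(matrix, matrix.sample_ids[i], matrix.sample_ids[j])
            genes_used[i, j] = genes_used[j, i] = len(genes)
            if len(genes) == 0:
                warnings.warn(
                    f"all genes excluded for pair ({matrix.sample_ids[i]}, "
                    f"{matrix.sample_ids[j]}); entry is missing",
                    stacklevel=2,
                )
                values[i, j] = values[j, i] = np.nan
            else:
                values[i, j] = values[j, i] = float(cv2.mean())
    return NoiseMatrix(
        sample_ids=list(matrix.sample_ids), values=values, genes_used=genes_used
    )
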