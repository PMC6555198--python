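"""PCA over samples and seeded k-means clustering.

Samples are the observations and genes the variables: each sample becomes a
point in gene space, which is what the exploratory plots show.  Default PCA
preprocessing is log10(x+1) followed by gene-wise centering; unit-variance
scaling is optional because raw magnitudes would otherwise be dominated by a
handful of highly expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from transtat.exceptions import ValidationError
from transtat.io_formats import ExpressionMatrix

__all__ = ["PCAResult", "KMeansResult", "pca", "kmeans"]


@dataclass
class PCAResult:
    sample_ids: list[str]
    gene_ids: list[str]
    scores: np.ndarray = field(repr=False)  # samples x components
    loadings: np.ndarray = field(repr=False)  # genes x components
    explained_variance: np.ndarray = field(repr=False)
    variance_fractions: np.ndarray = field(repr=False)
    processed: np.ndarray = field(repr=False)  # centered (scaled/logged) samples x genes

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class KMeansResult:
    k: int
    ids: list[str]
    labels: np.ndarray
    centroids: np.ndarray = field(repr=False)
    wcss: float = 0.0


def pca(
    matrix: ExpressionMatrix,
    log_transform: bool = True,
    scale: bool = False,
) -> PCAResult:
    """Principal components of samples-as-observations.

    Retains min(n_samples - 1, n_genes) components; variance fractions are
    non-negative, non-increasing, and sum to 1.
    """
    if matrix.n_samples < 2:
        raise ValidationError("PCA requires at least 2 samples")
    x = matrix.values.T.astype(float)  # samples x genes
    if np.all(x == x[0:1]):
        raise ValidationError("matrix is constant across samples; PCA undefined")
    gene_ids = list(matrix.gene_ids)
    if log_transform:
        x = np.log10(x + 1.0)
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
    if not np.any(x != 0):
        raise ValidationError("matrix is constant after preprocessing; PCA undefined")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_comp = min(matrix.n_samples - 1, len(gene_ids))
    ev = s**2 / (matrix.n_samples - 1)
    total = ev.sum()
    return PCAResult(
        sample_ids=list(matrix.sample_ids),
        gene_ids=gene_ids,
        scores=u[:, :n_comp] * s[:n_comp],
        loadings=vt[:n_comp].T,
        explained_variance=ev[:n_comp],
        variance_fractions=ev[:n_comp] / total,
        processed=x,
    )


def kmeans(
    data: np.ndarray,
    k: int,
    seed: int,
    n_restarts: int = 25,
    ids: list[str] | None = None,
) -> KMeansResult:
    """Lloyd k-means, best of ``n_restarts`` seeded runs by within-cluster
    sum of squares; deterministic for a given seed."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("kmeans expects a 2-D array (observations x features)")
    n_obs = data.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n_obs)]
    if len(ids) != n_obs:
        raise ValidationError("ids length does not match number of observations")
    if not 2 <= k <= n_obs:
        raise ValidationError(f"k must satisfy 2 <= k <= {n_obs}, got {k}")
    model = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(data)
    return KMeansResult(
        k=k,
        ids=list(ids),
        labels=model.labels_.astype(int),
        centroids=model.cluster_centers_,
        wcss=float(model.inertia_),
    )
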