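"""Gene selection, z-score scaling, Ward clustering with heatmap layout, and
volcano-plot categorization.

Scaling standardizes each gene's row to mean 0 and standard deviation 1
(n-1 convention).  Ward clustering uses Euclidean distances with the
Lance-Williams update on squared distances ("Ward.D2"-equivalent), i.e. the
scipy ``linkage(method="ward")`` convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from transtat.exceptions import ValidationError
from transtat.io_formats import DETable, ExpressionMatrix, SampleMetadata

__all__ = [
    "ScaledMatrix",
    "ClusteringResult",
    "HeatmapLayout",
    "VolcanoTable",
    "select_by_fold_change",
    "zscale",
    "ward_cluster",
    "heatmap_layout",
    "volcano_categorize",
]

_P_FLOOR = 1e-300  # underflow floor for -log10(p)


@dataclass
class ScaledMatrix:
    """Row-standardized expression (each gene: mean 0, sd 1, n-1 convention).

    ``row_means``/``row_sds`` record the scaling provenance; genes whose
    across-sample standard deviation was zero are dropped and listed in
    ``dropped_genes``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)
    row_means: np.ndarray = field(repr=False)
    row_sds: np.ndarray = field(repr=False)
    dropped_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClusteringResult:
    """Ward dendrogram cut into ``n_clusters`` gene clusters."""

    gene_ids: list[str]
    linkage: np.ndarray = field(repr=False)  # scipy linkage matrix
    n_clusters: int = 2
    labels: np.ndarray = field(default=None, repr=False)  # 1-based cluster ids
    leaf_order: list[int] = field(default_factory=list)
    clusters: dict[int, list[str]] = field(default_factory=dict)


@dataclass
class HeatmapLayout:
    """Plot-ready matrix with rows in dendrogram leaf order."""

    matrix: pd.DataFrame = field(repr=False)
    gene_order: list[str] = field(default_factory=list)
    sample_order: list[str] = field(default_factory=list)
    gene_linkage: np.ndarray = field(default=None, repr=False)
    sample_linkage: np.ndarray | None = field(default=None, repr=False)
    cluster_of: dict[str, int] = field(default_factory=dict)


@dataclass
class VolcanoTable:
    """Per-gene volcano coordinates and significance category."""

    table: pd.DataFrame = field(repr=False)
    p_threshold: float = 0.05
    fc_threshold: float = 1.0


def select_by_fold_change(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    cond_a: str,
    cond_b: str,
    min_fold: float,
    pseudocount: float = 1.0,
) -> list[str]:
    """Genes whose (pseudocounted) mean-expression fold change between the
    two conditions is >= min_fold or <= 1/min_fold."""
    if min_fold < 1:
        raise ValidationError("min_fold must be >= 1")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    metadata.validate_against(matrix)
    idx_a = [matrix.sample_index(s) for s in metadata.samples_for(cond_a) if s in matrix.sample_ids]
    idx_b = [matrix.sample_index(s) for s in metadata.samples_for(cond_b) if s in matrix.sample_ids]
    if not idx_a:
        raise ValidationError(f"condition {cond_a!r} has no samples in the matrix")
    if not idx_b:
        raise ValidationError(f"condition {cond_b!r} has no samples in the matrix")
    mean_a = matrix.values[:, idx_a].mean(axis=1) + pseudocount
    mean_b = matrix.values[:, idx_b].mean(axis=1) + pseudocount
    if pseudocount == 0 and (np.any(mean_a == 0) or np.any(mean_b == 0)):
        raise ValidationError("zero condition mean with pseudocount 0; fold undefined")
    fold = mean_b / mean_a
    keep = (fold >= min_fold) | (fold <= 1.0 / min_fold)
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def zscale(matrix: ExpressionMatrix) -> ScaledMatrix:
    """Standardize each gene row: Z = (x - row mean) / row sd (ddof=1).

    Zero-variance genes cannot be scaled; they are dropped and reported.
    """
    if matrix.n_samples < 2:
        raise ValidationError("scaling requires at least 2 samples")
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValidationError("all genes have zero variance; nothing to scale")
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} zero-variance gene(s) before scaling",
            stacklevel=2,
        )
    z = (matrix.values[keep] - means[keep, None]) / sds[keep, None]
    return ScaledMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        sample_ids=list(matrix.sample_ids),
        values=z,
        row_means=means[keep],
        row_sds=sds[keep],
        dropped_genes=dropped,
    )


def ward_cluster(scaled: ScaledMatrix, n_clusters: int) -> ClusteringResult:
    """Agglomerate scaled gene rows under Ward's minimum-variance criterion
    and cut the tree into ``n_clusters`` gene clusters."""
    n_genes = len(scaled.gene_ids)
    if n_genes < 2:
        raise ValidationError("clustering requires at least 2 genes")
    if not 2 <= n_clusters <= n_genes:
        raise ValidationError(
            f"n_clusters must satisfy 2 <= k <= {n_genes}, got {n_clusters}"
        )
    z = hierarchy.linkage(scaled.values, method="ward")
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    leaf_order = list(hierarchy.leaves_list(z))
    clusters: dict[int, list[str]] = {}
    for gene, lab in zip(scaled.gene_ids, labels):
        clusters.setdefault(int(lab), []).append(gene)
    return ClusteringResult(
        gene_ids=list(scaled.gene_ids),
        linkage=z,
        n_clusters=n_clusters,
        labels=labels.astype(int),
        leaf_order=leaf_order,
        clusters=clusters,
    )


def heatmap_layout(
    scaled: ScaledMatrix,
    clustering: ClusteringResult,
    cluster_samples: bool = False,
) -> HeatmapLayout:
    """Reorder the scaled matrix by dendrogram leaf order (and optionally
    Ward-order the sample axis) for plotting."""
    if clustering.gene_ids != scaled.gene_ids:
        raise ValidationError("clustering and scaled matrix cover different gene sets")
    gene_order = [scaled.gene_ids[i] for i in clustering.leaf_order]
    values = scaled.values[clustering.leaf_order]
    sample_order = list(scaled.sample_ids)
    sample_linkage = None
    if cluster_samples:
        sample_linkage = hierarchy.linkage(scaled.values.T, method="ward")
        order = list(hierarchy.leaves_list(sample_linkage))
        sample_order = [scaled.sample_ids[i] for i in order]
        values = values[:, order]
    df = pd.DataFrame(values, index=gene_order, columns=sample_order)
    cluster_of = {
        g: int(lab) for g, lab in zip(clustering.gene_ids, clustering.labels)
    }
    return HeatmapLayout(
        matrix=df,
        gene_order=gene_order,
        sample_order=sample_order,
        gene_linkage=clustering.linkage,
        sample_linkage=sample_linkage,
        cluster_of=cluster_of,
    )


def volcano_categorize(
    de: DETable,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
) -> VolcanoTable:
    """Categorize DE-table genes as sig-up / sig-down / not-sig.

    sig-up: p < p_threshold and log2fc >= fc_threshold;
    sig-down: p < p_threshold and log2fc <= -fc_threshold;
    -log10(p) uses an underflow floor (p = 0 maps to the floor, with a
    warning).
    """
    if not 0 < p_threshold < 1:
        raise ValidationError("p_threshold must lie in (0, 1)")
    if fc_threshold < 0:
        raise ValidationError("fc_threshold must be >= 0")
    df = de.table.copy()
    pv = df["pvalue"].to_numpy(dtype=float)
    if np.any(pv == 0):
        warnings.warn(
            f"{int((pv == 0).sum())} zero p-value(s) mapped to floor {_P_FLOOR:g}",
            stacklevel=2,
        )
    df["neg_log10_p"] = -np.log10(np.maximum(pv, _P_FLOOR))
    lfc = df["log2fc"].to_numpy(dtype=float)
    sig = pv < p_threshold
    category = np.where(
        sig & (lfc >= fc_threshold),
        "sig-up",
        np.where(sig & (lfc <= -fc_threshold), "sig-down", "not-sig"),
    )
    df["category"] = category
    return VolcanoTable(table=df, p_threshold=p_threshold, fc_threshold=fc_threshold)
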