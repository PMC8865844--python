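"""Projection of single-nucleus cluster transcriptomes onto spatial data.

Pseudobulk averaging per cluster, marker-restricted Spearman
correlation between nuclei and spatial cluster pseudobulks with
column-then-row scaling and clipping, and per-grid correlation scores
for selected nuclei clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .expression import ExpressionMatrix, MarkerTable

__all__ = [
    "PseudobulkMatrix",
    "CorrelationMap",
    "pseudobulk",
    "map_clusters",
    "grid_scores",
    "linkage_to_newick",
]


@dataclass
class PseudobulkMatrix:
    """Gene × cluster mean expression of a normalized layer."""

    values: pd.DataFrame  # genes x clusters
    n_samples: dict
    source: str  # "nuclei" or "spatial"

    @property
    def clusters(self) -> list:
        return list(self.values.columns)


@dataclass
class CorrelationMap:
    """Nuclei-cluster × spatial-cluster Spearman correlations.

    ``raw`` holds the Spearman matrix; ``scaled`` the z-scaled
    (columns first, then rows) and clipped version.  The nuclei-cluster
    dendrogram is a scipy linkage on (1 - Pearson) distances of the
    scaled rows.
    """

    raw: pd.DataFrame
    scaled: pd.DataFrame
    marker_genes: list
    dendrogram: np.ndarray | None


def pseudobulk(matrix: ExpressionMatrix, clusters) -> PseudobulkMatrix:
    """Arithmetic mean of the normalized layer per (gene, cluster)."""
    if matrix.layer not in ("lognorm", "log2TPM", "scaled"):
        raise ValueError("pseudobulk expects a normalized layer")
    labels = (
        clusters.loc[list(matrix.sample_ids)].to_numpy()
        if isinstance(clusters, pd.Series)
        else np.asarray(clusters)
    )
    if len(labels) != matrix.n_samples:
        raise ValueError("every sample needs a cluster label")
    X = matrix.dense()
    uniq = list(pd.unique(labels))
    cols, n_samples = {}, {}
    for cl in uniq:
        mask = labels == cl
        if not mask.any():
            raise ValueError(f"empty cluster {cl!r}")
        cols[cl] = X[:, mask].mean(axis=1)
        n_samples[cl] = int(mask.sum())
    values = pd.DataFrame(cols, index=matrix.gene_ids)
    return PseudobulkMatrix(values=values, n_samples=n_samples, source="unspecified")


def _zscale(df: pd.DataFrame, axis: int) -> pd.DataFrame:
    """R-style scale() along the given axis (ddof=1); constant slices -> 0."""
    mean = df.mean(axis=axis)
    sd = df.std(axis=axis, ddof=1)
    sd = sd.replace(0.0, np.nan)
    if axis == 0:
        out = (df - mean) / sd
    else:
        out = df.sub(mean, axis=0).div(sd, axis=0)
    return out.fillna(0.0)


def map_clusters(
    nuclei_pb: PseudobulkMatrix,
    spatial_pb: PseudobulkMatrix,
    spatial_markers: MarkerTable,
    top_n: int = 50,
) -> CorrelationMap:
    """Marker-restricted Spearman projection of nuclei onto spatial clusters.

    Restricts both pseudobulks to the union of each spatial cluster's
    ``top_n`` markers (ranked by adjusted then raw p), Spearman-
    correlates every (nuclei cluster, spatial cluster) pair, z-scales
    the matrix by column then by row, clips to [-1, 1], and Ward-
    clusters the nuclei clusters on (1 - Pearson) distances of the
    scaled rows.
    """
    marker_union: list = []
    seen = set()
    shared = set(nuclei_pb.values.index) & set(spatial_pb.values.index)
    for cl in spatial_pb.clusters:
        top = [
            g
            for g in MarkerTable(spatial_markers.table).top_genes(cl, n=len(spatial_markers.table), by="p_adj")
            if g in shared
        ]
        if len(top) < top_n:
            warnings.warn(
                f"spatial cluster {cl!r}: only {len(top)} usable markers (< {top_n})",
                stacklevel=2,
            )
        for g in top[:top_n]:
            if g not in seen:
                seen.add(g)
                marker_union.append(g)
    if not marker_union:
        raise ValueError("no usable marker genes shared between pseudobulks")
    A = nuclei_pb.values.loc[marker_union]
    B = spatial_pb.values.loc[marker_union]
    raw = np.full((A.shape[1], B.shape[1]), np.nan)
    for i, ca in enumerate(A.columns):
        for j, cb in enumerate(B.columns):
            a, b = A[ca].to_numpy(), B[cb].to_numpy()
            if a.std() == 0 or b.std() == 0:
                continue  # flagged as NaN
            raw[i, j] = spearmanr(a, b).statistic
    raw_df = pd.DataFrame(raw, index=A.columns, columns=B.columns)
    scaled = _zscale(_zscale(raw_df, axis=0), axis=1).clip(-1.0, 1.0)
    dendro = None
    if raw_df.shape[0] >= 2:
        rows = scaled.to_numpy()
        sd = rows.std(axis=1)
        if (sd > 0).all():
            d = np.clip(1.0 - np.corrcoef(rows), 0.0, 2.0)
            np.fill_diagonal(d, 0.0)
            dendro = linkage(squareform(d, checks=False), method="ward")
    return CorrelationMap(
        raw=raw_df, scaled=scaled, marker_genes=marker_union, dendrogram=dendro
    )


def grid_scores(
    nuclei_pb: PseudobulkMatrix,
    cluster_id,
    grid_matrix: ExpressionMatrix,
    marker_genes,
) -> pd.Series:
    """Spearman r of one nuclei-cluster pseudobulk against every grid.

    Raw correlations over ``marker_genes``; interpretable as fan or
    network scores depending on the chosen cluster.  Constant grids
    over the marker set yield NaN.
    """
    marker_genes = list(marker_genes)
    if cluster_id not in nuclei_pb.values.columns:
        raise ValueError(f"unknown nuclei cluster {cluster_id!r}")
    missing = [g for g in marker_genes if g not in set(nuclei_pb.values.index)]
    missing += [g for g in marker_genes if g not in set(grid_matrix.gene_ids)]
    if missing:
        raise ValueError(f"marker genes absent: {sorted(set(missing))}")
    ref = nuclei_pb.values.loc[marker_genes, cluster_id].to_numpy()
    G = grid_matrix.subset_genes(np.asarray(marker_genes, dtype=object)).dense()
    out = np.full(grid_matrix.n_samples, np.nan)
    if ref.std() > 0:
        for j in range(G.shape[1]):
            if G[:, j].std() > 0:
                out[j] = spearmanr(ref, G[:, j]).statistic
    return pd.Series(out, index=grid_matrix.sample_ids, name=f"score_{cluster_id}")


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)
    labels = list(labels)

    def _build(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _build(node.left, node.dist)
        right = _build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _build(tree, tree.dist) + ";"
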