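"""Pseudotemporal ordering of a synchronized mitotic wave.

Diffusion-map embedding with a density-normalized Gaussian kernel,
block-wise ranking along a user-supplied group sequence, LOESS-style
smoothed expression trends over the ordering, and the mirrored
pseudospatial ordering of grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .expression import ExpressionMatrix

__all__ = [
    "Ordering",
    "diffusion_map",
    "order_by_groups",
    "expression_trends",
    "pseudospatial_order",
    "loess_window",
]


@dataclass
class Ordering:
    """Block-wise pseudotime ranks (a permutation of 0..n-1)."""

    ranks: pd.Series  # sample_id -> rank
    component_values: pd.Series  # first diffusion component (after orientation)
    group_sequence: list

    def __post_init__(self) -> None:
        r = np.sort(self.ranks.to_numpy())
        if not np.array_equal(r, np.arange(len(r))):
            raise ValueError("ranks must be a permutation of 0..n-1")


def diffusion_map(
    features,
    n_comps: int = 2,
    kernel_sigma: float | str = "local",
    k_local: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Diffusion-map components of a sample × feature matrix.

    A Gaussian kernel on pairwise Euclidean distances (``kernel_sigma=
    "local"`` uses the distance to the ``k_local``-th neighbor per
    sample) is density-normalized (anisotropic, alpha = 1) and row-
    normalized into a transition operator; the top non-trivial right
    eigenvectors are returned with a deterministic sign convention
    (largest-magnitude entry positive).
    """
    X = np.asarray(features, dtype=float)
    ids = (
        np.asarray(features.index, dtype=object)
        if isinstance(features, pd.DataFrame)
        else np.arange(X.shape[0], dtype=object)
    )
    n = X.shape[0]
    if n < n_comps + 1:
        raise ValueError("need at least n_comps + 1 samples")
    D = squareform(pdist(X))
    if kernel_sigma == "local":
        k = min(k_local, n - 1)
        sig = np.sort(D, axis=1)[:, k]
        sig = np.maximum(sig, 1e-12 * max(D.max(), 1.0))
        denom = 2.0 * np.outer(sig, sig)
    else:
        s = float(kernel_sigma)
        if s <= 0:
            raise ValueError("kernel_sigma must be > 0")
        denom = 2.0 * s**2
    W = np.exp(-(D**2) / denom)
    n_comp_graph, labels = connected_components(W > 1e-12, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"kernel graph is disconnected: {n_comp_graph} components with sizes {sizes.tolist()}"
        )
    q = W.sum(axis=1)
    W1 = W / np.outer(q, q)  # alpha = 1 density normalization
    d1 = W1.sum(axis=1)
    A = W1 / np.sqrt(np.outer(d1, d1))  # symmetric conjugate of the transition operator
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    psi = vecs / np.sqrt(d1)[:, None]
    comps = psi[:, 1 : n_comps + 1]
    evals = vals[1 : n_comps + 1]
    # normalize and fix sign
    comps = comps / np.linalg.norm(comps, axis=0)
    for j in range(comps.shape[1]):
        if comps[np.abs(comps[:, j]).argmax(), j] < 0:
            comps[:, j] = -comps[:, j]
    names = [f"DC{i+1}" for i in range(comps.shape[1])]
    return pd.DataFrame(comps, index=ids, columns=names), evals


def order_by_groups(components, group_of_sample: pd.Series, group_sequence) -> Ordering:
    """Rank samples block-by-block along a group sequence.

    Within each block samples are sorted by the first diffusion
    component; the component's global direction is chosen so block
    medians increase along the sequence.  Empty groups in the sequence
    are skipped with a warning.
    """
    if isinstance(components, pd.DataFrame):
        comp = components.iloc[:, 0]
    elif isinstance(components, pd.Series):
        comp = components
    else:
        raise ValueError("components must be a Series or DataFrame indexed by sample")
    group_of_sample = group_of_sample.loc[comp.index]
    groups_present = set(group_of_sample)
    uncovered = groups_present - set(group_sequence)
    if uncovered:
        raise ValueError(f"group_sequence does not cover groups: {sorted(map(str, uncovered))}")
    blocks = []
    for g in group_sequence:
        members = comp.index[group_of_sample == g]
        if len(members) == 0:
            warnings.warn(f"group {g!r} is empty; skipped", stacklevel=2)
            continue
        blocks.append((g, members))
    medians = [float(comp.loc[m].median()) for _, m in blocks]
    c = comp.copy()
    if len(medians) >= 2:
        rho = spearmanr(np.arange(len(medians)), medians).statistic
        if np.isfinite(rho) and rho < 0:
            c = -c
    ranks = {}
    next_rank = 0
    for _, members in blocks:
        ordered = c.loc[members].sort_values(kind="mergesort").index
        for s in ordered:
            ranks[s] = next_rank
            next_rank += 1
    rank_series = pd.Series({s: ranks[s] for s in comp.index}, name="rank")
    return Ordering(
        ranks=rank_series.loc[comp.index],
        component_values=c,
        group_sequence=[g for g, _ in blocks],
    )


def loess_window(span: float, n: int) -> float:
    """Smoothing fraction from a span parameter.

    Spans in (0, 1] are used directly; larger spans are interpreted as
    a bandwidth in rank units and converted to ``max(0.3, span/n)``.
    """
    if span <= 0:
        raise ValueError("span must be > 0")
    return float(span) if span <= 1.0 else max(0.3, span / n)


def expression_trends(
    matrix: ExpressionMatrix, ordering: Ordering, genes, span: float = 10.0
) -> pd.DataFrame:
    """Locally weighted (LOESS) expression trends over pseudotime ranks.

    Returns a rank-indexed frame with one smoothed curve per gene.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in set(matrix.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    n = len(ordering.ranks)
    if n < 10:
        raise ValueError("need at least 10 ordered samples")
    frac = loess_window(span, n)
    if frac * n < 3:
        raise ValueError("span yields smoothing windows of fewer than 3 points")
    order = ordering.ranks.sort_values().index
    ranks = ordering.ranks.loc[order].to_numpy(dtype=float)
    sub = matrix.subset_samples(np.asarray(order, dtype=object))
    X = sub.dense()
    gene_pos = {g: i for i, g in enumerate(sub.gene_ids)}
    curves = {}
    for g in genes:
        y = X[gene_pos[g], :]
        sm = lowess(y, ranks, frac=frac, return_sorted=False)
        curves[g] = sm
    return pd.DataFrame(curves, index=pd.Index(ranks.astype(int), name="rank"))


def pseudospatial_order(
    grid_matrix: ExpressionMatrix,
    grid_clusters: pd.Series,
    marker_genes,
    n_comps: int = 2,
    k_local: int = 10,
) -> Ordering:
    """Diffusion + block ranking applied to grids of a cycling specimen.

    Blocks are the grid clusters ordered by their mean expression of
    ``marker_genes`` (ascending, i.e. late-phase markers define the end
    of the sequence); within blocks grids follow the first diffusion
    component of the full expression matrix.
    """
    marker_genes = list(marker_genes)
    missing = [g for g in marker_genes if g not in set(grid_matrix.gene_ids)]
    if missing:
        raise ValueError(f"marker genes absent: {missing}")
    sub = grid_matrix.subset_genes(np.asarray(marker_genes, dtype=object))
    mean_marker = pd.Series(sub.dense().mean(axis=0), index=grid_matrix.sample_ids)
    labels = grid_clusters.loc[list(grid_matrix.sample_ids)]
    block_means = mean_marker.groupby(labels).mean().sort_values()
    sequence = list(block_means.index)
    comps, _ = diffusion_map(
        pd.DataFrame(grid_matrix.dense().T, index=grid_matrix.sample_ids),
        n_comps=n_comps,
        k_local=k_local,
    )
    return order_by_groups(comps, labels, sequence)
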