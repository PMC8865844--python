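"""Shared expression-matrix machinery.

Normalizations (TPM, thresholded log2-TPM, log-normalization), sample
and gene filters, covariate-regression scaling, PCA, graph and
hierarchical clustering, one-vs-rest Wilcoxon marker detection,
expression-matched gene-set module scores, detected-gene overlaps, and
display-contrast quantiles.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

LAYERS = ("counts", "TPM", "log2TPM", "lognorm", "scaled")

__all__ = [
    "ExpressionMatrix",
    "MarkerTable",
    "ClusterAssignment",
    "tpm_from_counts",
    "log2_tpm_threshold",
    "lognormalize",
    "filter_samples_by_depth",
    "filter_annotated_genes",
    "scale_with_regression",
    "pca",
    "cluster_graph",
    "cluster_hierarchical",
    "rank_markers",
    "wilcoxon_rank_sum",
    "module_score",
    "detected_gene_overlap",
    "feature_contrast_limits",
]


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with a layer tag and sample metadata.

    ``values`` may be dense or scipy-sparse, oriented genes (rows) ×
    samples (columns).  ``sample_meta`` carries per-sample totals,
    detected-gene counts, specimen labels, coordinates and cluster
    labels as available.
    """

    values: np.ndarray | sparse.spmatrix
    layer: str
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=pd.Index(self.sample_ids))
        else:
            self.sample_meta = self.sample_meta.loc[list(self.sample_ids)]
        if self.layer == "counts":
            meta = self.sample_meta
            if "total" not in meta.columns:
                meta["total"] = np.asarray(self.dense().sum(axis=0)).ravel()
            if "n_genes_detected" not in meta.columns:
                meta["n_genes_detected"] = np.asarray((self.dense() > 0).sum(axis=0)).ravel()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def with_values(self, values, layer: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            layer=layer,
            gene_ids=self.gene_ids.copy(),
            sample_ids=self.sample_ids.copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return ExpressionMatrix(
            values=self.values[idx, :],
            layer=self.layer,
            gene_ids=self.gene_ids[idx],
            sample_ids=self.sample_ids.copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return ExpressionMatrix(
            values=self.values[:, idx],
            layer=self.layer,
            gene_ids=self.gene_ids.copy(),
            sample_ids=self.sample_ids[idx],
            sample_meta=self.sample_meta.iloc[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.sample_ids)


@dataclass
class MarkerTable:
    """Per-(gene, cluster) differential-expression results."""

    table: pd.DataFrame  # columns: gene, cluster, statistic, p, p_adj, avg_log_fc, pct_in, pct_out

    def top_genes(self, cluster, n: int, by: str = "p_adj") -> list:
        sub = self.table[self.table["cluster"] == cluster]
        sub = sub.sort_values([by, "p", "gene"], kind="mergesort")
        return list(sub["gene"].head(n))


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample_id -> contiguous integer cluster label from 0
    method: str
    params: dict = field(default_factory=dict)
    linkage: np.ndarray | None = None


def _relabel_contiguous(labels: np.ndarray, sample_ids: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first occurrence by sorted sample id."""
    order = np.argsort(np.asarray(sample_ids, dtype=object).astype(str), kind="mergesort")
    mapping: dict = {}
    for i in order:
        if labels[i] not in mapping:
            mapping[labels[i]] = len(mapping)
    return np.array([mapping[l] for l in labels], dtype=int)


# ---------------------------------------------------------------------------
# normalizations and filters
# ---------------------------------------------------------------------------

def tpm_from_counts(counts: ExpressionMatrix, gene_lengths) -> ExpressionMatrix:
    """Length-normalized transcripts-per-million from raw counts."""
    if counts.layer != "counts":
        raise ValueError("input layer must be 'counts'")
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != counts.n_genes:
        raise ValueError("one gene length per gene required")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.dense() / lengths[:, None]
    total = rate.sum(axis=0)
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise ValueError(f"zero-total sample(s): {list(counts.sample_ids[zero])}")
    return counts.with_values(rate / total * 1e6, "TPM")


def log2_tpm_threshold(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform TPM values > 1; values <= 1 become 0."""
    if tpm.layer != "TPM":
        raise ValueError("input layer must be 'TPM'")
    v = tpm.dense()
    out = np.where(v > 1.0, np.log2(np.maximum(v, 1.0)), 0.0)
    return tpm.with_values(out, "log2TPM")


def lognormalize(counts: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """``x -> ln(1 + scale_factor * x / column_total)`` per sample."""
    if counts.layer != "counts":
        raise ValueError("input layer must be 'counts'")
    v = counts.dense()
    total = v.sum(axis=0)
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise ValueError(f"zero-total sample(s): {list(counts.sample_ids[zero])}")
    return counts.with_values(np.log1p(scale_factor * v / total), "lognorm")


def filter_samples_by_depth(matrix: ExpressionMatrix, rule) -> ExpressionMatrix:
    """Remove samples whose sequencing depth lies outside per-specimen bounds.

    ``rule`` is either a single ``(min, max)`` pair (either bound may be
    None) applied to all samples, or a mapping specimen -> (min, max)
    keyed on the ``specimen`` column of the sample metadata.  Bounds are
    inclusive: samples with ``min <= total <= max`` are kept.
    """
    meta = matrix.sample_meta
    if "total" in meta.columns:
        totals = meta["total"].to_numpy(dtype=float)
    else:
        totals = np.asarray(matrix.dense().sum(axis=0), dtype=float)
    if isinstance(rule, dict):
        if "specimen" not in meta.columns:
            raise ValueError("per-specimen rule requires a 'specimen' metadata column")
        specimens = set(meta["specimen"])
        unknown = set(rule) - specimens
        if unknown:
            raise KeyError(f"rule references unknown specimen(s): {sorted(unknown)}")
        keep = np.ones(matrix.n_samples, dtype=bool)
        for spec, (lo, hi) in rule.items():
            m = (meta["specimen"] == spec).to_numpy()
            if lo is not None:
                keep &= ~m | (totals >= lo)
            if hi is not None:
                keep &= ~m | (totals <= hi)
    else:
        lo, hi = rule
        keep = np.ones(matrix.n_samples, dtype=bool)
        if lo is not None:
            keep &= totals >= lo
        if hi is not None:
            keep &= totals <= hi
    removed = int((~keep).sum())
    logger.info("filter_samples_by_depth: removed %d of %d samples", removed, matrix.n_samples)
    return matrix.subset_samples(keep)


def filter_annotated_genes(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Keep genes with a nonempty UniProt id or a nonempty description.

    ``annotation`` needs columns ``transcript_id``, ``uniprot_id``,
    ``description``.  Genes absent from the table count as unannotated.
    """
    for col in ("transcript_id", "uniprot_id", "description"):
        if col not in annotation.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    ann = annotation.set_index("transcript_id")

    def _nonempty(s) -> bool:
        return isinstance(s, str) and s.strip() != ""

    keep = np.array(
        [
            g in ann.index
            and (_nonempty(ann.at[g, "uniprot_id"]) or _nonempty(ann.at[g, "description"]))
            for g in matrix.gene_ids
        ]
    )
    logger.info(
        "filter_annotated_genes: kept %d of %d genes", int(keep.sum()), matrix.n_genes
    )
    return matrix.subset_genes(keep)


def scale_with_regression(
    matrix: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
    clip: float = 10.0,
) -> ExpressionMatrix:
    """Regress out per-sample covariates gene-wise, then z-score and clip.

    For each gene, ordinary-least-squares residuals of expression on the
    covariates (with intercept) are computed, z-scored across samples,
    and clipped to ``±clip``.  Default covariates are the detected-gene
    count and the library total from the sample metadata.
    """
    if matrix.layer not in ("lognorm", "log2TPM"):
        raise ValueError("input layer must be 'lognorm' or 'log2TPM'")
    if covariates is None:
        meta = matrix.sample_meta
        cols = [c for c in ("n_genes_detected", "total") if c in meta.columns]
        if not cols:
            raise ValueError("no covariates available in sample metadata")
        covariates = meta[cols]
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != matrix.n_samples:
        raise ValueError("covariates must have one row per sample")
    X = np.column_stack([np.ones(matrix.n_samples), C])
    Y = matrix.dense()  # genes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    sd = resid.std(axis=1, ddof=1)
    mean = resid.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (resid - mean[:, None]) / sd[:, None]
    z[sd <= 1e-12, :] = 0.0
    np.clip(z, -clip, clip, out=z)
    return matrix.with_values(z, "scaled")


# ---------------------------------------------------------------------------
# dimensionality reduction and clustering
# ---------------------------------------------------------------------------

def pca(matrix: ExpressionMatrix, n_pcs: int) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of samples in gene space with a deterministic sign convention.

    Returns ``(scores, explained_variance_ratio, loadings)`` where scores
    are samples × PCs.  Each component is oriented so its
    largest-magnitude gene loading is positive.
    """
    if n_pcs > min(matrix.n_genes, matrix.n_samples):
        raise ValueError("n_pcs exceeds min(genes, samples)")
    X = matrix.dense().T  # samples x genes
    model = PCA(n_components=n_pcs, svd_solver="full")
    scores = model.fit_transform(X)
    comps = model.components_
    flip = np.sign(comps[np.arange(n_pcs), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    comps = comps * flip[:, None]
    pc_names = [f"PC{i+1}" for i in range(n_pcs)]
    return (
        pd.DataFrame(scores, index=matrix.sample_ids, columns=pc_names),
        model.explained_variance_ratio_,
        pd.DataFrame(comps.T, index=matrix.gene_ids, columns=pc_names),
    )


def _snn_graph(scores: np.ndarray, k_neighbors: int, prune: float = 1.0 / 15.0):
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k_neighbors, n)).fit(scores)
    _, idx = nn.kneighbors(scores)
    sets = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        cand = set()
        for j in idx[i]:
            cand.update(idx[j])
        for j in cand:
            if j <= i:
                continue
            inter = len(sets[i] & sets[int(j)])
            union = len(sets[i] | sets[int(j)])
            w = inter / union if union else 0.0
            if w > prune:
                edges.append((i, int(j)))
                weights.append(w)
    return edges, weights


def cluster_graph(
    pc_scores: pd.DataFrame,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Modularity community detection on a shared-nearest-neighbor graph.

    Builds a kNN/SNN graph with Jaccard weights and partitions it with
    the Leiden algorithm at the given resolution.  Identical inputs and
    seed give identical labels.
    """
    import igraph as ig
    import leidenalg

    X = np.asarray(pc_scores, dtype=float)
    sample_ids = np.asarray(
        pc_scores.index if isinstance(pc_scores, pd.DataFrame) else np.arange(len(X)),
        dtype=object,
    )
    n = X.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of samples")
    edges, weights = _snn_graph(X, k_neighbors)
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = _relabel_contiguous(np.asarray(part.membership), sample_ids)
    return ClusterAssignment(
        labels=pd.Series(labels, index=sample_ids),
        method="graph",
        params={"k_neighbors": k_neighbors, "resolution": resolution, "seed": seed},
    )


def cluster_hierarchical(
    data, k: int | None = None, sample_ids=None
) -> ClusterAssignment:
    """Ward hierarchical clustering on (1 - Pearson) distances.

    ``data`` is an :class:`ExpressionMatrix` (samples = columns) or a
    samples × features array/DataFrame.  Cut at ``k`` clusters, or at
    the largest gap in merge heights when ``k`` is None.
    """
    if isinstance(data, ExpressionMatrix):
        X = data.dense().T
        sample_ids = data.sample_ids
    else:
        X = np.asarray(data, dtype=float)
        if sample_ids is None:
            sample_ids = (
                np.asarray(data.index, dtype=object)
                if isinstance(data, pd.DataFrame)
                else np.arange(X.shape[0])
            )
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance sample(s): {list(np.asarray(sample_ids)[bad])}")
    corr = np.corrcoef(X)
    d = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="ward")
    if k is None:
        heights = Z[:, 2]
        if len(heights) == 1:
            k = 2
        else:
            gaps = np.diff(heights)
            k = n - (int(np.argmax(gaps)) + 1)
            k = max(k, 1)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_contiguous(raw, np.asarray(sample_ids, dtype=object))
    return ClusterAssignment(
        labels=pd.Series(labels, index=np.asarray(sample_ids, dtype=object)),
        method="hierarchical",
        params={"k": int(k), "linkage": "ward", "distance": "1-pearson"},
        linkage=Z,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum marker detection
# ---------------------------------------------------------------------------

def _exact_ranksum_p(gene_ranks: np.ndarray, mask: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank sum of the masked group."""
    n = len(gene_ranks)
    n1 = int(mask.sum())
    obs = gene_ranks[mask].sum()
    mu = n1 * (n + 1) / 2.0
    combs = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    sums = gene_ranks[combs].sum(axis=1)
    return float(np.mean(np.abs(sums - mu) >= np.abs(obs - mu) - 1e-9))


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(z_or_u, p)``.

    ``method="asymptotic"`` uses the normal approximation with tie and
    continuity correction; ``"exact"`` enumerates all group assignments
    (feasible for small groups); ``"auto"`` picks exact when both groups
    have ≤ 8 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mask = np.zeros(n1 + n2, dtype=bool)
    mask[:n1] = True
    if method == "auto":
        method = "exact" if max(n1, n2) <= 8 else "asymptotic"
    if method == "exact":
        p = _exact_ranksum_p(ranks, mask)
        stat = float(ranks[mask].sum() - n1 * (n1 + 1) / 2.0)
        return stat, p
    stat, p = _asymptotic_ranksum(ranks[None, :], mask)
    return float(stat[0]), float(p[0])


def _asymptotic_ranksum(ranks: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected normal-approximation rank-sum test.

    ``ranks`` is genes × samples of within-gene ranks; returns z and
    two-sided p per gene.
    """
    n = ranks.shape[1]
    n1 = int(mask.sum())
    n2 = n - n1
    R1 = ranks[:, mask].sum(axis=1)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum over tie groups of (t^3 - t), per gene
    sorted_r = np.sort(ranks, axis=1)
    tie_term = np.zeros(ranks.shape[0])
    for g in range(ranks.shape[0]):
        _, counts = np.unique(sorted_r[g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    diff = U - mu
    cc = np.sign(diff) * 0.5  # continuity correction toward the mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (diff - cc) / np.sqrt(sigma2)
    z[sigma2 <= 0] = 0.0
    p = 2.0 * norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def rank_markers(
    matrix: ExpressionMatrix,
    clusters: pd.Series | np.ndarray,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    adjust: str = "bonferroni",
) -> MarkerTable:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    For each cluster, genes passing detection-fraction (``min_pct``) and
    log-fold-change (``logfc_min``, natural log of expm1-means) filters
    are tested two-sided against all remaining samples.  Small groups
    (both sides ≤ 8) use the exact permutation distribution; otherwise
    the tie-corrected normal approximation with continuity correction.
    Adjusted p-values are Bonferroni over the genes tested per cluster
    (or Benjamini-Hochberg with ``adjust="bh"``).
    """
    if matrix.layer not in ("lognorm", "log2TPM"):
        raise ValueError("input layer must be 'lognorm' or 'log2TPM'")
    labels = (
        clusters.loc[list(matrix.sample_ids)].to_numpy()
        if isinstance(clusters, pd.Series)
        else np.asarray(clusters)
    )
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    X = matrix.dense()
    expm1 = np.expm1(X)
    detected = X > 0
    rows = []
    for cl in uniq:
        mask = labels == cl
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in == 1:
            warnings.warn(f"cluster {cl!r} has a single sample", stacklevel=2)
        pct_in = detected[:, mask].mean(axis=1)
        pct_out = detected[:, ~mask].mean(axis=1)
        lfc = np.log(expm1[:, mask].mean(axis=1) + 1.0) - np.log(
            expm1[:, ~mask].mean(axis=1) + 1.0
        )
        test = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= logfc_min)
        idx = np.flatnonzero(test)
        if idx.size == 0:
            continue
        sub = X[idx, :]
        ranks = rankdata(sub, axis=1)
        if max(n_in, n_out) <= 8:
            stat = np.array([ranks[i, mask].sum() - n_in * (n_in + 1) / 2.0 for i in range(len(idx))])
            p = np.array([_exact_ranksum_p(ranks[i], mask) for i in range(len(idx))])
        else:
            stat, p = _asymptotic_ranksum(ranks, mask)
        if adjust == "bonferroni":
            p_adj = np.minimum(p * len(idx), 1.0)
        elif adjust == "bh":
            order = np.argsort(p, kind="mergesort")
            ranked = np.empty_like(p)
            m = len(p)
            q = p[order] * m / (np.arange(m) + 1)
            q = np.minimum.accumulate(q[::-1])[::-1]
            ranked[order] = np.minimum(q, 1.0)
            p_adj = ranked
        else:
            raise ValueError("adjust must be 'bonferroni' or 'bh'")
        rows.append(
            pd.DataFrame(
                {
                    "gene": matrix.gene_ids[idx],
                    "cluster": cl,
                    "statistic": stat,
                    "p": p,
                    "p_adj": p_adj,
                    "avg_log_fc": lfc[idx],
                    "pct_in": pct_in[idx],
                    "pct_out": pct_out[idx],
                }
            )
        )
    if not rows:
        table = pd.DataFrame(
            columns=["gene", "cluster", "statistic", "p", "p_adj", "avg_log_fc", "pct_in", "pct_out"]
        )
    else:
        table = pd.concat(rows, ignore_index=True)
    return MarkerTable(table=table)


# ---------------------------------------------------------------------------
# gene-set scores, overlaps, contrast
# ---------------------------------------------------------------------------

def module_score(
    matrix: ExpressionMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-sample gene-set score against expression-matched controls.

    Genes are binned by average expression across samples; for each set
    gene, control genes are drawn (seeded) from its bin; the score is
    the mean expression of the set minus the mean of the pooled control
    genes, per sample.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in gene_set if g not in pos]
    if missing:
        raise ValueError(f"gene_set members absent from matrix: {missing}")
    X = matrix.dense()
    avg = X.mean(axis=1)
    n_bins_eff = int(max(1, min(n_bins, matrix.n_genes)))
    # equal-occupancy bins on the rank of average expression
    order_rank = rankdata(avg, method="ordinal") - 1
    bins = (order_rank * n_bins_eff // matrix.n_genes).astype(int)
    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    for g in gene_set:
        b = bins[pos[g]]
        pool = np.flatnonzero(bins == b)
        take = min(n_ctrl, len(pool))
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False))
    set_idx = [pos[g] for g in gene_set]
    score = X[set_idx, :].mean(axis=0) - X[np.asarray(ctrl_idx), :].mean(axis=0)
    return pd.Series(score, index=matrix.sample_ids, name="module_score")


def detected_gene_overlap(
    matrices: dict[str, ExpressionMatrix] | list[ExpressionMatrix],
    quantile_cutoff: float = 0.10,
) -> dict:
    """Detected-gene sets per matrix and their Venn overlap counts.

    A gene counts as detected in a matrix when its total expression is
    nonzero and at least the ``quantile_cutoff`` quantile (linear
    interpolation) of the nonzero gene totals of that matrix.
    """
    if isinstance(matrices, list):
        matrices = {f"set{i}": m for i, m in enumerate(matrices)}
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    universes = [set(m.gene_ids) for m in matrices.values()]
    if not set.intersection(*universes):
        raise ValueError("matrices share no genes")
    detected: dict[str, set] = {}
    for name, m in matrices.items():
        totals = m.dense().sum(axis=1)
        nz = totals[totals > 0]
        if nz.size == 0:
            detected[name] = set()
            continue
        cutoff = np.quantile(nz, quantile_cutoff)
        detected[name] = set(m.gene_ids[(totals > 0) & (totals >= cutoff)])
    names = list(detected)
    venn: dict[tuple, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(detected[c] for c in combo))
            venn[combo] = len(inter)
    return {"detected": detected, "venn": venn}


def feature_contrast_limits(values) -> tuple[float, float]:
    """(10th, 90th) percentile of the nonzero values, for display contrast."""
    v = np.asarray(values, dtype=float).ravel()
    nz = v[v != 0]
    if nz.size == 0:
        raise ValueError("all values are zero")
    lo, hi = np.percentile(nz, [10, 90])
    return float(lo), float(hi)
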