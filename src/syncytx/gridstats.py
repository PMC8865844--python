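"""Grid-specific spatial transcriptome analyses.

Region-restricted differential expression (e.g. the food-contact
block), per-specimen fan scoring with top-grid extraction, and the
pairwise distance-versus-transcriptome-correlation statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .expression import ExpressionMatrix, MarkerTable, module_score, rank_markers

__all__ = [
    "GridLayout",
    "DistanceCorrelationResult",
    "region_de",
    "fan_score_specimens",
    "distance_correlation",
]


@dataclass
class GridLayout:
    """Physical layout of sampling grids.

    ``table`` is indexed by grid_id with columns ``row``, ``col``,
    ``x_center_um``, ``y_center_um``.  ``include`` marks grids that
    overlap the specimen (user-supplied inclusion mask; defaults to
    all).
    """

    table: pd.DataFrame
    pitch: float
    include: pd.Series | None = None

    def __post_init__(self) -> None:
        required = {"row", "col", "x_center_um", "y_center_um"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout table missing columns {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate grid ids")
        rc = list(zip(self.table["row"], self.table["col"]))
        if len(set(rc)) != len(rc):
            raise ValueError("duplicate (row, col) positions")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        # centers consistent with pitch: offsets x - col*pitch constant
        for axis, coord in (("col", "x_center_um"), ("row", "y_center_um")):
            off = self.table[coord] - self.table[axis] * self.pitch
            if off.size and (off.max() - off.min()) > 1e-6 * max(self.pitch, 1.0):
                raise ValueError(f"{coord} inconsistent with {axis} * pitch")
        if self.include is None:
            self.include = pd.Series(True, index=self.table.index)
        else:
            self.include = self.include.reindex(self.table.index).fillna(False).astype(bool)

    @property
    def grid_ids(self) -> np.ndarray:
        return np.asarray(self.table.index, dtype=object)

    def centers(self, grid_ids=None) -> np.ndarray:
        t = self.table if grid_ids is None else self.table.loc[list(grid_ids)]
        return t[["x_center_um", "y_center_um"]].to_numpy(dtype=float)


@dataclass
class DistanceCorrelationResult:
    """Pairwise grid distance vs transcriptome correlation, with OLS fit."""

    pairs: pd.DataFrame  # columns: grid_i, grid_j, distance_um, pearson_r
    slope: float
    intercept: float
    slope_p: float
    slope_se: float
    n_pairs: int

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import t as t_dist

        df = self.n_pairs - 2
        tcrit = t_dist.ppf(1 - alpha / 2, df)
        return (self.slope - tcrit * self.slope_se, self.slope + tcrit * self.slope_se)


def region_de(
    matrix: ExpressionMatrix,
    layout: GridLayout,
    region_grids,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
) -> MarkerTable:
    """Differential expression of a grid region against all other grids.

    Delegates to :func:`rank_markers` with a two-group labeling; rows of
    the returned table for the region are flagged with cluster label
    ``"region"``.
    """
    region = set(region_grids)
    if not region:
        raise ValueError("region_grids is empty")
    samples = set(matrix.sample_ids)
    if not region <= samples:
        raise ValueError(f"region grids not in matrix: {sorted(region - samples)}")
    if region == samples:
        raise ValueError("region must be a proper subset of the grids")
    if len(region) == 1:
        warnings.warn("single-grid region: statistics are unstable", stacklevel=2)
    labels = pd.Series(
        ["region" if s in region else "rest" for s in matrix.sample_ids],
        index=matrix.sample_ids,
    )
    markers = rank_markers(matrix, labels, min_pct=min_pct, logfc_min=logfc_min)
    table = markers.table[markers.table["cluster"] == "region"].reset_index(drop=True)
    return MarkerTable(table=table)


@dataclass
class FanScoreResult:
    scores: dict[str, pd.Series]  # specimen -> per-grid score
    top_grids: dict[str, list]  # specimen -> top_n grid ids
    pooled: ExpressionMatrix | None  # top grids of all specimens, joint gene set


def fan_score_specimens(
    matrices: dict[str, ExpressionMatrix],
    fan_marker_genes,
    top_n: int = 10,
    seed: int = 0,
) -> FanScoreResult:
    """Module-score every grid of every specimen against fan markers.

    Returns per-grid scores, the ``top_n`` highest-scoring grids per
    specimen, and a pooled matrix of those grids (shared genes) for
    joint clustering.
    """
    fan_marker_genes = list(fan_marker_genes)
    scores: dict[str, pd.Series] = {}
    top: dict[str, list] = {}
    for name, m in matrices.items():
        present = [g for g in fan_marker_genes if g in set(m.gene_ids)]
        if len(present) <= len(fan_marker_genes) / 2:
            raise ValueError(f"specimen {name!r} is missing more than half the marker genes")
        s = module_score(m, present, seed=seed)
        scores[name] = s
        top[name] = list(s.sort_values(ascending=False).head(top_n).index)
    shared = set.intersection(*(set(m.gene_ids) for m in matrices.values()))
    shared_genes = sorted(shared)
    pooled = None
    if shared_genes:
        blocks, ids, meta = [], [], []
        for name, m in matrices.items():
            sub = m.subset_genes(np.asarray(shared_genes, dtype=object)).subset_samples(
                np.asarray(top[name], dtype=object)
            )
            blocks.append(sub.dense())
            ids.extend(f"{name}:{s}" for s in sub.sample_ids)
            meta.extend([name] * sub.n_samples)
        pooled = ExpressionMatrix(
            values=np.concatenate(blocks, axis=1),
            layer=next(iter(matrices.values())).layer,
            gene_ids=np.asarray(shared_genes, dtype=object),
            sample_ids=np.asarray(ids, dtype=object),
            sample_meta=pd.DataFrame({"specimen": meta}, index=ids),
        )
    return FanScoreResult(scores=scores, top_grids=top, pooled=pooled)


def distance_correlation(
    matrix: ExpressionMatrix,
    layout: GridLayout,
    n_hvg: int = 200,
    hvg_matrix: ExpressionMatrix | None = None,
) -> DistanceCorrelationResult:
    """Pairwise grid-center distance vs pairwise transcriptome correlation.

    From the scaled layer: (1) select the ``n_hvg`` most variable genes
    — ranked on ``hvg_matrix`` (e.g. the lognorm layer) when given,
    since z-scored rows are all equally variable; (2) shift each gene by
    the absolute value of its minimum so all values are non-negative;
    (3) Pearson-correlate every grid pair (diagonal excluded); (4) pair
    the correlations with Euclidean distances between grid centers; (5)
    OLS of correlation on distance with a two-sided slope test.
    """
    if matrix.layer != "scaled":
        raise ValueError("input layer must be 'scaled'")
    included = [g for g in matrix.sample_ids if bool(layout.include.get(g, False))]
    if len(included) < 3:
        raise ValueError("need at least 3 included grids")
    sub = matrix.subset_samples(np.asarray(included, dtype=object))
    X = sub.dense()
    if n_hvg > sub.n_genes:
        warnings.warn(
            f"requested {n_hvg} variable genes but only {sub.n_genes} available; using all",
            stacklevel=2,
        )
        n_hvg = sub.n_genes
    if hvg_matrix is not None:
        if not np.array_equal(hvg_matrix.gene_ids, matrix.gene_ids):
            raise ValueError("hvg_matrix must share the gene order of the scaled matrix")
        hvg_sub = hvg_matrix.subset_samples(np.asarray(included, dtype=object))
        var = hvg_sub.dense().var(axis=1)
    else:
        var = X.var(axis=1)
    # rounded variance + gene-index tiebreak => sample-order invariant
    order_key = np.lexsort((np.arange(len(var)), -np.round(var, 9)))
    top = order_key[:n_hvg]
    X = X[top, :]
    X = X + np.abs(X.min(axis=1))[:, None]
    corr = np.corrcoef(X.T)
    centers = layout.centers(included)
    iu, ju = np.triu_indices(len(included), k=1)
    dist = np.hypot(
        centers[iu, 0] - centers[ju, 0], centers[iu, 1] - centers[ju, 1]
    )
    r = corr[iu, ju]
    fit = linregress(dist, r)
    pairs = pd.DataFrame(
        {
            "grid_i": np.asarray(included, dtype=object)[iu],
            "grid_j": np.asarray(included, dtype=object)[ju],
            "distance_um": dist,
            "pearson_r": r,
        }
    )
    return DistanceCorrelationResult(
        pairs=pairs,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_p=float(fit.pvalue),
        slope_se=float(fit.stderr),
        n_pairs=len(r),
    )
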