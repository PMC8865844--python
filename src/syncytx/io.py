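"""Readers, writers, run configuration, and the staged pipeline runner.

All deliverable formats are plain text: MatrixMarket MTX with TSV
sidecars for sparse counts, TSV gene × grid tables, CSV coordinate and
point tables, JSON truth/summary files, Newick dendrograms.  Every
writer/reader pair round-trips bit-exactly for integers and to 1e-12
for floats.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .density import PointPattern, density_ttest, fan_network_split, kde_density_map
from .expression import (
    ExpressionMatrix,
    cluster_graph,
    cluster_hierarchical,
    lognormalize,
    log2_tpm_threshold,
    pca,
    rank_markers,
    scale_with_regression,
    tpm_from_counts,
)
from .gridstats import GridLayout
from .mapping import linkage_to_newick, map_clusters, pseudobulk
from .pseudotime import diffusion_map, order_by_groups
from .simulate import (
    SimulationConfig,
    simulate_nuclei_counts,
    simulate_nuclei_pattern,
    simulate_spatial_grids,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "density", "grids", "markers", "map", "wave")

__all__ = [
    "read_mtx",
    "write_mtx",
    "read_grid_table",
    "write_grid_table",
    "read_points_csv",
    "write_points_csv",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# sparse counts (MatrixMarket + sidecars)
# ---------------------------------------------------------------------------

def write_mtx(matrix: ExpressionMatrix, mtx_path, features_path, barcodes_path) -> None:
    values = matrix.values
    if not sparse.issparse(values):
        values = sparse.coo_matrix(values)
    spio.mmwrite(str(mtx_path), values, field="integer" if matrix.layer == "counts" else None)
    Path(features_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(f"{s}\n" for s in matrix.sample_ids))


def read_mtx(
    mtx_path, features_path, barcodes_path, on_float: str = "error"
) -> ExpressionMatrix:
    """Read a counts matrix with row/column id sidecar files.

    ``on_float="truncate"`` warns and truncates non-integer entries;
    the default raises.
    """
    m = spio.mmread(str(mtx_path))
    genes = [l for l in Path(features_path).read_text().splitlines() if l != ""]
    samples = [l for l in Path(barcodes_path).read_text().splitlines() if l != ""]
    if m.shape != (len(genes), len(samples)):
        raise ValueError(
            f"dimension mismatch: matrix {m.shape}, features {features_path} has "
            f"{len(genes)} lines, barcodes {barcodes_path} has {len(samples)} lines"
        )
    m = sparse.csr_matrix(m)
    if not np.issubdtype(m.dtype, np.integer):
        if np.any(m.data != np.trunc(m.data)):
            if on_float == "truncate":
                warnings.warn("non-integer entries truncated to integers", stacklevel=2)
            else:
                raise ValueError("non-integer entries in counts matrix")
        m = sparse.csr_matrix((m.data.astype(np.int64), m.indices, m.indptr), shape=m.shape)
    return ExpressionMatrix(
        values=m,
        layer="counts",
        gene_ids=np.asarray(genes, dtype=object),
        sample_ids=np.asarray(samples, dtype=object),
    )


# ---------------------------------------------------------------------------
# dense grid tables
# ---------------------------------------------------------------------------

def write_grid_table(matrix: ExpressionMatrix, layout: GridLayout, tsv_path, coords_path) -> None:
    df = matrix.to_frame()
    with open(tsv_path, "w") as fh:
        fh.write(f"# layer={matrix.layer} units=counts-or-normalized genes x grids\n")
        df.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.12g")
    coords = layout.table.copy()
    coords.insert(0, "grid_id", coords.index)
    coords["pitch_um"] = layout.pitch
    coords["include"] = layout.include.loc[coords.index].astype(int)
    coords.to_csv(coords_path, index=False, float_format="%.12g")


def read_grid_table(tsv_path, coords_path, layer: str = "counts"):
    """Read a gene × grid TSV and its coordinate CSV into matrix + layout.

    Grids missing coordinates are dropped with a warning; duplicate
    grid ids in the coordinate table are an error.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#", index_col=0)
    coords = pd.read_csv(coords_path)
    if coords["grid_id"].duplicated().any():
        raise ValueError("duplicated grid_id in coordinate table")
    coords = coords.set_index("grid_id")
    known = [g for g in df.columns if g in coords.index]
    missing = [g for g in df.columns if g not in coords.index]
    if missing:
        warnings.warn(f"dropping {len(missing)} grids without coordinates", stacklevel=2)
    df = df[known]
    coords = coords.loc[known]
    pitch = float(coords["pitch_um"].iloc[0]) if "pitch_um" in coords.columns else 1.0
    include = (
        coords["include"].astype(bool)
        if "include" in coords.columns
        else pd.Series(True, index=coords.index)
    )
    layout = GridLayout(
        table=coords[["row", "col", "x_center_um", "y_center_um"]],
        pitch=pitch,
        include=include,
    )
    values = df.to_numpy()
    if layer == "counts":
        values = values.astype(np.int64)
    matrix = ExpressionMatrix(
        values=values,
        layer=layer,
        gene_ids=np.asarray(df.index, dtype=object),
        sample_ids=np.asarray(df.columns, dtype=object),
        sample_meta=coords[["row", "col", "x_center_um", "y_center_um"]].copy(),
    )
    return matrix, layout


# ---------------------------------------------------------------------------
# point tables
# ---------------------------------------------------------------------------

def write_points_csv(pattern: PointPattern, path) -> None:
    df = pattern.to_frame()
    header = ",".join(f"{c}" for c in df.columns)
    with open(path, "w") as fh:
        xmin, ymin, xmax, ymax = pattern.domain
        fh.write(f"# domain_um={xmin},{ymin},{xmax},{ymax}\n")
        fh.write(header + "\n")
        df.to_csv(fh, index=False, header=False, float_format="%.12g")


def read_points_csv(path) -> PointPattern:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# domain_um="):
            raise ValueError("point CSV must start with a '# domain_um=' header")
        domain = tuple(float(v) for v in first.strip().split("=", 1)[1].split(","))
        df = pd.read_csv(fh)
    return PointPattern(
        points=df[["x_um", "y_um"]].to_numpy(dtype=float),
        domain=domain,
        diameter=df["diameter_um"].to_numpy(dtype=float) if "diameter_um" in df else None,
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

_STAGE_PARAM_KEYS = {
    "simulate": set(SimulationConfig.__dataclass_fields__),
    "density": {"bandwidth", "cell_size"},
    "grids": {"n_pcs", "cluster_method", "k", "k_neighbors", "resolution"},
    "markers": {"min_pct", "logfc_min", "adjust"},
    "map": {"top_n", "n_pcs", "k_neighbors", "resolution"},
    "wave": {"n_comps", "k_local", "n_marker_genes"},
}


@dataclass
class RunConfig:
    """Fully explicit, serializable pipeline configuration."""

    seed: int = 0
    outdir: str = "run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        bad_keys = set(self.params) - set(STAGES)
        if bad_keys:
            raise ValueError(f"params for unknown stage(s): {sorted(bad_keys)}")
        for stage, p in self.params.items():
            extra = set(p) - _STAGE_PARAM_KEYS[stage]
            if extra:
                raise ValueError(f"unknown keys for stage {stage!r}: {sorted(extra)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = {"seed", "outdir", "stages", "params"}
        extra = set(data) - allowed
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "stages": list(self.stages),
            "params": {k: dict(v) for k, v in self.params.items()},
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in order; return the run directory.

    Writes all stage outputs plus ``manifest.json`` recording the
    config, seed, a parameter hash, and per-stage timings and output
    hashes.  A stage failure halts the run with the stage name; partial
    outputs are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "syncytx",
        "seed": config.seed,
        "config": config.to_dict(),
        "param_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in config.to_dict().items() if k != "outdir"},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "stages": [],
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        before = {p for p in out.rglob("*") if p.is_file()}
        try:
            _STAGE_FNS[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            _write_json(out / "manifest.json", manifest)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        after = {p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"}
        outputs = sorted(str(p.relative_to(out)) for p in (after - before) | (after & before))
        manifest["stages"].append(
            {
                "name": stage,
                "params": dict(config.params.get(stage, {})),
                "outputs": {rel: _sha256(out / rel) for rel in outputs},
                "elapsed_s": round(time.perf_counter() - t0, 4),
            }
        )
        logger.info("stage %s done in %.2fs", stage, manifest["stages"][-1]["elapsed_s"])
    _write_json(out / "manifest.json", manifest)
    return out


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    p = dict(config.params.get("simulate", {}))
    p.setdefault("seed", config.seed)
    cfg = SimulationConfig(**p)
    state["sim_cfg"] = cfg
    pattern, pat_truth = simulate_nuclei_pattern(cfg)
    write_points_csv(pattern, out / "points.csv")
    pat_truth.to_json(out / "points_truth.json")
    grids, layout, grid_truth = simulate_spatial_grids(cfg)
    write_grid_table(grids, layout, out / "grids.tsv", out / "grid_coords.csv")
    grid_truth.to_json(out / "grids_truth.json")
    nuc, nuc_truth = simulate_nuclei_counts(cfg)
    write_mtx(nuc, out / "nuclei.mtx", out / "nuclei_features.tsv", out / "nuclei_barcodes.tsv")
    nuc_truth.to_json(out / "nuclei_truth.json")
    state.update(pattern=pattern, grids=grids, layout=layout, nuclei=nuc)


def _require(state: dict, key: str, loader):
    if key not in state:
        state[key] = loader()
    return state[key]


def _stage_density(config: RunConfig, out: Path, state: dict) -> None:
    p = config.params.get("density", {})
    pattern = _require(state, "pattern", lambda: read_points_csv(out / "points.csv"))
    dmap = kde_density_map(
        pattern, bandwidth=p.get("bandwidth", "auto"), cell_size=p.get("cell_size", 20.0)
    )
    split = fan_network_split(dmap)
    fan_rows = [i for i, l in enumerate(split.bin_labels) if l == "fan"]
    net_rows = [i for i, l in enumerate(split.bin_labels) if l == "network"]
    t, pval, means = density_ttest(
        dmap.values[fan_rows, :].ravel(), dmap.values[net_rows, :].ravel()
    )
    pd.DataFrame(
        {"profile": split.profile, "label": split.bin_labels}
    ).to_csv(out / "density_profile.tsv", sep="\t", index_label="row")
    _write_json(
        out / "density_summary.json",
        {
            "threshold": split.threshold,
            "t": t,
            "p": pval,
            "mean_fan": means[0],
            "mean_network": means[1],
            "bandwidth": dmap.bandwidth,
            "cell_size": dmap.cell_size,
            "total_mass": dmap.total_mass,
            "n_points": pattern.n,
        },
    )


def _load_grids(out: Path):
    return read_grid_table(out / "grids.tsv", out / "grid_coords.csv")


def _stage_grids(config: RunConfig, out: Path, state: dict) -> None:
    p = config.params.get("grids", {})
    if "grids" not in state:
        state["grids"], state["layout"] = _load_grids(out)
    grids = state["grids"]
    log2 = log2_tpm_threshold(tpm_from_counts(grids, np.ones(grids.n_genes)))
    scaled = scale_with_regression(log2)
    state["grids_log2"] = log2
    state["grids_scaled"] = scaled
    n_pcs = p.get("n_pcs", 10)
    scores, evr, _ = pca(scaled, n_pcs=n_pcs)
    method = p.get("cluster_method", "hierarchical")
    if method == "graph":
        assign = cluster_graph(
            scores,
            k_neighbors=p.get("k_neighbors", 15),
            resolution=p.get("resolution", 0.4),
            seed=config.seed,
        )
    else:
        assign = cluster_hierarchical(scores, k=p.get("k"))
    state["grid_clusters"] = assign
    scores.to_csv(out / "grid_pca.tsv", sep="\t", float_format="%.12g")
    assign.labels.rename("cluster").to_csv(out / "grid_clusters.tsv", sep="\t")
    _write_json(
        out / "grids_summary.json",
        {"explained_variance_ratio": evr.tolist(), "method": assign.method, "params": assign.params},
    )


def _stage_markers(config: RunConfig, out: Path, state: dict) -> None:
    p = config.params.get("markers", {})
    if "grids_log2" not in state:
        _stage_grids(config, out, state)
    markers = rank_markers(
        state["grids_log2"],
        state["grid_clusters"].labels,
        min_pct=p.get("min_pct", 0.1),
        logfc_min=p.get("logfc_min", 0.25),
        adjust=p.get("adjust", "bonferroni"),
    )
    state["grid_markers"] = markers
    markers.table.to_csv(out / "grid_markers.tsv", sep="\t", index=False, float_format="%.12g")


def _stage_map(config: RunConfig, out: Path, state: dict) -> None:
    p = config.params.get("map", {})
    nuclei = _require(
        state,
        "nuclei",
        lambda: read_mtx(
            out / "nuclei.mtx", out / "nuclei_features.tsv", out / "nuclei_barcodes.tsv"
        ),
    )
    if "grid_markers" not in state:
        _stage_markers(config, out, state)
    nuc_log = lognormalize(nuclei)
    nuc_scaled = scale_with_regression(nuc_log)
    scores, _, _ = pca(nuc_scaled, n_pcs=p.get("n_pcs", 10))
    assign = cluster_graph(
        scores,
        k_neighbors=p.get("k_neighbors", 15),
        resolution=p.get("resolution", 0.5),
        seed=config.seed,
    )
    state["nuclei_clusters"] = assign
    state["nuclei_log"] = nuc_log
    state["nuclei_pca"] = scores
    nuc_pb = pseudobulk(nuc_log, assign.labels)
    nuc_pb.source = "nuclei"
    sp_pb = pseudobulk(state["grids_log2"], state["grid_clusters"].labels)
    sp_pb.source = "spatial"
    cmap = map_clusters(nuc_pb, sp_pb, state["grid_markers"], top_n=p.get("top_n", 50))
    cmap.raw.to_csv(out / "map_raw.tsv", sep="\t", float_format="%.12g")
    cmap.scaled.to_csv(out / "map_scaled.tsv", sep="\t", float_format="%.12g")
    if cmap.dendrogram is not None:
        (out / "map_dendrogram.nwk").write_text(
            linkage_to_newick(cmap.dendrogram, list(cmap.raw.index))
        )
    assign.labels.rename("cluster").to_csv(out / "nuclei_clusters.tsv", sep="\t")


def _stage_wave(config: RunConfig, out: Path, state: dict) -> None:
    p = config.params.get("wave", {})
    if "nuclei_clusters" not in state:
        _stage_map(config, out, state)
    nuc_log = state["nuclei_log"]
    assign = state["nuclei_clusters"]
    markers = rank_markers(nuc_log, assign.labels)
    # sequence blocks by mean expression of the top markers of the last cluster
    clusters = sorted(assign.labels.unique())
    ref = markers.top_genes(clusters[-1], n=p.get("n_marker_genes", 10))
    if not ref:
        ref = list(nuc_log.gene_ids[:10])
    sub = nuc_log.subset_genes(np.asarray(ref, dtype=object))
    mean_ref = pd.Series(sub.dense().mean(axis=0), index=nuc_log.sample_ids)
    seq = list(mean_ref.groupby(assign.labels).mean().sort_values().index)
    comps, _ = diffusion_map(
        state["nuclei_pca"], n_comps=p.get("n_comps", 2), k_local=p.get("k_local", 10)
    )
    ordering = order_by_groups(comps, assign.labels, seq)
    df = pd.DataFrame(
        {
            "rank": ordering.ranks,
            "component": ordering.component_values,
            "cluster": assign.labels,
        }
    )
    df.to_csv(out / "wave_ordering.csv", index_label="sample_id", float_format="%.12g")


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "density": _stage_density,
    "grids": _stage_grids,
    "markers": _stage_markers,
    "map": _stage_map,
    "wave": _stage_wave,
}
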