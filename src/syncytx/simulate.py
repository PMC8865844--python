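"""Ground-truth synthetic data for every pipeline stage.

Generates plasmodium-like nuclei point patterns (inhomogeneous
hard-core process), rendered fluorescence-like images, gridded
transcriptomes with region programs and a traveling cyclic wave, and
single-nucleus / amoeba count matrices at configurable depth.

All distributional choices are stand-ins (the underlying study is
observational and defines no generative model); truth files carry a
note flagging this.  Identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .density import PointPattern
from .expression import ExpressionMatrix
from .gridstats import GridLayout

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_nuclei_pattern",
    "render_nuclei_image",
    "simulate_spatial_grids",
    "simulate_nuclei_counts",
    "simulate_amoeba_counts",
]

_TRUTH_NOTE = (
    "synthetic stand-in: generative distributions are artifact choices, "
    "not measurements"
)


@dataclass
class SimulationConfig:
    """All knobs for the synthetic generators.

    Defaults emulate the measured scales of the emulated system: mean
    nucleus diameter ≈ 5.65 µm, single-nucleus depth ≈ 591 UMIs,
    amoeba depth ≈ 14,525 UMIs, SmartSeq2-like grid libraries.
    """

    domain_size: tuple[float, float] = (800.0, 500.0)  # (width, height) um
    fan_fraction: float = 0.3  # fraction of the y-extent assigned to the fan
    lambda_fan: float = 0.02  # nuclei per um^2
    lambda_network: float = 0.01
    hardcore_radius: float = 2.0  # um, min center-to-center spacing
    diameter_mean: float = 5.65  # um
    diameter_cv: float = 0.15
    n_grids: tuple[int, int] = (8, 8)  # (rows, cols)
    grid_pitch: float = 4000.0  # um per grid
    n_genes: int = 1000
    n_markers_per_program: int = 20
    program_log2fc: float = 1.0
    wave_speed: float = 2.0 * np.pi / 8.0  # phase units per grid column
    wave_amplitude: float = 1.0
    libsize_grid: float = 200_000.0
    libsize_nucleus: float = 591.0
    libsize_amoeba: float = 14_525.0
    nb_dispersion: float | None = 10.0  # None => Poisson limit
    n_nuclei: int = 1000
    n_amoebae: int = 500
    n_phase_bins: int = 8
    oat_size: int = 4  # oat block is oat_size x oat_size grids, 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_fan <= 0 or self.lambda_network <= 0:
            raise ValueError("intensities must be > 0")
        if self.hardcore_radius < 0:
            raise ValueError("hardcore_radius must be >= 0")
        if not 0 < self.fan_fraction < 1:
            raise ValueError("fan_fraction must be in (0, 1)")
        for name in ("libsize_grid", "libsize_nucleus", "libsize_amoeba"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.domain_size[0] <= 0 or self.domain_size[1] <= 0:
            raise ValueError("domain_size must be positive")
        if self.diameter_mean <= 0 or self.diameter_cv < 0:
            raise ValueError("diameter distribution must have positive mean, cv >= 0")
        if self.nb_dispersion is not None and not np.isfinite(self.nb_dispersion):
            self.nb_dispersion = None
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0 (or None for Poisson)")


@dataclass
class SyntheticTruth:
    """Generative labels for acceptance checks; round-trips through JSON."""

    region_of_grid: dict[str, str] = field(default_factory=dict)
    phase_of_grid: dict[str, float] = field(default_factory=dict)
    program_genes: dict[str, list[str]] = field(default_factory=dict)
    cluster_of_nucleus: dict[str, str] = field(default_factory=dict)
    region_of_point: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    note: str = _TRUTH_NOTE

    def __post_init__(self) -> None:
        sets = [set(v) for v in self.program_genes.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("program gene sets must be disjoint")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# point pattern
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_nuclei_pattern(cfg: SimulationConfig) -> tuple[PointPattern, SyntheticTruth]:
    """Inhomogeneous hard-core point process with a fan/network split.

    The fan band (top ``fan_fraction`` of the y-extent) has intensity
    ``lambda_fan``, the rest ``lambda_network``.  The hard core is
    realized by dependent thinning (Matérn II) with the proposal
    intensity boosted so the retained intensity matches the target.
    Diameters are log-normal with the configured mean and CV.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    width, height = cfg.domain_size
    y_split = height * (1.0 - cfg.fan_fraction)
    r = cfg.hardcore_radius
    disc = np.pi * r**2

    proposals, regions = [], []
    for region, lam, y0, y1 in (
        ("network", cfg.lambda_network, 0.0, y_split),
        ("fan", cfg.lambda_fan, y_split, height),
    ):
        if r > 0:
            cap = 1.0 / disc
            if lam >= 0.99 * cap:
                raise ValueError(
                    f"lambda_{region}={lam:g} exceeds the hard-core packing bound "
                    f"~{0.99 * cap:g} nuclei/um^2 at hardcore_radius={r:g}"
                )
            lam_prop = -np.log1p(-lam * disc) / disc  # Matern II compensation
        else:
            lam_prop = lam
        area = width * (y1 - y0)
        n = rng.poisson(lam_prop * area)
        pts = np.column_stack(
            [rng.uniform(0.0, width, n), rng.uniform(y0, y1, n)]
        )
        proposals.append(pts)
        regions.extend([region] * n)
    pts = np.concatenate(proposals, axis=0)
    regions = np.asarray(regions, dtype=object)
    marks = rng.uniform(size=len(pts))

    if r > 0 and len(pts) > 1:
        keep = np.ones(len(pts), dtype=bool)
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(r):
            if marks[i] < marks[j]:
                keep[j] = False
            else:
                keep[i] = False
        pts, regions = pts[keep], regions[keep]

    mu, sigma = _lognormal_params(cfg.diameter_mean, cfg.diameter_cv)
    diam = rng.lognormal(mu, sigma, size=len(pts))
    pattern = PointPattern(
        points=pts, domain=(0.0, 0.0, width, height), diameter=diam
    )
    truth = SyntheticTruth(
        region_of_point=list(regions),
        params={
            "lambda_fan": cfg.lambda_fan,
            "lambda_network": cfg.lambda_network,
            "fan_fraction": cfg.fan_fraction,
            "y_split": y_split,
            "hardcore_radius": r,
            "diameter_mean": cfg.diameter_mean,
            "diameter_cv": cfg.diameter_cv,
        },
    )
    return pattern, truth


def render_nuclei_image(
    pattern: PointPattern,
    pixel_size: float,
    psf_sigma: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render nuclei as Gaussian spots plus additive Gaussian noise.

    Each nucleus becomes an isotropic Gaussian of width
    ``sqrt(psf_sigma^2 + (d/4)^2)`` at its position; the label mask
    paints a disk of its radius with the 1-based object id.  Points
    outside the pattern domain are rejected by the pattern itself.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    xmin, ymin, xmax, ymax = pattern.domain
    n_cols = max(1, int(np.ceil((xmax - xmin) / pixel_size)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / pixel_size)))
    image = np.zeros((n_rows, n_cols))
    mask = np.zeros((n_rows, n_cols), dtype=np.int32)
    diam = (
        pattern.diameter
        if pattern.diameter is not None
        else np.zeros(pattern.n)
    )
    for i in range(pattern.n):
        x, y = pattern.points[i]
        s = float(np.hypot(psf_sigma, diam[i] / 4.0))
        s = max(s, pixel_size / 4.0)
        half = max(3.0 * s, diam[i] / 2.0) + pixel_size
        c0 = max(0, int((x - xmin - half) / pixel_size))
        c1 = min(n_cols, int((x - xmin + half) / pixel_size) + 1)
        r0 = max(0, int((y - ymin - half) / pixel_size))
        r1 = min(n_rows, int((y - ymin + half) / pixel_size) + 1)
        xc = xmin + (np.arange(c0, c1) + 0.5) * pixel_size
        yc = ymin + (np.arange(r0, r1) + 0.5) * pixel_size
        gx = np.exp(-((xc - x) ** 2) / (2 * s**2))
        gy = np.exp(-((yc - y) ** 2) / (2 * s**2))
        image[r0:r1, c0:c1] += np.outer(gy, gx)
        dist2 = (yc[:, None] - y) ** 2 + (xc[None, :] - x) ** 2
        radius = max(diam[i] / 2.0, pixel_size * 0.75)
        mask_win = mask[r0:r1, c0:c1]
        mask_win[dist2 <= radius**2] = i + 1
    if noise_sd > 0:
        rng = np.random.default_rng([seed, 99])
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image, mask


# ---------------------------------------------------------------------------
# expression programs
# ---------------------------------------------------------------------------

def _gene_params(cfg: SimulationConfig):
    """Seeded gene-level parameters shared by all count simulators."""
    rng = np.random.default_rng([cfg.seed, 0])
    gene_ids = np.asarray([f"g{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    baseline = rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    m = cfg.n_markers_per_program
    if 4 * m > cfg.n_genes:
        raise ValueError("n_genes too small for 4 marker programs")
    markers = {
        "fan": np.arange(0, m),
        "network": np.arange(m, 2 * m),
        "oat": np.arange(2 * m, 3 * m),
    }
    wave_idx = np.arange(3 * m, 4 * m)
    peaks = 2.0 * np.pi * np.arange(m) / m
    return gene_ids, baseline, markers, wave_idx, peaks


def _wave_factor(cfg: SimulationConfig, phase: float, wave_idx, peaks, n_genes) -> np.ndarray:
    f = np.ones(n_genes)
    if cfg.wave_amplitude > 0:
        f[wave_idx] = np.exp(cfg.wave_amplitude * np.cos(phase - peaks))
    return f


def _draw_counts(rng, probs: np.ndarray, mean_depth: float, dispersion) -> np.ndarray:
    """One library: gamma-perturbed rates, Poisson depth, multinomial draw.

    Marginals are negative-binomial-like with variance
    ``mean + mean^2/dispersion``; ``dispersion=None`` gives the Poisson
    limit.  The column sum equals the drawn library size exactly.
    """
    depth = rng.poisson(mean_depth)
    if dispersion is not None:
        rates = rng.gamma(dispersion, probs / dispersion)
    else:
        rates = probs
    total = rates.sum()
    if total <= 0:
        rates = np.full_like(probs, 1.0 / len(probs))
        total = 1.0
    return rng.multinomial(depth, rates / total)


def simulate_spatial_grids(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, GridLayout, SyntheticTruth]:
    """Gridded transcriptome with region programs and a traveling wave.

    Expected expression per grid = baseline × region-program
    fold-changes × cyclic wave factor ``exp(a*cos(phase - peak))`` for
    wave genes, with phase advancing by ``wave_speed`` per grid column.
    Counts follow the dispersed multinomial of :func:`_draw_counts`.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    gene_ids, baseline, markers, wave_idx, peaks = _gene_params(cfg)
    rows, cols = cfg.n_grids
    pitch = cfg.grid_pitch
    height = rows * pitch
    y_split = height * (1.0 - cfg.fan_fraction)

    grid_ids, rec, region_of, phase_of = [], [], {}, {}
    counts = np.zeros((cfg.n_genes, rows * cols), dtype=np.int64)
    k = 0
    for r in range(rows):
        for c in range(cols):
            gid = f"grid_r{r:02d}c{c:02d}"
            x, y = (c + 0.5) * pitch, (r + 0.5) * pitch
            region = "fan" if y > y_split else "network"
            if (
                cfg.oat_size > 0
                and region == "network"
                and r < cfg.oat_size
                and c >= cols - cfg.oat_size
            ):
                region = "oat"
            phase = (cfg.wave_speed * c) % (2.0 * np.pi)
            w = baseline.copy()
            w[markers[region if region in markers else "network"]] *= 2.0**cfg.program_log2fc
            w *= _wave_factor(cfg, phase, wave_idx, peaks, cfg.n_genes)
            counts[:, k] = _draw_counts(rng, w / w.sum(), cfg.libsize_grid, cfg.nb_dispersion)
            grid_ids.append(gid)
            rec.append((r, c, x, y))
            region_of[gid] = region
            phase_of[gid] = float(phase)
            k += 1

    layout = GridLayout(
        table=pd.DataFrame(
            rec, columns=["row", "col", "x_center_um", "y_center_um"], index=grid_ids
        ),
        pitch=pitch,
    )
    meta = layout.table.copy()
    meta["specimen"] = "SM1"
    matrix = ExpressionMatrix(
        values=counts,
        layer="counts",
        gene_ids=gene_ids,
        sample_ids=np.asarray(grid_ids, dtype=object),
        sample_meta=meta,
    )
    truth = SyntheticTruth(
        region_of_grid=region_of,
        phase_of_grid=phase_of,
        program_genes={
            **{k2: list(gene_ids[v]) for k2, v in markers.items()},
            "wave": list(gene_ids[wave_idx]),
        },
        params={"program_log2fc": cfg.program_log2fc, "wave_amplitude": cfg.wave_amplitude},
    )
    return matrix, layout, truth


def _program_profile(cfg, program, baseline, markers, wave_idx, peaks) -> np.ndarray:
    w = baseline.copy()
    if program in markers:
        w[markers[program]] *= 2.0**cfg.program_log2fc
    elif program.startswith("phase_"):
        k = int(program.split("_")[1])
        phase = 2.0 * np.pi * k / cfg.n_phase_bins
        w *= _wave_factor(cfg, phase, wave_idx, peaks, len(baseline))
    elif program != "base":
        raise ValueError(f"unknown program {program!r}")
    return w / w.sum()


def _simulate_cells(
    cfg: SimulationConfig,
    programs: list[str],
    n_cells: int,
    mean_depth: float,
    prefix: str,
    stream: int,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    rng = np.random.default_rng([cfg.seed, stream])
    gene_ids, baseline, markers, wave_idx, peaks = _gene_params(cfg)
    profiles = {
        p: _program_profile(cfg, p, baseline, markers, wave_idx, peaks) for p in programs
    }
    assignment = rng.integers(0, len(programs), size=n_cells)
    counts = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
    cell_ids = np.asarray([f"{prefix}{i:05d}" for i in range(n_cells)], dtype=object)
    for i in range(n_cells):
        counts[:, i] = _draw_counts(
            rng, profiles[programs[assignment[i]]], mean_depth, cfg.nb_dispersion
        )
    matrix = ExpressionMatrix(
        values=sparse.csr_matrix(counts),
        layer="counts",
        gene_ids=gene_ids,
        sample_ids=cell_ids,
        sample_meta=pd.DataFrame(
            {"program": [programs[a] for a in assignment]}, index=cell_ids
        ),
    )
    truth = SyntheticTruth(
        cluster_of_nucleus={c: programs[a] for c, a in zip(cell_ids, assignment)},
        program_genes={
            **{k2: list(gene_ids[v]) for k2, v in markers.items()},
            "wave": list(gene_ids[wave_idx]),
        },
        params={"mean_depth": mean_depth, "programs": list(programs)},
    )
    return matrix, truth


def _resolve_programs(cfg: SimulationConfig, programs) -> list[str]:
    if programs is None:
        return ["fan", "network"]
    if programs == "phase":
        return [f"phase_{k}" for k in range(cfg.n_phase_bins)]
    return list(programs)


def simulate_nuclei_counts(
    cfg: SimulationConfig, programs=None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Sparse single-nucleus UMI counts at shallow depth.

    Each nucleus gets a program (default fan/network; pass
    ``programs="phase"`` for wave-phase bins) and a multinomial UMI
    vector at Poisson(``libsize_nucleus``) depth from the program's
    relative-expression profile.
    """
    return _simulate_cells(
        cfg, _resolve_programs(cfg, programs), cfg.n_nuclei, cfg.libsize_nucleus, "n", 3
    )


def simulate_amoeba_counts(
    cfg: SimulationConfig, phase_programs: bool = True
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Sparse single-cell counts with cyclic phase programs, deep libraries."""
    programs = "phase" if phase_programs else ["base"]
    return _simulate_cells(
        cfg, _resolve_programs(cfg, programs), cfg.n_amoebae, cfg.libsize_amoeba, "a", 4
    )
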