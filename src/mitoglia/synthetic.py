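"""Seeded generators of microglia-like cells with known ground truth.

The study's raw volumes are not deposited, so every pipeline stage is
exercised on synthetic cells: a stochastic branched tree stands in for the
traced processes, organelles are ellipsoids placed along the tree with a
controllable perinuclear mixture weight, and their volumes are lognormal
draws rescaled so the total content per cell is hit exactly.  Phenotype
knobs mirror the biology the metrics are designed to detect:

* ``fragmentation`` — scales the organelle count and widens the lognormal
  volume spread at fixed total content, lowering the per-cell median volume
  (fission-dominated networks: many small organelles);
* ``elongation`` — ellipsoid aspect ratio; higher values lower sphericity
  (tubular, fused organelles);
* ``perinuclear_bias`` — probability an organelle sits within 10 μm of the
  soma;
* ``hyperfused_fraction`` — probability a cell carries one dominant large
  organelle (the largest-organelle metric's target phenotype);
* ``branch_prob_decay`` — how quickly branching decays with distance from
  the soma; higher values shift Sholl mass closer to the soma, as in
  injury-responsive cells.

All randomness flows from a single seed through ``numpy.random.default_rng``;
generation is a pure function of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (
    CellRecord,
    DomainError,
    FilamentTree,
    OrganelleRecord,
    QpcrRecord,
    VoxelImage,
)
from .segmentation import wadell_sphericity

#: Default voxel spacing of the emulated acquisition (z, y, x) μm.
ACQUISITION_SPACING = (0.15, 0.05, 0.05)
#: Coarser isotropic spacing used for fast end-to-end runs.
FAST_SPACING = (0.2, 0.2, 0.2)

#: Lognormal spread grows with fragmentation: sigma² = sigma0² + coupling·ln f.
#: With the defaults, fragmentation 1.5 at 1.3× content yields ~1.5× organelle
#: count and ~0.6× per-cell median volume — the injury-responsive phenotype.
SIGMA_FRAG_COUPLING = 1.8


@dataclass
class SyntheticCellParams:
    """Generative knobs for one microglia-like cell."""

    # morphology
    n_primary_branches: int = 5
    branch_length_mean: float = 12.0     # μm, primary branch length scale
    branch_prob_decay: float = 0.03      # per μm of distance from the soma
    max_branch_depth: int = 4
    soma_radius: float = 2.5             # μm (the 5 μm nucleus spot)
    node_radius: float = 0.4             # μm process tube radius
    # cell size
    cell_volume: float = 1500.0          # μm³
    # mitochondria
    target_content_pct: float = 5.0      # % of cell volume
    content_cv: float = 0.15             # per-cell lognormal CV of the target
    fragmentation: float = 1.0
    elongation: float = 2.0              # ellipsoid long:short aspect, >= 1
    perinuclear_bias: float = 0.3
    hyperfused_fraction: float = 0.0
    hyperfused_volume: float = 10.0      # μm³ dominant organelle volume
    n_mito_base: float = 60.0            # mean count at fragmentation 1
    volume_sigma0: float = 0.4           # lognormal sigma at fragmentation 1
    # vesicles (CD68-like)
    vesicle_content_pct: float = 2.0
    vesicle_fragmentation: float = 1.0
    vesicle_elongation: float = 1.2
    vesicle_perinuclear_bias: float = 0.2
    n_vesicle_base: float = 15.0
    # placement
    min_separation: float | None = None  # μm gap enforced between organelles
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.perinuclear_bias <= 1 and 0 <= self.vesicle_perinuclear_bias <= 1):
            raise DomainError("perinuclear biases must be in [0, 1]")
        if not (0 <= self.hyperfused_fraction <= 1):
            raise DomainError("hyperfused_fraction must be in [0, 1]")
        if self.fragmentation <= 0 or self.vesicle_fragmentation <= 0:
            raise DomainError("fragmentation must be > 0")
        if self.elongation < 1 or self.vesicle_elongation < 1:
            raise DomainError("elongation must be >= 1")
        if self.cell_volume <= 0 or self.target_content_pct < 0:
            raise DomainError("cell_volume must be > 0 and content >= 0")


def naive_params(**overrides) -> SyntheticCellParams:
    """Baseline surveillant phenotype."""
    return replace(SyntheticCellParams(), **overrides)


def onc_params(**overrides) -> SyntheticCellParams:
    """Injury-responsive phenotype: fragmented network (0.6× median volume,
    1.5× count), 1.3× content, +~15 points perinuclear, Sholl mass shifted
    toward the soma."""
    base = SyntheticCellParams(
        fragmentation=1.5,
        target_content_pct=6.5,
        perinuclear_bias=0.5,
        branch_prob_decay=0.06,
        elongation=1.5,
        vesicle_content_pct=3.0,
    )
    return replace(base, **overrides)


def onc_hyperfused_params(**overrides) -> SyntheticCellParams:
    """Stressed phenotype with stochastic hyperfusion: half the cells carry
    one dominant ~10 μm³ organelle.  Unlike the fragmented injury response,
    hyperfusion keeps the count/spread at baseline — the network fuses
    rather than fissions — so the largest-organelle metric, not the median
    volume, is what separates this group."""
    base = SyntheticCellParams(
        target_content_pct=6.5,
        perinuclear_bias=0.5,
        branch_prob_decay=0.06,
        hyperfused_fraction=0.5,
        hyperfused_volume=10.0,
        vesicle_content_pct=3.0,
    )
    return replace(base, **overrides)


PRESETS = {
    "naive": naive_params,
    "onc": onc_params,
    "onc-hyperfused": onc_hyperfused_params,
}


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perturb(direction: np.ndarray, rng: np.random.Generator, angle_sd: float) -> np.ndarray:
    v = direction + rng.normal(scale=angle_sd, size=3)
    n = np.linalg.norm(v)
    return direction if n == 0 else v / n


def _generate_tree(params: SyntheticCellParams, rng: np.random.Generator) -> FilamentTree:
    step = 2.0
    nodes: dict[int, tuple[int | None, np.ndarray, float]] = {
        0: (None, np.zeros(3), params.soma_radius)
    }
    next_id = 1
    # (parent node, direction, remaining length, depth)
    stack: list[tuple[int, np.ndarray, float, int]] = []
    for _ in range(params.n_primary_branches):
        length = rng.gamma(2.0, params.branch_length_mean / 2.0)
        stack.append((0, _random_unit(rng), float(length), 0))
    while stack and next_id < 4000:
        pid, direction, remaining, depth = stack.pop()
        pos = nodes[pid][1]
        seg = min(step, remaining)
        new_pos = pos + direction * seg
        nid = next_id
        nodes[nid] = (pid, new_pos, params.node_radius)
        next_id += 1
        remaining -= seg
        if remaining > 1e-9:
            stack.append((nid, _perturb(direction, rng, 0.25), remaining, depth))
        elif depth < params.max_branch_depth:
            d = float(np.linalg.norm(new_pos))
            p_branch = 0.9 * math.exp(-params.branch_prob_decay * d)
            if rng.random() < p_branch:
                scale = params.branch_length_mean * 0.7 ** (depth + 1)
                for _ in range(2):
                    length = rng.gamma(2.0, scale / 2.0)
                    stack.append((nid, _perturb(direction, rng, 0.6), float(length), depth + 1))
    return FilamentTree(nodes=nodes)


def _arc_points(tree: FilamentTree, step: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Sample points along the tree arc length; returns positions, distances."""
    root = tree.root_position
    points = [root]
    for start, end in tree.edges():
        length = float(np.linalg.norm(end - start))
        n = max(1, int(math.ceil(length / step)))
        for t in np.linspace(0.0, 1.0, n + 1)[1:]:
            points.append(start + t * (end - start))
    pts = np.asarray(points)
    return pts, np.linalg.norm(pts - root, axis=1)


# ---------------------------------------------------------------------------
# Organelle population
# ---------------------------------------------------------------------------

def _prolate_surface_area(volume: float, aspect: float) -> tuple[float, np.ndarray]:
    """Surface area and semi-axes (c, b, b) of a prolate spheroid."""
    b = (3.0 * volume / (4.0 * math.pi * aspect)) ** (1.0 / 3.0)
    c = aspect * b
    if aspect == 1.0:
        area = math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0)
    else:
        e = math.sqrt(1.0 - (b / c) ** 2)
        area = 2.0 * math.pi * b**2 * (1.0 + (c / (b * e)) * math.asin(e))
    return area, np.array([c, b, b])


def _sample_population(
    rng: np.random.Generator,
    arc_pos: np.ndarray,
    arc_dist: np.ndarray,
    *,
    total_volume: float,
    n_base: float,
    fragmentation: float,
    sigma0: float,
    elongation: float,
    perinuclear_bias: float,
    hyperfused: bool,
    hyperfused_volume: float,
    min_separation: float | None,
    id_prefix: str,
    perinuclear_radius: float = 10.0,
) -> tuple[list[OrganelleRecord], np.ndarray, np.ndarray]:
    """Place one organelle population; returns (records, long-axis dirs, semi-axes)."""
    if total_volume <= 0:
        return [], np.zeros((0, 3)), np.zeros((0, 3))
    n = max(1, int(rng.poisson(n_base * fragmentation)))
    sigma2 = max(0.05, sigma0**2 + SIGMA_FRAG_COUPLING * math.log(fragmentation))
    raw = rng.lognormal(mean=0.0, sigma=math.sqrt(sigma2), size=n)
    if hyperfused and n >= 2:
        h = min(hyperfused_volume, 0.8 * total_volume)
        raw[0] = raw[1:].sum() * h / (total_volume - h)
    volumes = total_volume * raw / raw.sum()  # exact total by construction

    near = np.flatnonzero(arc_dist <= perinuclear_radius)
    if near.size == 0:
        near = np.array([int(np.argmin(arc_dist))])
    records: list[OrganelleRecord] = []
    dirs = np.zeros((n, 3))
    axes = np.zeros((n, 3))
    placed_pos: list[np.ndarray] = []
    placed_reach: list[float] = []
    for i in range(n):
        area, semi = _prolate_surface_area(float(volumes[i]), elongation)
        reach = float(semi[0])
        for _attempt in range(800):
            perinuclear_draw = rng.random() < perinuclear_bias
            pool = near if perinuclear_draw else np.arange(arc_pos.shape[0])
            pos = arc_pos[int(rng.choice(pool))]
            if min_separation is not None:
                # jitter off the arc relieves crowding along thin processes;
                # the jitter scale escalates as attempts fail
                pos = pos + rng.normal(0.0, 0.4 + _attempt / 150.0, size=3)
                if perinuclear_draw and np.linalg.norm(pos) > perinuclear_radius:
                    continue
                ok = all(
                    np.linalg.norm(pos - q) >= reach + r + min_separation
                    for q, r in zip(placed_pos, placed_reach)
                )
                if ok:
                    break
            else:
                break
        else:
            raise DomainError(
                "could not place organelles with the requested min_separation"
            )
        placed_pos.append(pos)
        placed_reach.append(reach)
        dirs[i] = _random_unit(rng)
        axes[i] = semi
        records.append(OrganelleRecord(
            organelle_id=f"{id_prefix}{i + 1}",
            volume=float(volumes[i]),
            surface_area=area,
            sphericity=wadell_sphericity(float(volumes[i]), area),
            centroid=pos.copy(),
            distance_to_soma=float(np.linalg.norm(pos)),
        ))
    return records, dirs, axes


# ---------------------------------------------------------------------------
# Cell and cohort generation
# ---------------------------------------------------------------------------

def generate_cell(
    params: SyntheticCellParams,
    seed: int | None = None,
    cell_id: str = "cell",
) -> CellRecord:
    """One synthetic microglia: tree, mitochondria, vesicles, ground truth.

    Deterministic in (params, seed); ``seed`` defaults to ``params.seed``.
    The per-cell mitochondrial content target is the stated percentage times
    a lognormal factor with CV ``content_cv`` (mean 1); the drawn target is
    hit exactly by deterministic rescaling and recorded in the metadata.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    tree = _generate_tree(params, rng)
    arc_pos, arc_dist = _arc_points(tree)

    def _target(pct: float) -> float:
        if params.content_cv > 0:
            cv = params.content_cv
            pct = pct * float(np.exp(rng.normal(-0.5 * cv**2, cv)))
        return pct / 100.0 * params.cell_volume

    mito_total = _target(params.target_content_pct)
    ves_total = _target(params.vesicle_content_pct)
    if mito_total + ves_total >= params.cell_volume:
        raise DomainError("organelle content exceeds the cell volume")

    hyperfused = bool(rng.random() < params.hyperfused_fraction)
    mito, mito_dirs, mito_axes = _sample_population(
        rng, arc_pos, arc_dist,
        total_volume=mito_total,
        n_base=params.n_mito_base,
        fragmentation=params.fragmentation,
        sigma0=params.volume_sigma0,
        elongation=params.elongation,
        perinuclear_bias=params.perinuclear_bias,
        hyperfused=hyperfused,
        hyperfused_volume=params.hyperfused_volume,
        min_separation=params.min_separation,
        id_prefix="mito",
    )
    ves, ves_dirs, ves_axes = _sample_population(
        rng, arc_pos, arc_dist,
        total_volume=ves_total,
        n_base=params.n_vesicle_base,
        fragmentation=params.vesicle_fragmentation,
        sigma0=params.volume_sigma0,
        elongation=params.vesicle_elongation,
        perinuclear_bias=params.vesicle_perinuclear_bias,
        hyperfused=False,
        hyperfused_volume=0.0,
        min_separation=params.min_separation,
        id_prefix="cd68_",
    )
    return CellRecord(
        cell_id=cell_id,
        cell_volume=params.cell_volume,
        soma_center=np.zeros(3),
        soma_spot_diameter=2.0 * params.soma_radius,
        mitochondria=mito,
        vesicles=ves,
        filament=tree,
        metadata={
            "params": params,
            "hyperfused": hyperfused,
            "mito_total_volume": mito_total,
            "vesicle_total_volume": ves_total,
            "mito_dirs": mito_dirs,
            "mito_axes": mito_axes,
            "vesicle_dirs": ves_dirs,
            "vesicle_axes": ves_axes,
        },
    )


def generate_cohort(
    group_specs: dict[str, SyntheticCellParams],
    n_cells_per_group: int,
    seed: int = 0,
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Independent cells per group, each with its own derived seed.

    Returns the cells and a ground-truth table of the generating parameters
    per group (for planted-effect recovery tests).
    """
    if n_cells_per_group < 1:
        raise DomainError("n_cells_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    cells: list[CellRecord] = []
    truth_rows = []
    for group, params in group_specs.items():
        truth_rows.append({"group": group, **{
            k: v for k, v in params.__dict__.items() if isinstance(v, (int, float))
        }})
        for j in range(n_cells_per_group):
            child_seed = int(rng.integers(0, 2**31))
            cell = generate_cell(params, seed=child_seed, cell_id=f"{group}_{j}")
            cell.group = group
            cell.condition = group
            cells.append(cell)
    return cells, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

@dataclass
class RasterizedCell:
    cell_mask: VoxelImage
    mitochondria: VoxelImage
    vesicles: VoxelImage
    mito_truth: np.ndarray      # int labels, index = organelle order + 1
    vesicle_truth: np.ndarray
    origin: np.ndarray          # physical position of voxel (0,0,0) corner


def _paint_sphere(grid, origin, spacing, center, radius, value=1):
    lo = np.maximum(((center - radius - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(((center + radius - origin) / spacing).astype(int) + 2, grid.shape)
    if np.any(lo >= hi):
        return
    idx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum(
        ((idx[k] + 0.5) * spacing[k] + origin[k] - center[k]) ** 2 for k in range(3)
    )
    region = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region[d2 <= radius**2] = value


def _paint_ellipsoid(grid, origin, spacing, center, direction, semi_axes, value):
    c, b = float(semi_axes[0]), float(semi_axes[1])
    lo = np.maximum(((center - c - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(((center + c - origin) / spacing).astype(int) + 2, grid.shape)
    if np.any(lo >= hi):
        return
    idx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    rel = [(idx[k] + 0.5) * spacing[k] + origin[k] - center[k] for k in range(3)]
    proj = sum(rel[k] * direction[k] for k in range(3))          # along long axis
    r2 = sum(rel[k] ** 2 for k in range(3))
    inside = (proj / c) ** 2 + (r2 - proj**2) / b**2 <= 1.0
    region = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region[inside] = value


def rasterize_cell(
    cell: CellRecord,
    spacing: tuple[float, float, float] = FAST_SPACING,
    margin: float = 2.0,
) -> RasterizedCell:
    """Render a synthetic cell into voxel channels with ground-truth labels.

    The cell mask is the union of a tube along the tree (node radii), the
    soma sphere, and every organelle, so organelles always lie inside the
    mask.  Organelles are analytic prolate ellipsoids; the mitochondria and
    vesicle channels are binary intensity 1 with per-organelle label grids
    returned for segmentation ground truth.
    """
    if "mito_axes" not in cell.metadata:
        raise DomainError("rasterize_cell requires a synthetic cell with shape metadata")
    spacing_arr = np.asarray(spacing, dtype=float)
    tree = cell.filament
    if tree is None:
        raise DomainError("cell has no filament tree")
    node_pos = np.array([pos for _, pos, _ in tree.nodes.values()])
    node_rad = np.array([rad for _, _, rad in tree.nodes.values()])
    mins = [node_pos.min(axis=0) - node_rad.max()]
    maxs = [node_pos.max(axis=0) + node_rad.max()]
    for organelles, axes in (
        (cell.mitochondria, cell.metadata["mito_axes"]),
        (cell.vesicles, cell.metadata["vesicle_axes"]),
    ):
        for o, semi in zip(organelles, axes):
            mins.append(o.centroid - semi[0])
            maxs.append(o.centroid + semi[0])
    lo = np.min(mins, axis=0) - margin
    hi = np.max(maxs, axis=0) + margin
    shape = np.ceil((hi - lo) / spacing_arr).astype(int)
    if int(np.prod(shape)) > 600_000_000:
        raise DomainError(f"rasterization grid too large: {tuple(shape)}")
    origin = lo

    mask = np.zeros(shape, dtype=np.uint8)
    mito_ch = np.zeros(shape, dtype=np.uint8)
    ves_ch = np.zeros(shape, dtype=np.uint8)
    mito_truth = np.zeros(shape, dtype=np.int32)
    ves_truth = np.zeros(shape, dtype=np.int32)

    # tree tube: spheres along each segment
    step = float(spacing_arr.min()) / 2.0
    for start, end in tree.edges():
        length = float(np.linalg.norm(end - start))
        n = max(1, int(math.ceil(length / step)))
        for t in np.linspace(0.0, 1.0, n + 1):
            _paint_sphere(mask, origin, spacing_arr, start + t * (end - start),
                          float(node_rad.min()), 1)
    _paint_sphere(mask, origin, spacing_arr, tree.root_position,
                  float(tree.nodes[tree.root][2]), 1)

    for channel, truth, organelles, dirs, axes in (
        (mito_ch, mito_truth, cell.mitochondria,
         cell.metadata["mito_dirs"], cell.metadata["mito_axes"]),
        (ves_ch, ves_truth, cell.vesicles,
         cell.metadata["vesicle_dirs"], cell.metadata["vesicle_axes"]),
    ):
        for i, o in enumerate(organelles):
            if np.any(o.centroid - axes[i][0] < lo) or np.any(o.centroid + axes[i][0] > hi):
                raise DomainError(f"organelle {o.organelle_id} outside the field of view")
            _paint_ellipsoid(channel, origin, spacing_arr, o.centroid, dirs[i], axes[i], 1)
            _paint_ellipsoid(truth, origin, spacing_arr, o.centroid, dirs[i], axes[i], i + 1)
    mask |= (mito_ch > 0) | (ves_ch > 0)

    sp = tuple(float(s) for s in spacing_arr)
    return RasterizedCell(
        cell_mask=VoxelImage(mask, sp),
        mitochondria=VoxelImage(mito_ch, sp),
        vesicles=VoxelImage(ves_ch, sp),
        mito_truth=mito_truth,
        vesicle_truth=ves_truth,
        origin=origin,
    )


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def generate_qpcr(
    true_fold_changes: dict[str, float],
    noise_sd: float = 0.1,
    n_samples: int = 6,
    seed: int = 0,
    reference_gene: str = "Gapdh",
    control_group: str = "WT_naive",
    treated_group: str = "treated",
    n_replicates: int = 3,
) -> list[QpcrRecord]:
    """Cq tables with planted fold changes for one control/treated contrast.

    Cq = base − log2(expression) + Gaussian noise per technical replicate;
    control samples express every gene at 1, treated samples at the planted
    fold.  The reference gene's own fold change is forced to 1.
    """
    rng = np.random.default_rng(seed)
    genes = {reference_gene: 1.0}
    genes.update({g: f for g, f in true_fold_changes.items() if g != reference_gene})
    base_cq = {reference_gene: 18.0}
    for i, g in enumerate(g for g in genes if g != reference_gene):
        base_cq[g] = 22.0 + 0.5 * i
    records: list[QpcrRecord] = []
    for group, is_treated in ((control_group, False), (treated_group, True)):
        for s in range(n_samples):
            sample_id = f"{group}_s{s + 1}"
            for gene, fold in genes.items():
                expr = fold if (is_treated and gene != reference_gene) else 1.0
                mean = base_cq[gene] - math.log2(expr)
                reps = mean + rng.normal(0.0, noise_sd, size=n_replicates)
                records.append(QpcrRecord(
                    sample_id=sample_id, group=group, gene=gene,
                    cq_replicates=[float(c) for c in reps],
                ))
    return records
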