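"""Domain types and readers/writers for the formats the pipeline touches.

All physical quantities are in micrometres (μm, μm², μm³).  Voxel spacing is
stored axis-ordered ``(z, y, x)`` and applied at measurement time; volumes are
never resampled.  Voxel index ``(0, 0, 0)`` maps to the physical position
``spacing / 2`` (voxel-center convention), which keeps centroids unbiased.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("mitoglia")


class MitogliaError(Exception):
    """Base class for pipeline errors."""


class FormatError(MitogliaError):
    """A file does not conform to the expected dialect."""


class DomainError(MitogliaError):
    """An input violates a precondition of an operation."""


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Sentinel for per-cell metrics that are undefined (e.g. on an empty cell).
#: Kept distinct from 0.0, which would bias group medians.
UNDEFINED = float("nan")


def is_undefined(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class OrganelleRecord:
    """One segmented 3D organelle or vesicle.

    ``sphericity`` is the Wadell sphericity pi^(1/3) (6V)^(2/3) / A; it is 1
    for a perfect ball and lower for elongated shapes.  On coarsely rasterized
    objects the triangulated surface area can undershoot, so values slightly
    above 1 are possible and tolerated (discretization effect, not an error).
    """

    organelle_id: str
    volume: float
    surface_area: float
    sphericity: float
    centroid: np.ndarray  # (z, y, x) in μm
    distance_to_soma: float | None = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.volume <= 0:
            raise DomainError(f"organelle {self.organelle_id}: volume must be > 0")
        if self.surface_area <= 0:
            raise DomainError(f"organelle {self.organelle_id}: surface_area must be > 0")
        if self.sphericity <= 0:
            raise DomainError(f"organelle {self.organelle_id}: sphericity must be > 0")
        if not np.all(np.isfinite(self.centroid)) or self.centroid.shape != (3,):
            raise DomainError(f"organelle {self.organelle_id}: centroid must be a finite 3-vector")
        if self.distance_to_soma is not None and self.distance_to_soma < 0:
            raise DomainError(f"organelle {self.organelle_id}: distance_to_soma must be >= 0")


@dataclass
class FilamentTree:
    """A traced cell skeleton rooted at the soma.

    ``nodes`` maps node id -> (parent id or None for the root, position μm,
    radius μm).  Exactly one root; every parent exists; acyclic.
    """

    nodes: dict[int, tuple[int | None, np.ndarray, float]]

    def __post_init__(self) -> None:
        roots = [nid for nid, (par, _, _) in self.nodes.items() if par is None]
        if len(roots) != 1:
            raise FormatError(f"filament tree must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        for nid, (par, _, _) in self.nodes.items():
            if par is not None and par not in self.nodes:
                raise FormatError(f"node {nid} references missing parent {par}")
        # acyclicity: walk each node to the root
        for nid in self.nodes:
            seen = set()
            cur: int | None = nid
            while cur is not None:
                if cur in seen:
                    raise FormatError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = self.nodes[cur][0]

    @property
    def root(self) -> int:
        return self._root

    @property
    def root_position(self) -> np.ndarray:
        return self.nodes[self._root][1]

    def edges(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Parent->child straight segments as (start, end) position pairs."""
        return [
            (self.nodes[par][1], pos)
            for nid, (par, pos, _) in self.nodes.items()
            if par is not None
        ]

    def n_edges(self) -> int:
        return sum(1 for _, (par, _, _) in self.nodes.items() if par is not None)


@dataclass
class VoxelImage:
    """A 3D scalar grid with anisotropic voxel spacing (z, y, x) in μm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise DomainError("voxel image must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DomainError("spacing must be three positive values (z, y, x)")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class CellRecord:
    """One microglia with its organelle populations and optional tracing."""

    cell_id: str
    cell_volume: float
    soma_center: np.ndarray
    genotype: str = "WT"
    condition: str = "naive"
    sex: str = "male"
    layer: str = "IPL"
    group: str = ""
    soma_spot_diameter: float = 5.0  # the nucleus marker spot, μm
    mitochondria: list[OrganelleRecord] = field(default_factory=list)
    vesicles: list[OrganelleRecord] = field(default_factory=list)
    filament: FilamentTree | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        if self.cell_volume <= 0:
            raise DomainError(f"cell {self.cell_id}: cell_volume must be > 0")
        if self.soma_spot_diameter <= 0:
            raise DomainError(f"cell {self.cell_id}: soma_spot_diameter must be > 0")


@dataclass
class QpcrRecord:
    """Cq values for one (sample, gene), typically a technical triplicate."""

    sample_id: str
    group: str
    gene: str
    cq_replicates: list[float]
    batch: str = "1"

    def __post_init__(self) -> None:
        if not self.cq_replicates:
            raise DomainError(f"{self.sample_id}/{self.gene}: cq_replicates is empty")
        for cq in self.cq_replicates:
            if not (0 < cq <= 40):
                raise DomainError(f"{self.sample_id}/{self.gene}: Cq {cq} outside (0, 40]")

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq_replicates))


# ---------------------------------------------------------------------------
# Organelle statistics tables (CSV)
# ---------------------------------------------------------------------------

_ORGANELLE_COLUMNS = [
    "cell_id", "organelle_id", "volume", "surface_area", "sphericity",
    "cx", "cy", "cz",
]
_NUMERIC_COLUMNS = ["volume", "surface_area", "sphericity", "cx", "cy", "cz"]


def read_organelle_table(path: str | Path) -> dict[str, list[OrganelleRecord]]:
    """Read a per-organelle statistics CSV grouped by cell id.

    Expects header columns ``cell_id, organelle_id, volume, surface_area,
    sphericity, cx, cy, cz`` and optionally ``distance_to_soma``.  Centroid
    columns are (x, y, z); records store centroids as (z, y, x).
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "organelle_id": str})
    for col in _ORGANELLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    for col in _NUMERIC_COLUMNS + (["distance_to_soma"] if "distance_to_soma" in df.columns else []):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        elif df[col].isna().any() and col != "distance_to_soma":
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0]) + 2
        else:
            df[col] = vals
            continue
        raise FormatError(f"{path}: non-numeric value in column '{col}' at row {row}")

    out: dict[str, list[OrganelleRecord]] = {}
    has_dist = "distance_to_soma" in df.columns
    for i, row in df.iterrows():
        dist = None
        if has_dist and pd.notna(row["distance_to_soma"]):
            dist = float(row["distance_to_soma"])
        rec = OrganelleRecord(
            organelle_id=str(row["organelle_id"]),
            volume=float(row["volume"]),
            surface_area=float(row["surface_area"]),
            sphericity=float(row["sphericity"]),
            centroid=np.array([row["cz"], row["cy"], row["cx"]], dtype=float),
            distance_to_soma=dist,
        )
        out.setdefault(str(row["cell_id"]), []).append(rec)
    return out


def write_organelle_table(
    records: Mapping[str, Sequence[OrganelleRecord]], path: str | Path
) -> None:
    rows = []
    for cell_id, recs in records.items():
        for r in recs:
            rows.append({
                "cell_id": cell_id,
                "organelle_id": r.organelle_id,
                "volume": r.volume,
                "surface_area": r.surface_area,
                "sphericity": r.sphericity,
                "cx": r.centroid[2],
                "cy": r.centroid[1],
                "cz": r.centroid[0],
                "distance_to_soma": "" if r.distance_to_soma is None else r.distance_to_soma,
            })
    pd.DataFrame(rows, columns=_ORGANELLE_COLUMNS + ["distance_to_soma"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# SWC filament tracings
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> FilamentTree:
    """Read an SWC tracing: ``id type x y z radius parent``, parent -1 = root.

    Coordinates are in μm; positions are stored (z, y, x).
    """
    nodes: dict[int, tuple[int | None, np.ndarray, float]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                nid = int(parts[0])
                x, y, z, radius = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable numeric field") from exc
            if nid in nodes:
                raise FormatError(f"{path}:{lineno}: duplicate node id {nid}")
            nodes[nid] = (None if parent == -1 else parent, np.array([z, y, x]), radius)
    if not nodes:
        raise FormatError(f"{path}: no nodes")
    return FilamentTree(nodes=nodes)


def write_swc(tree: FilamentTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(tree.nodes):
            par, pos, radius = tree.nodes[nid]
            ntype = 1 if par is None else 3
            fh.write(
                f"{nid} {ntype} {pos[2]:.6f} {pos[1]:.6f} {pos[0]:.6f} "
                f"{radius:.6f} {-1 if par is None else par}\n"
            )


# ---------------------------------------------------------------------------
# Voxel volumes (TIFF)
# ---------------------------------------------------------------------------

def read_tiff(path: str | Path, spacing: tuple[float, float, float]) -> VoxelImage:
    """Read a TIFF stack; spacing (z, y, x) μm is supplied by the caller."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, ...]
    return VoxelImage(data=data, spacing=spacing)


def write_tiff(image: VoxelImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), image.data, photometric="minisblack")


# ---------------------------------------------------------------------------
# qPCR Cq tables (tidy CSV: one row per technical replicate)
# ---------------------------------------------------------------------------

_QPCR_COLUMNS = ["sample_id", "group", "gene", "cq"]


def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    """Read a tidy Cq table (columns sample_id, group, gene, cq[, batch])."""
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "gene": str})
    for col in _QPCR_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if "batch" not in df.columns:
        df["batch"] = "1"
    df["batch"] = df["batch"].astype(str)
    cq = pd.to_numeric(df["cq"], errors="coerce")
    if cq.isna().any():
        row = int(np.flatnonzero(cq.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: non-numeric value in column 'cq' at row {row}")
    df["cq"] = cq
    records = []
    for (sample, group, gene, batch), sub in df.groupby(
        ["sample_id", "group", "gene", "batch"], sort=False
    ):
        records.append(QpcrRecord(
            sample_id=sample, group=group, gene=gene,
            cq_replicates=[float(v) for v in sub["cq"]], batch=batch,
        ))
    return records


def write_qpcr_table(records: Iterable[QpcrRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "group": r.group, "gene": r.gene,
         "cq": cq, "batch": r.batch}
        for r in records
        for cq in r.cq_replicates
    ]
    pd.DataFrame(rows, columns=_QPCR_COLUMNS + ["batch"]).to_csv(path, index=False)
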