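"""Per-cell mitochondrial and CD68-vesicle metrics.

Three metric families per cell:

* connectivity — median organelle volume, organelle count, mean sphericity,
  and the largest organelle volume (a marker for hyperfused networks);
* content — total organelle volume as a percentage of cell volume;
* localization — Euclidean distance of each organelle centroid from the soma
  spot center, the perinuclear volume fraction (distance ≤ 10 μm by default),
  and a distance-binned volume profile (10 μm bins, normalized to total).

Vesicles use the same code paths as mitochondria.  Metrics on an empty
organelle list are NaN (an explicit undefined marker — zeros would bias group
medians), except the count, which is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import CellRecord, DomainError, OrganelleRecord, UNDEFINED

#: Perinuclear boundary: distance ≤ 10 μm from the soma spot center counts
#: as perinuclear (closed boundary; the soma spot sits at the nucleus, so
#: this reaches at most ~5–7 μm beyond the nuclear membrane).
DEFAULT_PERINUCLEAR_RADIUS = 10.0
DEFAULT_BIN_WIDTH = 10.0


@dataclass
class CellMetrics:
    """The per-cell summary the group comparisons and the PCA consume."""

    median_mito_volume: float = UNDEFINED
    n_mito: int = 0
    mean_sphericity: float = UNDEFINED
    largest_mito_volume: float = UNDEFINED
    pct_mito_volume: float = UNDEFINED
    pct_cd68_volume: float = UNDEFINED
    perinuclear_pct: float = UNDEFINED
    perinuclear_radius: float = DEFAULT_PERINUCLEAR_RADIUS
    binned_profile: np.ndarray = field(default_factory=lambda: np.zeros(0))


def connectivity_metrics(mitochondria: list[OrganelleRecord]) -> dict[str, float]:
    """Median volume, count, mean sphericity, and largest volume per cell."""
    if not mitochondria:
        return {
            "median_mito_volume": UNDEFINED,
            "n_mito": 0,
            "mean_sphericity": UNDEFINED,
            "largest_mito_volume": UNDEFINED,
        }
    volumes = np.array([o.volume for o in mitochondria])
    sphericities = np.array([o.sphericity for o in mitochondria])
    return {
        "median_mito_volume": float(np.median(volumes)),
        "n_mito": len(mitochondria),
        "mean_sphericity": float(sphericities.mean()),
        "largest_mito_volume": float(volumes.max()),
    }


def content_metrics(
    organelles: list[OrganelleRecord], cell_volume: float
) -> dict[str, float]:
    """Total organelle volume and its percentage of the cell volume."""
    if cell_volume <= 0:
        raise DomainError("cell_volume must be > 0")
    total = float(sum(o.volume for o in organelles))
    return {"total_volume": total, "pct_of_cell": 100.0 * total / cell_volume}


def _bin_index(distance: float, bin_width: float) -> int:
    """Bins [0, w], (w, 2w], ...: bin 0 is closed at both edges."""
    if distance <= bin_width:
        return 0
    return int(math.ceil(distance / bin_width)) - 1


def localization_metrics(
    organelles: list[OrganelleRecord],
    soma_center: np.ndarray,
    radius: float = DEFAULT_PERINUCLEAR_RADIUS,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict:
    """Distances to soma, perinuclear volume fraction, and binned profile.

    perinuclear_pct = 100 × Σ_{d ≤ radius} volume / Σ volume.  The profile's
    bin k holds the volume fraction at distances in (k·w, (k+1)·w] (bin 0
    closed at 0); it sums to 1 whenever organelles exist.
    """
    if radius <= 0 or bin_width <= 0:
        raise DomainError("radius and bin_width must be > 0")
    soma_center = np.asarray(soma_center, dtype=float)
    if not organelles:
        return {
            "distances": np.zeros(0),
            "perinuclear_pct": UNDEFINED,
            "binned_profile": np.zeros(0),
        }
    centroids = np.array([o.centroid for o in organelles])
    volumes = np.array([o.volume for o in organelles])
    distances = np.linalg.norm(centroids - soma_center, axis=1)
    total = volumes.sum()
    perinuclear_pct = 100.0 * volumes[distances <= radius].sum() / total
    n_bins = max(1, _bin_index(float(distances.max()), bin_width) + 1)
    profile = np.zeros(n_bins)
    for d, v in zip(distances, volumes):
        profile[_bin_index(float(d), bin_width)] += v
    profile /= total
    return {
        "distances": distances,
        "perinuclear_pct": float(perinuclear_pct),
        "binned_profile": profile,
    }


def annotate_distances(
    organelles: list[OrganelleRecord], soma_center: np.ndarray
) -> None:
    """Fill ``distance_to_soma`` in place from centroid–soma distances."""
    soma_center = np.asarray(soma_center, dtype=float)
    for o in organelles:
        o.distance_to_soma = float(np.linalg.norm(o.centroid - soma_center))


def compute_cell_metrics(
    cell: CellRecord,
    radius: float = DEFAULT_PERINUCLEAR_RADIUS,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> CellMetrics:
    """All per-cell metrics for one CellRecord (mitochondria + vesicles)."""
    conn = connectivity_metrics(cell.mitochondria)
    mito_content = content_metrics(cell.mitochondria, cell.cell_volume)
    cd68_content = content_metrics(cell.vesicles, cell.cell_volume)
    loc = localization_metrics(cell.mitochondria, cell.soma_center, radius, bin_width)
    annotate_distances(cell.mitochondria, cell.soma_center)
    annotate_distances(cell.vesicles, cell.soma_center)
    return CellMetrics(
        median_mito_volume=conn["median_mito_volume"],
        n_mito=conn["n_mito"],
        mean_sphericity=conn["mean_sphericity"],
        largest_mito_volume=conn["largest_mito_volume"],
        pct_mito_volume=mito_content["pct_of_cell"],
        pct_cd68_volume=cd68_content["pct_of_cell"],
        perinuclear_pct=loc["perinuclear_pct"],
        perinuclear_radius=radius,
        binned_profile=loc["binned_profile"],
    )
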