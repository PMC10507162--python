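"""Voxel-channel segmentation into per-cell organelle records.

The stand-in for interactive surface creation: the channel is restricted to
the cell mask, optionally Gaussian-smoothed at a physical "surface detail"
scale, thresholded, and connected components are labeled and measured.
Surface area comes from a marching-cubes triangulation of each component
(voxel-face counting overestimates the area of a ball by ~50% and would
corrupt sphericity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core_io import DomainError, OrganelleRecord, VoxelImage

logger = logging.getLogger("mitoglia")

#: Surface-detail smoothing scales (μm) used for the three channel kinds.
DEFAULT_DETAIL_LEVELS = {"cell": 0.5, "mitochondria": 0.2, "vesicles": 0.4}

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentationParams:
    """Knobs of the thresholding segmentation.

    threshold      absolute intensity cutoff (the source workflow's wizard
                   threshold; always a user/config input).
    min_volume     components with physical volume strictly below this are
                   dropped (μm³).
    connectivity   voxel adjacency: 6 (faces), 18 (+edges), 26 (+corners).
    detail_level   Gaussian sigma in μm applied before thresholding; 0
                   disables smoothing.
    """

    threshold: float
    min_volume: float = 0.0
    connectivity: int = 26
    detail_level: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise DomainError("threshold must be finite")
        if self.min_volume < 0:
            raise DomainError("min_volume must be >= 0")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise DomainError("connectivity must be one of 6, 18, 26")
        if self.detail_level < 0:
            raise DomainError("detail_level must be >= 0")


def segment_cell_channels(
    cell_mask: VoxelImage, channel: VoxelImage, params: SegmentationParams
) -> np.ndarray:
    """Label organelle components of ``channel`` inside ``cell_mask``.

    Returns an integer grid with contiguous positive labels (0 = background).
    Steps: zero outside the mask, Gaussian-smooth at ``detail_level`` (μm,
    converted to voxels per axis), threshold (> threshold), re-apply the mask,
    label with the stated connectivity, drop components below ``min_volume``,
    and relabel contiguously preserving original label order.
    """
    if cell_mask.data.shape != channel.data.shape:
        raise DomainError(
            f"mask shape {cell_mask.data.shape} != channel shape {channel.data.shape}"
        )
    if cell_mask.spacing != channel.spacing:
        raise DomainError("mask and channel must share voxel spacing")

    mask = cell_mask.data > 0
    if not mask.any():
        logger.warning("cell mask is empty: returning empty labeling")
        return np.zeros(channel.data.shape, dtype=np.int32)

    img = np.where(mask, channel.data.astype(float), 0.0)
    if params.detail_level > 0:
        sigma_vox = [params.detail_level / s for s in channel.spacing]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    fg = (img > params.threshold) & mask

    labels = measure.label(fg, connectivity=_CONNECTIVITY_RANK[params.connectivity])
    labels = labels.astype(np.int32)
    if params.min_volume > 0 and labels.max() > 0:
        voxvol = channel.voxel_volume
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts * voxvol >= params.min_volume)
        keep = keep[keep > 0]
        remap = np.zeros(counts.size, dtype=np.int32)
        remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
        labels = remap[labels]
    return labels


def _component_surface_area(
    component: np.ndarray, spacing: tuple[float, float, float]
) -> float:
    """Triangulated isosurface area (level 0.5) of a padded binary component.

    The binary field is lightly Gaussian-smoothed (sigma = 1 voxel) before
    meshing: marching cubes on raw binary data carries a staircase bias of
    roughly +8% area for balls that does not vanish with refinement, while
    the smoothed isosurface converges to the true area.  Components too small
    to survive smoothing (peak below the iso-level) fall back to the
    unsmoothed mesh.
    """
    padded = np.pad(component.astype(np.float32), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def wadell_sphericity(volume: float, surface_area: float) -> float:
    """pi^(1/3) (6V)^(2/3) / A — 1 for a ball, lower for elongated shapes."""
    return float(math.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface_area)


def measure_components(
    labels: np.ndarray,
    spacing: tuple[float, float, float],
    id_prefix: str = "org",
) -> list[OrganelleRecord]:
    """Measure volume, surface area, sphericity and centroid per label.

    Volume is voxel count × voxel volume; the centroid is the unweighted mean
    of voxel centers, with voxel index (0,0,0) at physical position
    spacing/2.  Surface area comes from a marching-cubes mesh of the binary
    component with the physical spacing applied.
    """
    spacing = tuple(float(s) for s in spacing)
    voxvol = float(np.prod(spacing))
    records: list[OrganelleRecord] = []
    if labels.size == 0 or labels.max() == 0:
        return records
    # bounding boxes via find_objects keep marching cubes local per component
    slices = ndimage.find_objects(labels)
    for lab, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        component = labels[slc] == lab
        n_vox = int(component.sum())
        volume = n_vox * voxvol
        area = _component_surface_area(component, spacing)
        idx = np.argwhere(component).astype(float)
        offset = np.array([s.start for s in slc], dtype=float)
        centroid = (idx.mean(axis=0) + offset + 0.5) * np.asarray(spacing)
        records.append(OrganelleRecord(
            organelle_id=f"{id_prefix}{lab}",
            volume=volume,
            surface_area=area,
            sphericity=wadell_sphericity(volume, area),
            centroid=centroid,
        ))
    return records
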