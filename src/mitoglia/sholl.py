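"""3D Sholl analysis of filament tracings and the PCA-guided Sholl index.

Intersections are counted as strict crossings of straight parent–child
segments with concentric spheres at 1 μm radius steps, truncated at 60 μm.
The Sholl index is the fraction of all intersections that fall in the
11–20 μm radial band — the band with the greatest first-axis PCA loading on
per-cell-normalized binned Sholl curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DomainError, FilamentTree, UNDEFINED

DEFAULT_STEP = 1.0
DEFAULT_R_MAX = 60.0
DEFAULT_BAND = (11.0, 20.0)


@dataclass
class ShollCurve:
    """Intersection counts at radii step, 2·step, ..., r_max."""

    counts: np.ndarray
    step: float = DEFAULT_STEP
    r_max: float = DEFAULT_R_MAX

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.step <= 0:
            raise DomainError("step must be > 0")
        n = int(round(self.r_max / self.step))
        if self.counts.shape != (n,):
            raise DomainError(f"expected {n} counts for r_max={self.r_max}, step={self.step}")
        if (self.counts < 0).any():
            raise DomainError("counts must be non-negative")

    @property
    def radii(self) -> np.ndarray:
        return self.step * np.arange(1, self.counts.size + 1)


def _segment_crossings(p0: np.ndarray, p1: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Number of strict crossings of the segment p0→p1 with each sphere.

    Solves |p0 + t (p1 − p0)|² = r² and counts distinct roots strictly inside
    (0, 1); a tangency (double root) does not cross.
    """
    v = p1 - p0
    a = float(v @ v)
    out = np.zeros(radii.size, dtype=int)
    if a == 0.0:
        return out
    b = 2.0 * float(p0 @ v)
    c0 = float(p0 @ p0)
    disc = b * b - 4.0 * a * (c0 - radii**2)
    pos = disc > 0
    if not pos.any():
        return out
    sq = np.sqrt(disc[pos])
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    out[pos] = ((t1 > 0) & (t1 < 1)).astype(int) + ((t2 > 0) & (t2 < 1)).astype(int)
    return out


def sholl_curve(
    tree: FilamentTree,
    center: np.ndarray | None = None,
    step: float = DEFAULT_STEP,
    r_max: float = DEFAULT_R_MAX,
) -> ShollCurve:
    """Count sphere crossings of the tracing at radii step, 2·step, ..., r_max.

    ``center`` defaults to the tree root (the soma).  Segments are straight
    lines between node positions; a segment whose endpoint distances straddle
    a radius crosses once, and a segment that dips through a sphere crosses
    twice.
    """
    if step <= 0:
        raise DomainError("step must be > 0")
    center = tree.root_position if center is None else np.asarray(center, dtype=float)
    n = int(round(r_max / step))
    radii = step * np.arange(1, n + 1)
    counts = np.zeros(n, dtype=int)
    for start, end in tree.edges():
        counts += _segment_crossings(start - center, end - center, radii)
    return ShollCurve(counts=counts, step=step, r_max=r_max)


def sholl_index(curve: ShollCurve, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Fraction of all intersections at radii within ``band`` (inclusive).

    Both the band sum and the total are taken over the truncated curve.
    Returns the undefined marker (NaN) for an all-zero curve.
    """
    total = int(curve.counts.sum())
    if total == 0:
        return UNDEFINED
    radii = curve.radii
    in_band = (radii >= band[0]) & (radii <= band[1])
    return float(curve.counts[in_band].sum() / total)


def band_profile(curve: ShollCurve, band_width: float = 10.0) -> np.ndarray:
    """Per-cell-normalized intersection fractions in consecutive radial bands.

    Bands partition (0, r_max] into widths of ``band_width``; fractions sum
    to 1 for a non-degenerate curve.
    """
    total = curve.counts.sum()
    if total == 0:
        raise DomainError("cannot normalize an all-zero Sholl curve")
    radii = curve.radii
    n_bands = int(np.ceil(curve.r_max / band_width))
    out = np.zeros(n_bands)
    for k in range(n_bands):
        lo, hi = k * band_width, (k + 1) * band_width
        sel = (radii > lo) & (radii <= hi)
        out[k] = curve.counts[sel].sum() / total
    return out


def dominant_bin_by_pca(profiles: np.ndarray) -> tuple[int, float]:
    """The bin with the largest |loading| on the first principal axis.

    ``profiles`` is a cells × bins matrix of per-cell-normalized values (rows
    sum to 1).  Columns are mean-centered, the first right singular vector is
    the leading loading pattern, and the returned loading is sign-fixed
    positive.  Ties break toward the lower bin index.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DomainError("need a 2D matrix with at least 2 rows")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        raise DomainError("degenerate profile matrix: no variance across cells")
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    bin_index = int(np.argmax(np.abs(loading)))
    return bin_index, float(abs(loading[bin_index]))
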