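"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive implementations (breadth-first flood
fill, dense arc-length sampling, direct eigendecomposition) kept independent
of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitoglia import FilamentTree


# ---------------------------------------------------------------------------
# flood-fill connected-components oracle
# ---------------------------------------------------------------------------

def _offsets(connectivity: int) -> list[tuple[int, int, int]]:
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                rank = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and rank > 1:
                    continue
                if connectivity == 18 and rank > 2:
                    continue
                out.append((dz, dy, dx))
    return out


def flood_fill_components(foreground: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a binary grid as sets of voxel index tuples."""
    offsets = _offsets(connectivity)
    shape = foreground.shape
    remaining = {tuple(v) for v in np.argwhere(foreground)}
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if (
                    0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2] and nb in remaining
                ):
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(frozenset(comp))
    return components


def label_grid_components(labels: np.ndarray) -> list[frozenset]:
    """Voxel membership sets of a labeled grid, for comparison with the oracle."""
    return [
        frozenset(tuple(v) for v in np.argwhere(labels == lab))
        for lab in range(1, int(labels.max()) + 1)
    ]


# ---------------------------------------------------------------------------
# dense-sampling Sholl crossing oracle
# ---------------------------------------------------------------------------

def sampled_sholl_counts(
    tree: FilamentTree, center: np.ndarray, radii: np.ndarray, ds: float = 0.01
) -> np.ndarray:
    """Count sign changes of (distance − r) along densely sampled segments."""
    counts = np.zeros(radii.size, dtype=int)
    for start, end in tree.edges():
        length = float(np.linalg.norm(end - start))
        if length == 0:
            continue
        n = max(2, int(np.ceil(length / ds)) + 1)
        t = np.linspace(0.0, 1.0, n)
        pts = start[None, :] + t[:, None] * (end - start)[None, :]
        d = np.linalg.norm(pts - center, axis=1)
        for i, r in enumerate(radii):
            sign = np.sign(d - r)
            counts[i] += int(np.sum(sign[:-1] * sign[1:] < 0))
    return counts


def random_tree(rng: np.random.Generator, n_nodes: int = 40, scale: float = 15.0) -> FilamentTree:
    """A random valid filament tree rooted at the origin."""
    nodes = {0: (None, np.zeros(3), 2.0)}
    for nid in range(1, n_nodes):
        parent = int(rng.integers(0, nid))
        pos = nodes[parent][1] + rng.normal(scale=scale / np.sqrt(n_nodes), size=3)
        nodes[nid] = (parent, pos, 0.4)
    return FilamentTree(nodes=nodes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
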