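"""Periodic-boundary distance kernels shared by the analysis modules.

All routines assume an orthorhombic box and apply the minimum-image
convention in all three dimensions.  The fast paths use a periodic
``scipy.spatial.cKDTree``; each has a brute-force all-pairs counterpart
used as an independent oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box) per dimension."""
    return np.mod(coords, box)


def wrap_strict(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap into [0, box) exactly (float-rounding at the edge sent to 0)."""
    wrapped = wrap(coords, box)
    return np.where(wrapped >= box, 0.0, wrapped)


def periodic_tree(coords: np.ndarray, box: np.ndarray) -> cKDTree:
    return cKDTree(wrap_strict(coords, box), boxsize=box)


def min_image_deltas(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors a[i] - b[j] -> (len(a), len(b), 3)."""
    d = a[:, None, :] - b[None, :, :]
    return d - box * np.round(d / box)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances (len(a), len(b))."""
    return np.linalg.norm(min_image_deltas(a, b, box), axis=-1)


def min_cross_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum PBC distance over all (a, b) pairs, via neighbor search."""
    tree = periodic_tree(b, box)
    d, _ = tree.query(wrap_strict(a, box), k=1)
    return float(np.min(d))


def min_cross_distance_brute(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Brute-force counterpart of :func:`min_cross_distance` (oracle)."""
    best = np.inf
    # chunk the outer loop to bound memory on large groups
    for start in range(0, len(a), 512):
        block = pairwise_distances(a[start:start + 512], b, box)
        best = min(best, float(block.min()))
    return best


def neighbors_within(
    query: np.ndarray, targets: np.ndarray, box: np.ndarray, cutoff: float
) -> np.ndarray:
    """Boolean mask over ``targets``: any query point within ``cutoff``."""
    tree = periodic_tree(targets, box)
    hit = np.zeros(len(targets), dtype=bool)
    q = wrap_strict(query, box)
    for idx in tree.query_ball_point(q, r=cutoff):
        hit[idx] = True
    return hit


def min_distance_per_point(
    query: np.ndarray, targets: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """For each query point, PBC distance to its nearest target."""
    tree = periodic_tree(targets, box)
    d, _ = tree.query(wrap_strict(query, box), k=1)
    return np.asarray(d, dtype=float)
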