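"""Residue-residue minimum-distance contact maps of oligomers.

Cell (i, j) holds the minimum distance between any atom of accumulated
residue i and any atom of accumulated residue j; the map carries a
time-mean layer and a standard-deviation layer over the analysis
window.  Distances are plain Euclidean: each chain is treated as whole
(never split across periodic images), matching how oligomer
conformations are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import Frame, Trajectory


@dataclass
class ContactMap:
    """Symmetric per-residue distance map with mean and SD layers."""

    mean: np.ndarray  # (R, R) nm
    sd: np.ndarray  # (R, R) nm
    n_frames: int
    window: tuple[float, float]

    @property
    def n_residues(self) -> int:
        return self.mean.shape[0]

    def contact_fraction(self, threshold: float = 0.5) -> float:
        """Fraction of off-diagonal cells with mean distance <= threshold."""
        r = self.n_residues
        off = ~np.eye(r, dtype=bool)
        return float((self.mean[off] <= threshold).mean())


def _residue_keys(frame: Frame) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Accumulated residue ordering and per-protein-atom row index."""
    mask = frame.atoms_of_type("protein")
    if not mask.any():
        raise ValueError("frame contains no protein atoms")
    chains = frame.chain_id[mask]
    resids = frame.residue_index[mask]
    keys: list[tuple[str, int]] = []
    for c in sorted(set(chains)):
        for r in sorted(set(int(x) for x, ch in zip(resids, chains) if ch == c)):
            keys.append((c, r))
    index = {k: i for i, k in enumerate(keys)}
    rows = np.array([index[(c, int(r))] for c, r in zip(chains, resids)])
    return keys, rows


def frame_distance_matrix(frame: Frame) -> np.ndarray:
    """Single-frame residue-residue minimum-distance matrix."""
    mask = frame.atoms_of_type("protein")
    keys, rows = _residue_keys(frame)
    coords = frame.coordinates[mask]
    n = len(keys)
    d_atoms = cdist(coords, coords)
    out = np.full((n, n), np.inf)
    # reduce atom-pair distances to residue-pair minima
    np.minimum.at(out, (rows[:, None], rows[None, :]), d_atoms)
    np.fill_diagonal(out, 0.0)
    return out


def residue_contact_map(traj: Trajectory, window: float | None = None
                        ) -> ContactMap:
    """Time-mean and SD contact map over the trailing window.

    ``window=None`` uses every frame.
    """
    frames = (traj.frames if window is None
              else traj.trailing_window(window))
    if not frames:
        raise ValueError("empty analysis window")
    mats = np.stack([frame_distance_matrix(f) for f in frames])
    times = [f.time for f in frames]
    return ContactMap(mats.mean(axis=0), mats.std(axis=0, ddof=0),
                      len(frames), (min(times), max(times)))


def save_map(cmap: ContactMap, path, layer: str = "mean") -> None:
    """Write one layer as a dense whitespace-separated table."""
    np.savetxt(path, getattr(cmap, layer), fmt="%.4f")
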