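"""Protein-membrane binding kinetics from minimum-distance series.

The three-panel analysis: per-group minimum distance versus time,
contact counts within a 2 nm interaction threshold versus time, and
the time-averaged per-residue minimum-distance spectrum over a
trailing window.  A simple threshold-persistence detector turns a
mindist series into a lipid-binding time: the protein is bound from
the earliest time it comes within ``d_bind`` of the group and stays
within ``d_hold`` for ``t_persist``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import argrelmin

from . import _geometry as geom
from .io import Frame, Trajectory

CONTACT_THRESHOLD = 2.0  # nm, interaction threshold for contact counts

#: detector defaults (CG time scale, microseconds)
D_BIND = 0.6  # nm
D_HOLD = 0.8  # nm
T_PERSIST = 0.5  # us


@dataclass
class MindistSeries:
    """Minimum distance and contact count of one group over time."""

    times: np.ndarray
    mindist: np.ndarray  # nm
    contacts: np.ndarray  # molecules of the group within 2 nm
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mindist = np.asarray(self.mindist, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=int)
        if not (len(self.times) == len(self.mindist) == len(self.contacts)):
            raise ValueError("series columns differ in length")
        if np.any(self.mindist < 0):
            raise ValueError("negative distances")


@dataclass
class ResidueSpectrum:
    """Time-averaged per-residue minimum distance to a group.

    Residues are numbered by accumulated index across chains
    (1..chain_length x n_chains); ``chain_bounds`` gives the first
    accumulated index of each chain.
    """

    values: np.ndarray  # nm, one per accumulated residue
    chain_bounds: tuple[int, ...]
    window: tuple[float, float]
    group: str = ""

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BindingEvent:
    """Detector outcome; ``time`` is None when unbound."""

    bound: bool
    time: float | None
    d_bind: float
    d_hold: float
    t_persist: float
    truncated: bool = False  # persistence window ran past the series end


def _group_masks(frame: Frame, group: str | Sequence[str]) -> np.ndarray:
    types = (group,) if isinstance(group, str) else tuple(group)
    mask = frame.atoms_of_type(*types)
    if not mask.any():
        raise ValueError(f"no atoms of group {types} in frame")
    return mask


def mindist_series(
    traj: Trajectory,
    group: str | Sequence[str],
    contact_threshold: float = CONTACT_THRESHOLD,
    brute_force: bool = False,
) -> MindistSeries:
    """Protein-group minimum distance and contact count per frame.

    The contact count is the number of group *molecules* having any
    atom within ``contact_threshold`` of any protein atom.
    """
    times, dmin, ncontact = [], [], []
    for frame in traj:
        prot = frame.coordinates[_group_masks(frame, "protein")]
        gmask = _group_masks(frame, group)
        gcoords = frame.coordinates[gmask]
        gids = frame.molecule_id[gmask]
        if brute_force:
            d = geom.pairwise_distances(gcoords, prot, frame.box)
            dmin.append(float(d.min()))
            hit = (d <= contact_threshold).any(axis=1)
        else:
            dmin.append(geom.min_cross_distance(prot, gcoords, frame.box))
            hit = geom.neighbors_within(prot, gcoords, frame.box,
                                        contact_threshold)
        ncontact.append(len(np.unique(gids[hit])))
        times.append(frame.time)
    label = group if isinstance(group, str) else "+".join(group)
    return MindistSeries(np.array(times), np.array(dmin), np.array(ncontact),
                         group=label)


def residue_spectrum(
    traj: Trajectory,
    group: str | Sequence[str],
    window: float,
    chain_length: int = 130,
) -> ResidueSpectrum:
    """Mean per-residue minimum distance over the trailing window.

    Residues are ordered chain by chain (accumulated numbering); each
    frame contributes the minimum distance from that residue's atoms
    to any group atom.
    """
    frames = traj.trailing_window(window)
    if not frames:
        raise ValueError("empty averaging window")
    first = frames[0]
    prot_mask = _group_masks(first, "protein")
    chains = sorted(set(first.chain_id[prot_mask]))
    keys = []  # (chain, resid) in accumulated order
    for c in chains:
        resids = sorted(set(
            int(r) for r, ch in zip(first.residue_index[prot_mask],
                                    first.chain_id[prot_mask]) if ch == c))
        keys.extend((c, r) for r in resids)
    key_index = {k: i for i, k in enumerate(keys)}

    acc = np.zeros(len(keys))
    for frame in frames:
        gmask = _group_masks(frame, group)
        gcoords = frame.coordinates[gmask]
        pmask = _group_masks(frame, "protein")
        d_atom = geom.min_distance_per_point(
            frame.coordinates[pmask], gcoords, frame.box)
        per_res = np.full(len(keys), np.inf)
        rows = np.array([key_index[(c, int(r))] for c, r in
                         zip(frame.chain_id[pmask], frame.residue_index[pmask])])
        np.minimum.at(per_res, rows, d_atom)
        acc += per_res
    values = acc / len(frames)
    bounds = []
    seen = set()
    for i, (c, _) in enumerate(keys):
        if c not in seen:
            bounds.append(i + 1)
            seen.add(c)
    label = group if isinstance(group, str) else "+".join(group)
    t = [f.time for f in frames]
    return ResidueSpectrum(values, tuple(bounds), (min(t), max(t)), label)


def detect_binding_time(
    series: MindistSeries,
    d_bind: float = D_BIND,
    d_hold: float = D_HOLD,
    t_persist: float = T_PERSIST,
) -> BindingEvent:
    """Earliest time the series enters and holds the bound regime.

    Binding at time ``t`` requires ``mindist(t) <= d_bind`` and
    ``mindist <= d_hold`` for every frame in ``[t, t + t_persist]``;
    when the persistence window runs past the end of the series the
    available frames are used and the event is flagged truncated.
    """
    if len(series.times) == 0:
        raise ValueError("empty series")
    t = series.times
    d = series.mindist
    for i in range(len(t)):
        if d[i] > d_bind:
            continue
        end = t[i] + t_persist
        in_window = (t >= t[i]) & (t <= end)
        if np.all(d[in_window] <= d_hold):
            return BindingEvent(
                True, float(t[i]), d_bind, d_hold, t_persist,
                truncated=bool(t[-1] < end))
    return BindingEvent(False, None, d_bind, d_hold, t_persist)


def difference_spectrum(a: ResidueSpectrum, b: ResidueSpectrum) -> np.ndarray:
    """Per-residue difference ``a - b`` (e.g. WT minus MBD)."""
    if len(a) != len(b):
        raise ValueError(f"spectrum lengths differ: {len(a)} vs {len(b)}")
    return a.values - b.values


def find_dips(values: np.ndarray | ResidueSpectrum, threshold: float = 1.0
              ) -> np.ndarray:
    """Local minima below the threshold, as 1-based residue indices.

    Mirrors the reporting rule that only dips with minimum distance
    under 1.0 nm count as binding sites.
    """
    x = values.values if isinstance(values, ResidueSpectrum) else np.asarray(values)
    if not np.all(np.isfinite(x)):
        raise ValueError("spectrum contains non-finite values")
    (idx,) = argrelmin(x, order=1)
    return idx[x[idx] < threshold] + 1
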