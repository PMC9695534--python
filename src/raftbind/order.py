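"""Acyl-chain orientational order parameters.

For carbon ``i`` of a chain, the order parameter is

    S(i) = < 0.5 (3 cos^2 theta_i - 1) >

where ``theta_i`` is the angle between the flanking vector - from
carbon ``i-1`` to carbon ``i+1`` - and the bilayer normal (the fixed
z-axis of these planar rafts).  Carbon numbering starts at 1 next to
the lipid headgroup; terminal carbons have no flanking pair and carry
no value.  Averages run over chains, lipids and window frames, with
the SEM taken across replicates when several are given and across
lipids otherwise.  S is 1 for chains perfectly aligned with the
normal, 0 at the magic angle (~54.74 deg) or for an isotropic
ensemble, and -0.5 for chains lying in the membrane plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import Frame, Trajectory
from .shells import select_annular


@dataclass
class OrderProfile:
    """Per-carbon order parameter with uncertainty.

    ``carbons`` are the interior carbon indices (2..L-1, 1-based);
    ``sem_across`` records whether the SEM was taken across replicates
    or across lipids.
    """

    carbons: np.ndarray
    values: np.ndarray
    sem: np.ndarray
    selection: str = "all"  # AL | nAL | all
    species: str = ""
    n_lipids: float = 0.0
    sem_across: str = "lipids"

    def __post_init__(self) -> None:
        if np.any(self.values < -0.5 - 1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("order parameter outside [-0.5, 1]")


def p2(cos_theta: np.ndarray) -> np.ndarray:
    """Second Legendre polynomial 0.5 (3 cos^2 - 1)."""
    c = np.asarray(cos_theta, dtype=float)
    return 0.5 * (3.0 * c * c - 1.0)


def order_from_chains(chains: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Order profile of raw chain coordinates ``(n_chains, L, 3)``.

    Returns (carbon indices, per-carbon mean S, per-carbon SEM across
    chains).  This is the kernel behind :func:`order_profile` and the
    direct route for synthetic chain ensembles.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3 or chains.shape[1] < 3:
        raise ValueError("need (n_chains, L >= 3, 3) coordinates")
    flanking = chains[:, 2:, :] - chains[:, :-2, :]  # (n, L-2, 3)
    norms = np.linalg.norm(flanking, axis=-1)
    if np.any(norms == 0):
        raise ValueError("degenerate flanking vector (coincident beads)")
    cos_t = flanking[..., 2] / norms
    s = p2(cos_t)  # (n, L-2)
    carbons = np.arange(2, chains.shape[1])
    sem = (s.std(axis=0, ddof=1) / np.sqrt(s.shape[0])
           if s.shape[0] > 1 else np.full(s.shape[1], np.nan))
    return carbons, s.mean(axis=0), sem


def _lipid_chains(frame: Frame, molecule_ids: Iterable[int]) -> np.ndarray:
    """Stack the chain-bead coordinates of the given lipid molecules.

    Chain beads are the atoms named ``C*`` in file order; all selected
    lipids must share a chain length.  The flanking-vector geometry is
    invariant to the leaflet's up/down orientation because cos^2 enters
    the order parameter, so both leaflets stack directly.
    """
    wanted = set(int(m) for m in molecule_ids)
    chains = []
    for mol, atoms in frame.molecules().items():
        if mol not in wanted:
            continue
        cmask = np.array([str(frame.atom_names[i]).startswith("C")
                          for i in atoms])
        beads = frame.coordinates[atoms[cmask]]
        if len(beads) >= 3:
            chains.append(beads)
    if not chains:
        raise ValueError("selection contains no lipids with >= 3 chain beads")
    lengths = {len(c) for c in chains}
    if len(lengths) > 1:
        raise ValueError(f"mixed chain lengths {sorted(lengths)} in selection")
    return np.stack(chains)


def order_profile(
    traj: Trajectory | Sequence[Trajectory],
    molecule_ids: Iterable[int],
    window: float,
    selection: str = "all",
    species: str = "",
) -> OrderProfile:
    """Time-averaged order profile of a lipid selection.

    With a list of replicate trajectories the SEM is computed across
    replicates of window means; with a single trajectory it falls back
    to the SEM across lipids (pooling window frames), flagged in
    ``sem_across``.
    """
    replicates = [traj] if isinstance(traj, Trajectory) else list(traj)
    per_rep = []
    sem_lipids = None
    carbons = None
    n_lipids = 0.0
    for rep in replicates:
        frames = rep.trailing_window(window)
        if not frames:
            raise ValueError("empty averaging window")
        stacks = [_lipid_chains(f, molecule_ids) for f in frames]
        all_chains = np.concatenate(stacks, axis=0)
        carbons, mean, sem_lipids = order_from_chains(all_chains)
        per_rep.append(mean)
        n_lipids = len(stacks[0])
    values = np.mean(per_rep, axis=0)
    if len(per_rep) > 1:
        sem = np.std(per_rep, axis=0, ddof=1) / np.sqrt(len(per_rep))
        across = "replicates"
    else:
        sem = sem_lipids
        across = "lipids"
    return OrderProfile(carbons, values, sem, selection, species,
                        n_lipids, across)


def shell_order_comparison(
    traj: Trajectory | Sequence[Trajectory],
    cutoff: float = 0.5,
    window: float = 5.0,
    species_list: Sequence[str] = ("DPPC", "DLPC", "GM1", "POPS"),
) -> dict[str, dict[str, OrderProfile | None]]:
    """Paired AL/nAL order profiles per lipid species.

    The AL shell is taken from the final frame of each replicate (the
    bound state the window averages over); nAL is its complement.
    Species absent from the system are skipped; an empty AL shell
    yields ``None`` for that profile.
    """
    replicates = [traj] if isinstance(traj, Trajectory) else list(traj)
    ref = replicates[0][-1]
    out: dict[str, dict[str, OrderProfile | None]] = {}
    shells = [select_annular(rep[-1], cutoff) for rep in replicates]
    for species in species_list:
        if not ref.atoms_of_type(species).any():
            continue
        al_ids = [sorted(m for m in sh.annular if sh.species[m] == species)
                  for sh in shells]
        nal_ids = [sorted(m for m in sh.non_annular if sh.species[m] == species)
                   for sh in shells]
        profiles: dict[str, OrderProfile | None] = {}
        for label, ids_per_rep in (("AL", al_ids), ("nAL", nal_ids)):
            if all(len(ids) == 0 for ids in ids_per_rep):
                profiles[label] = None
                continue
            per_rep_profiles = [
                order_profile(rep, ids, window, label, species)
                for rep, ids in zip(replicates, ids_per_rep) if ids]
            values = np.mean([p.values for p in per_rep_profiles], axis=0)
            if len(per_rep_profiles) > 1:
                sem = (np.std([p.values for p in per_rep_profiles], axis=0,
                              ddof=1) / np.sqrt(len(per_rep_profiles)))
                across = "replicates"
            else:
                sem = per_rep_profiles[0].sem
                across = per_rep_profiles[0].sem_across
            profiles[label] = OrderProfile(
                per_rep_profiles[0].carbons, values, sem, label, species,
                float(np.mean([p.n_lipids for p in per_rep_profiles])), across)
        out[species] = profiles
    return out
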