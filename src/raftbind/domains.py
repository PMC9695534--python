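"""Lo/Ld/Lod domain classification of phase-separated raft bilayers.

The rules mirror the distance-based selection used to analyze the raft
systems: a DPPC with any atom within 0.5 nm of another DPPC (same
leaflet, minimum image) belongs to the liquid-ordered Lo domain; a
DLPC likewise in contact with another DLPC belongs to the
liquid-disordered Ld domain; the remaining PC lipids form the mixed
boundary Lod domain.  Each cholesterol inherits the domain of its
nearest PC lipid (Lo-CHOL / Ld-CHOL / Lod-CHOL); GM1 and POPS carry
their cluster labels by species.  Classification is per frame and per
leaflet, with no temporal smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _geometry as geom
from .io import Frame

PC_SPECIES = ("DPPC", "DLPC")
CORE_LABEL = {"DPPC": "Lo", "DLPC": "Ld"}
#: tie-break priority for cholesterol attachment on exact distance ties
CHOL_PRIORITY = ("Lo", "Lod", "Ld")

DOMAIN_LABELS = (
    "Lo", "Ld", "Lod", "Lo-CHOL", "Ld-CHOL", "Lod-CHOL",
    "GM-cluster", "PS-cluster",
)


@dataclass
class DomainAssignment:
    """Per-lipid domain labels and leaflets for one frame."""

    labels: dict[int, str]  # molecule_id -> domain label
    leaflet: dict[int, str]  # molecule_id -> upper/lower
    cutoff: float  # nm contact cutoff used
    chol_flagged: set[int] = field(default_factory=set)  # CHOL beyond cutoff

    def of_species(self, frame: Frame, species: str) -> dict[int, str]:
        mols = {int(m) for m, t in zip(frame.molecule_id, frame.molecule_type)
                if t == species}
        return {m: lab for m, lab in self.labels.items() if m in mols}


def assign_leaflets(frame: Frame) -> dict[int, str]:
    """Assign each lipid to a leaflet by its head-bead z position.

    The head bead is the first atom of each lipid molecule; the
    midplane is the mean head-bead z over all lipids.  Raises on
    frames without lipids or with a degenerate (flat) distribution.
    """
    lipid_mask = frame.atoms_of_type(*("DPPC", "DLPC", "CHOL", "GM1", "POPS"))
    if not lipid_mask.any():
        raise ValueError("frame contains no lipid atoms")
    heads: dict[int, float] = {}
    for mol, atoms in frame.molecules().items():
        if lipid_mask[atoms[0]]:
            heads[mol] = float(frame.coordinates[atoms[0], 2])
    zs = np.array(list(heads.values()))
    if np.ptp(zs) < 1e-6:
        raise ValueError("degenerate leaflet geometry: all head beads at one z")
    midplane = zs.mean()
    return {mol: ("upper" if z >= midplane else "lower")
            for mol, z in heads.items()}


def _contact_molecules(
    coords: np.ndarray, mol_ids: np.ndarray, box: np.ndarray, cutoff: float,
    brute_force: bool = False,
) -> set[int]:
    """Molecules with any atom within cutoff of a *different* molecule."""
    in_contact: set[int] = set()
    if len(coords) == 0:
        return in_contact
    if brute_force:
        d = geom.pairwise_distances(coords, coords, box)
        close = (d <= cutoff) & (mol_ids[:, None] != mol_ids[None, :])
        hit = close.any(axis=1)
        return set(int(m) for m in np.unique(mol_ids[hit]))
    tree = geom.periodic_tree(coords, box)
    for i, j in tree.query_pairs(cutoff):
        if mol_ids[i] != mol_ids[j]:
            in_contact.add(int(mol_ids[i]))
            in_contact.add(int(mol_ids[j]))
    return in_contact


def classify_pc(
    frame: Frame,
    cutoff: float = 0.5,
    leaflets: Mapping[int, str] | None = None,
    head_only: bool = False,
    brute_force: bool = False,
) -> DomainAssignment:
    """Classify DPPC/DLPC into Lo, Ld and Lod, per leaflet.

    A PC lipid joins its species' core domain (Lo for DPPC, Ld for
    DLPC) when any of its atoms lies within ``cutoff`` of an atom of
    *another* lipid of the same species in the same leaflet, under the
    minimum-image convention; the remaining PCs are Lod.  With
    ``head_only`` the contact search uses head beads only.
    ``brute_force`` switches to the all-pairs reference path.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if leaflets is None:
        leaflets = assign_leaflets(frame)
    labels: dict[int, str] = {}
    leaflet_out: dict[int, str] = {}
    for species in PC_SPECIES:
        mask = frame.atoms_of_type(species)
        if head_only:
            first_atoms = {atoms[0] for mol, atoms in frame.molecules().items()}
            mask = mask & np.isin(np.arange(frame.n_atoms), list(first_atoms))
        mols_here = np.unique(frame.molecule_id[frame.atoms_of_type(species)])
        for side in ("upper", "lower"):
            side_mols = [m for m in mols_here if leaflets.get(int(m)) == side]
            side_mask = mask & np.isin(frame.molecule_id, side_mols)
            coords = frame.coordinates[side_mask]
            ids = frame.molecule_id[side_mask]
            contact = _contact_molecules(coords, ids, frame.box, cutoff,
                                         brute_force)
            for m in side_mols:
                m = int(m)
                labels[m] = CORE_LABEL[species] if m in contact else "Lod"
                leaflet_out[m] = side
    # cluster species labelled by type
    for species, label in (("GM1", "GM-cluster"), ("POPS", "PS-cluster")):
        for m in np.unique(frame.molecule_id[frame.atoms_of_type(species)]):
            labels[int(m)] = label
            leaflet_out[int(m)] = leaflets[int(m)]
    return DomainAssignment(labels, leaflet_out, cutoff)


def assign_chol(
    frame: Frame,
    pc_assignment: DomainAssignment,
    cutoff: float = 0.5,
    brute_force: bool = False,
) -> DomainAssignment:
    """Attach each cholesterol to the domain of its nearest PC lipid.

    CHOL whose minimum distance to any PC atom exceeds ``cutoff`` is
    still labelled by its nearest PC but flagged.  Exact distance ties
    across domains resolve by the fixed priority Lo > Lod > Ld.
    Extends and returns a copy of ``pc_assignment``.
    """
    pc_mask = frame.atoms_of_type(*PC_SPECIES)
    if not pc_mask.any():
        raise ValueError("frame contains no PC lipids")
    chol_mols = np.unique(frame.molecule_id[frame.atoms_of_type("CHOL")])
    labels = dict(pc_assignment.labels)
    leaflet = dict(pc_assignment.leaflet)
    flagged: set[int] = set(pc_assignment.chol_flagged)

    chol_atom_mask = frame.atoms_of_type("CHOL")
    chol_coords = frame.coordinates[chol_atom_mask]
    chol_ids = frame.molecule_id[chol_atom_mask]
    mol_index = {int(m): k for k, m in enumerate(chol_mols)}
    row = np.array([mol_index[int(m)] for m in chol_ids])

    # per-CHOL-molecule minimum distance to each domain's PC atom pool
    dom_min = np.full((len(chol_mols), len(CHOL_PRIORITY)), np.inf)
    for col, domain in enumerate(CHOL_PRIORITY):
        dom_mols = [m for m, lab in pc_assignment.labels.items() if lab == domain]
        pool = frame.coordinates[pc_mask & np.isin(frame.molecule_id, dom_mols)]
        if len(pool) == 0:
            continue
        if brute_force:
            d_atoms = geom.pairwise_distances(chol_coords, pool, frame.box
                                              ).min(axis=1)
        else:
            d_atoms = geom.min_distance_per_point(chol_coords, pool, frame.box)
        np.minimum.at(dom_min[:, col], row, d_atoms)

    leaflets_all = assign_leaflets(frame)
    for k, m in enumerate(chol_mols):
        m = int(m)
        # first strict minimum in priority order: Lo > Lod > Ld on ties
        col = int(np.argmin(dom_min[k]))
        best_d = dom_min[k, col]
        labels[m] = f"{CHOL_PRIORITY[col]}-CHOL"
        leaflet[m] = leaflets_all[m]
        if best_d > cutoff:
            flagged.add(m)
    return DomainAssignment(labels, leaflet, pc_assignment.cutoff, flagged)


def classify_frame(frame: Frame, cutoff: float = 0.5, **kw) -> DomainAssignment:
    """PC classification followed by cholesterol attachment."""
    pc = classify_pc(frame, cutoff, **kw)
    if frame.atoms_of_type("CHOL").any():
        return assign_chol(frame, pc, cutoff,
                           brute_force=kw.get("brute_force", False))
    return pc


@dataclass
class DomainComposition:
    """Per-species distribution over domains, averaged with SEM.

    ``percentages[species][domain]`` is the mean percentage of that
    species found in that domain (per species, domains sum to 100);
    ``sem`` matches its shape.  With a single replicate the SEM is
    undefined and ``sem_defined`` is False.
    """

    percentages: dict[str, dict[str, float]]
    sem: dict[str, dict[str, float]]
    counts: dict[str, dict[str, float]]
    n_replicates: int
    n_frames: int
    sem_defined: bool


_SPECIES_DOMAINS = {
    "DPPC": ("Lo", "Lod"),
    "DLPC": ("Ld", "Lod"),
    "CHOL": ("Lo-CHOL", "Ld-CHOL", "Lod-CHOL"),
    "GM1": ("GM-cluster",),
    "POPS": ("PS-cluster",),
}


def composition_summary(
    replicate_assignments: Sequence[Sequence[DomainAssignment]],
    species_of: Mapping[int, str],
) -> DomainComposition:
    """Time- and replicate-averaged domain composition.

    ``replicate_assignments`` holds, per replicate, the per-frame
    assignments inside the averaging window.  Percentages are averaged
    over frames within each replicate, then the mean and standard
    error of the mean are taken across replicates.
    """
    if not replicate_assignments or not any(replicate_assignments):
        raise ValueError("empty averaging window")
    per_rep: list[dict[str, dict[str, float]]] = []
    per_rep_counts: list[dict[str, dict[str, float]]] = []
    n_frames = 0
    for rep in replicate_assignments:
        if not rep:
            raise ValueError("replicate with empty window")
        n_frames += len(rep)
        frame_pcts: dict[str, dict[str, list[float]]] = {}
        frame_counts: dict[str, dict[str, list[float]]] = {}
        for assignment in rep:
            tallies: dict[str, dict[str, int]] = {}
            for mol, label in assignment.labels.items():
                sp = species_of[mol]
                tallies.setdefault(sp, {}).setdefault(label, 0)
                tallies[sp][label] += 1
            for sp, by_label in tallies.items():
                total = sum(by_label.values())
                domains = _SPECIES_DOMAINS.get(sp, tuple(by_label))
                for domain in domains:
                    count = by_label.get(domain, 0)
                    frame_pcts.setdefault(sp, {}).setdefault(domain, []).append(
                        100.0 * count / total)
                    frame_counts.setdefault(sp, {}).setdefault(domain, []).append(
                        float(count))
        per_rep.append({sp: {d: float(np.mean(v)) for d, v in by_d.items()}
                        for sp, by_d in frame_pcts.items()})
        per_rep_counts.append({sp: {d: float(np.mean(v)) for d, v in by_d.items()}
                               for sp, by_d in frame_counts.items()})

    n_rep = len(per_rep)
    percentages: dict[str, dict[str, float]] = {}
    sems: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, float]] = {}
    for sp in {s for rep in per_rep for s in rep}:
        percentages[sp] = {}
        sems[sp] = {}
        counts[sp] = {}
        domains = {d for rep in per_rep for d in rep.get(sp, {})}
        for domain in domains:
            vals = np.array([rep.get(sp, {}).get(domain, 0.0) for rep in per_rep])
            cnts = np.array([rep.get(sp, {}).get(domain, 0.0)
                             for rep in per_rep_counts])
            percentages[sp][domain] = float(vals.mean())
            counts[sp][domain] = float(cnts.mean())
            sems[sp][domain] = (float(vals.std(ddof=1) / np.sqrt(n_rep))
                                if n_rep > 1 else float("nan"))
    return DomainComposition(
        percentages, sems, counts, n_rep, n_frames, sem_defined=n_rep > 1)


def label_agreement(
    assignment: DomainAssignment,
    truth_labels: Mapping[int, str],
    restrict: Iterable[int] | None = None,
) -> float:
    """Fraction of molecules whose label matches the planted truth."""
    mols = set(truth_labels) if restrict is None else set(restrict)
    mols &= set(assignment.labels)
    if not mols:
        raise ValueError("no molecules to compare")
    hits = sum(assignment.labels[m] == truth_labels[m] for m in mols)
    return hits / len(mols)
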