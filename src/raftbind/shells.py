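"""Annular lipid shell selection and composition around a bound protein.

A lipid belongs to the annular shell (AL) at a given cutoff when any
of its atoms lies within that cutoff of any protein atom under the
minimum-image convention; every other lipid of the analyzed leaflet(s)
is non-annular (nAL).  Shell compositions are reported as per-species
percentages of the AL membership with SEM over time windows and
replicates, the quantities tabulated alongside binding times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _geometry as geom
from .io import LIPID_TYPES, Frame


@dataclass
class ShellSelection:
    """AL/nAL partition of the lipids of one frame at one cutoff."""

    cutoff: float  # nm
    annular: set[int]  # molecule ids in the shell
    non_annular: set[int]
    species: dict[int, str]  # molecule id -> lipid species

    def __post_init__(self) -> None:
        overlap = self.annular & self.non_annular
        if overlap:
            raise ValueError(f"AL and nAL overlap: {sorted(overlap)[:5]} ...")

    @property
    def total(self) -> int:
        return len(self.annular)

    def count_by_species(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.annular:
            out[self.species[m]] = out.get(self.species[m], 0) + 1
        return out


def select_annular(
    frame: Frame,
    cutoff: float,
    leaflets: Mapping[int, str] | None = None,
    leaflet_filter: str | None = None,
    brute_force: bool = False,
) -> ShellSelection:
    """Select the annular lipid shell around the frame's protein.

    Both leaflets are eligible by default; pass ``leaflet_filter``
    ("upper"/"lower", with ``leaflets`` from
    :func:`raftbind.domains.assign_leaflets`) to restrict the analyzed
    lipid population.  Water and ions are never shell members.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    protein_mask = frame.atoms_of_type("protein")
    if not protein_mask.any():
        raise ValueError("frame contains no protein atoms")
    lipid_mask = frame.atoms_of_type(*LIPID_TYPES)
    if leaflet_filter is not None:
        if leaflets is None:
            raise ValueError("leaflet_filter requires leaflet assignments")
        keep = [m for m, side in leaflets.items() if side == leaflet_filter]
        lipid_mask &= np.isin(frame.molecule_id, keep)

    lipid_coords = frame.coordinates[lipid_mask]
    lipid_ids = frame.molecule_id[lipid_mask]
    prot_coords = frame.coordinates[protein_mask]

    if brute_force:
        d = geom.pairwise_distances(lipid_coords, prot_coords, frame.box)
        hit_atoms = (d <= cutoff).any(axis=1)
    else:
        hit_atoms = geom.neighbors_within(
            prot_coords, lipid_coords, frame.box, cutoff)

    all_mols = set(int(m) for m in np.unique(lipid_ids))
    annular = set(int(m) for m in np.unique(lipid_ids[hit_atoms]))
    species = {}
    for m in all_mols:
        first = np.flatnonzero(lipid_ids == m)[0]
        species[m] = str(frame.molecule_type[lipid_mask][first])
    return ShellSelection(cutoff, annular, all_mols - annular, species)


@dataclass
class ShellComposition:
    """Mean AL composition with SEM over window frames and replicates."""

    percentages: dict[str, float]  # species -> mean % of the shell
    sem: dict[str, float]
    total: float  # mean lipid count in the shell
    total_sem: float
    n_replicates: int
    sem_defined: bool
    empty: bool = False  # true when every selection had an empty shell


def shell_composition(
    replicate_selections: Sequence[Sequence[ShellSelection]],
) -> ShellComposition:
    """Average shell composition over window frames, SEM across replicates.

    Per replicate, species percentages and the total count are averaged
    over the frames of the window; the mean and standard error of the
    mean are then taken across replicates.  An entirely empty shell is
    returned flagged with undefined percentages.
    """
    if not replicate_selections or not any(replicate_selections):
        raise ValueError("no shell selections given")
    all_species = sorted({
        sp for rep in replicate_selections for sel in rep
        for sp in sel.species.values()})
    per_rep_pct: list[dict[str, float]] = []
    per_rep_total: list[float] = []
    any_nonempty = False
    for rep in replicate_selections:
        if not rep:
            raise ValueError("replicate with empty window")
        pcts = {sp: [] for sp in all_species}
        totals = []
        for sel in rep:
            totals.append(sel.total)
            if sel.total == 0:
                continue
            any_nonempty = True
            by_sp = sel.count_by_species()
            for sp in all_species:
                pcts[sp].append(100.0 * by_sp.get(sp, 0) / sel.total)
        per_rep_total.append(float(np.mean(totals)))
        per_rep_pct.append({sp: (float(np.mean(v)) if v else float("nan"))
                            for sp, v in pcts.items()})
    n_rep = len(per_rep_pct)
    if not any_nonempty:
        return ShellComposition(
            {sp: float("nan") for sp in all_species},
            {sp: float("nan") for sp in all_species},
            0.0, 0.0, n_rep, sem_defined=False, empty=True)
    percentages = {}
    sems = {}
    for sp in all_species:
        vals = np.array([rep[sp] for rep in per_rep_pct])
        percentages[sp] = float(np.nanmean(vals))
        sems[sp] = (float(np.nanstd(vals, ddof=1) / np.sqrt(n_rep))
                    if n_rep > 1 else float("nan"))
    totals = np.array(per_rep_total)
    return ShellComposition(
        percentages, sems, float(totals.mean()),
        (float(totals.std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1
         else float("nan")),
        n_rep, sem_defined=n_rep > 1)
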