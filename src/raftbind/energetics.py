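"""Protein-lipid binding energetics from nonbonded energy tables.

Consumes time series of Lennard-Jones and Coulomb protein-lipid
energies (kJ/mol, one pair of columns per lipid species), averages
them over a trailing window per replicate, and reports per-species
means with SEM across replicates, the all-lipid sum, the Coulomb
fraction of each total, and binding energies normalized by the
time-averaged 1.2 nm annular lipid count.  Pairwise energies are
never computed from coordinates here; tables come from upstream
force-field evaluation (or the synthetic table generator in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import ENERGY_TERMS, EnergyTable
from .shells import ShellComposition

NORMALIZATION_CUTOFF = 1.2  # nm, the energy-calculation threshold


@dataclass
class SpeciesEnergy:
    """Mean energies (kJ/mol) of one species with SEM across replicates."""

    lennard_jones: float
    coulomb: float
    lj_sem: float = float("nan")
    coulomb_sem: float = float("nan")
    total_sem: float = float("nan")

    @property
    def total(self) -> float:
        return self.lennard_jones + self.coulomb


@dataclass
class BindingEnergyReport:
    """Per-species binding energies plus the all-lipid sum."""

    species: dict[str, SpeciesEnergy]
    window: float
    n_replicates: int
    sem_defined: bool
    normalized: dict[str, float] = field(default_factory=dict)
    shell_count: float | None = None

    @property
    def all_lipid_total(self) -> float:
        return sum(e.total for e in self.species.values())


def aggregate_energies(
    tables: Sequence[EnergyTable], window: float
) -> BindingEnergyReport:
    """Window-average each replicate's table; SEM across replicates.

    All tables must carry the same (species, term) column tags.  The
    trailing ``window`` is taken in each table's own time units.
    """
    if not tables:
        raise ValueError("no energy tables given")
    tag_sets = [frozenset(t.tags.values()) for t in tables]
    if len(set(tag_sets)) != 1:
        raise ValueError("replicate tables carry different column tags")
    species_terms = sorted(tag_sets[0])
    species_names = sorted({sp for sp, _ in species_terms})
    for sp in species_names:
        terms = {term for s, term in species_terms if s == sp}
        if terms != set(ENERGY_TERMS):
            raise ValueError(f"species {sp} missing terms {set(ENERGY_TERMS) - terms}")

    # per replicate, per species: window means of LJ and Coulomb
    rep_means: dict[str, dict[str, list[float]]] = {
        sp: {t: [] for t in ENERGY_TERMS} for sp in species_names}
    for table in tables:
        rows = table.window(window)
        if rows.empty:
            raise ValueError("window contains no rows")
        for col, (sp, term) in table.tags.items():
            rep_means[sp][term].append(float(rows[col].mean()))

    n_rep = len(tables)
    species: dict[str, SpeciesEnergy] = {}
    for sp in species_names:
        lj = np.array(rep_means[sp]["lennard_jones"])
        cou = np.array(rep_means[sp]["coulomb"])
        tot = lj + cou
        if n_rep > 1:
            sems = tuple(float(x.std(ddof=1) / np.sqrt(n_rep))
                         for x in (lj, cou, tot))
        else:
            sems = (float("nan"),) * 3
        species[sp] = SpeciesEnergy(float(lj.mean()), float(cou.mean()),
                                    *sems)
    return BindingEnergyReport(species, window, n_rep, sem_defined=n_rep > 1)


def coulomb_fraction(report: BindingEnergyReport) -> dict[str, float]:
    """Per-species |Coulomb| / |total| fraction.

    Raises on a zero total.  A sign mismatch between the LJ and
    Coulomb terms makes the ratio ill-defined as a "share of the
    binding energy"; such species are still reported but the fraction
    may exceed 1 - callers can detect this via
    :func:`coulomb_sign_flags`.
    """
    out = {}
    for sp, e in report.species.items():
        if e.total == 0:
            raise ZeroDivisionError(f"zero total energy for {sp}")
        out[sp] = abs(e.coulomb) / abs(e.total)
    return out


def coulomb_sign_flags(report: BindingEnergyReport) -> dict[str, bool]:
    """True where the LJ and Coulomb means have opposite signs."""
    return {sp: (e.lennard_jones * e.coulomb < 0)
            for sp, e in report.species.items()}


def normalize_by_shell(
    report: BindingEnergyReport,
    shell: ShellComposition | float,
) -> BindingEnergyReport:
    """Divide each species total by the time-averaged 1.2 nm shell count.

    ``shell`` is a :class:`~raftbind.shells.ShellComposition` from the
    1.2 nm annular selection (its mean total count is used) or a bare
    count.  Returns a copy of the report with ``normalized`` filled
    (kJ/mol per annular lipid).
    """
    count = shell if isinstance(shell, (int, float)) else shell.total
    if not count or count <= 0:
        raise ValueError("shell count must be positive for normalization")
    normalized = {sp: e.total / count for sp, e in report.species.items()}
    normalized["all"] = report.all_lipid_total / count
    return BindingEnergyReport(
        dict(report.species), report.window, report.n_replicates,
        report.sem_defined, normalized, float(count))


def make_energy_table(
    species_means: Mapping[str, tuple[float, float]],
    n_rows: int = 100,
    dt: float = 0.05,
    noise: float = 0.0,
    seed: int = 0,
) -> EnergyTable:
    """Synthesize a tagged energy table with known per-species means.

    ``species_means`` maps species -> (LJ, Coulomb) kJ/mol.  With
    ``noise`` > 0, Gaussian noise of that standard deviation is added
    row-wise (the expected window mean stays at the planted value).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    data = {"time": np.arange(n_rows) * dt}
    tags = {}
    for sp, (lj, cou) in species_means.items():
        for term, mean in (("lennard_jones", lj), ("coulomb", cou)):
            col = f"{sp} {'LJ' if term == 'lennard_jones' else 'Coul.'}"
            series = np.full(n_rows, float(mean))
            if noise > 0:
                series = series + rng.normal(0, noise, n_rows)
            data[col] = series
            tags[col] = (sp, term)
    return EnergyTable(pd.DataFrame(data), tags)
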