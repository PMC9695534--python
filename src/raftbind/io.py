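"""Coordinate, trajectory and energy-table I/O.

Formats covered:

* GRO (fixed-column GROMACS coordinate file, nm) - read and write;
* frame-concatenated GRO as a multi-frame trajectory, with the time
  stamp taken from a ``t=`` token in each frame title line;
* PDB (read-only, Angstrom converted to nm on read);
* XVG energy tables (``@``/``#`` metadata, whitespace-separated rows),
  with legend lines mapped to (species, term) column tags.

All coordinates are nm internally and boxes are orthorhombic; triclinic
box lines (nonzero off-diagonal components) are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MOLECULE_TYPES = (
    "DPPC", "DLPC", "CHOL", "GM1", "POPS", "protein", "water", "ion",
)

AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: residue-name aliases -> canonical molecule type; user-extensible via
#: the ``aliases`` argument of :func:`classify_residue_name`.
DEFAULT_ALIASES: Mapping[str, str] = {
    "DPPC": "DPPC",
    "DLPC": "DLPC",
    "CHOL": "CHOL",
    "CHL1": "CHOL",
    "GM1": "GM1",
    "DPG1": "GM1",
    "POPS": "POPS",
    "PS": "POPS",
    "W": "water",
    "SOL": "water",
    "TIP3": "water",
    "NA": "ion",
    "CL": "ion",
    "NA+": "ion",
    "CL-": "ion",
    "ION": "ion",
}

LIPID_TYPES = ("DPPC", "DLPC", "CHOL", "GM1", "POPS")

ENERGY_TERMS = ("lennard_jones", "coulomb")


class FormatError(ValueError):
    """Malformed input file."""


def classify_residue_name(
    resname: str, aliases: Mapping[str, str] | None = None
) -> str:
    """Map a residue name to the closed molecule-type vocabulary."""
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    name = resname.strip().upper()
    if name in table:
        return table[name]
    if name in AMINO3 or name == "K18":
        return "protein"
    raise FormatError(f"unrecognized residue name {resname!r}")


@dataclass
class Frame:
    """One configuration: coordinates plus molecule/residue topology.

    Coordinates are nm; ``box`` holds the three orthorhombic box
    lengths.  ``molecule_id`` groups atoms into molecules (one id per
    lipid/water/ion molecule, one per protein chain); ``residue_index``
    is the per-molecule residue number (1-based, the GRO resid);
    ``chain_id`` labels protein chains ("" for non-protein atoms).
    """

    coordinates: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray  # (3,) nm
    atom_names: np.ndarray  # (n_atoms,) str
    molecule_id: np.ndarray  # (n_atoms,) int
    molecule_type: np.ndarray  # (n_atoms,) str
    residue_index: np.ndarray  # (n_atoms,) int
    chain_id: np.ndarray  # (n_atoms,) str
    title: str = ""
    time: float | None = None  # trajectory time stamp (us CG / ns AA)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.box > 0):
            raise ValueError(f"box lengths must be positive, got {self.box}")
        n = len(self.coordinates)
        for name in ("atom_names", "molecule_id", "molecule_type",
                     "residue_index", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        unknown = set(np.unique(self.molecule_type)) - set(MOLECULE_TYPES)
        if unknown:
            raise ValueError(f"unknown molecule types {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    def select(self, mask: np.ndarray) -> "Frame":
        """Sub-frame of the atoms where ``mask`` is true."""
        return Frame(
            self.coordinates[mask], self.box.copy(), self.atom_names[mask],
            self.molecule_id[mask], self.molecule_type[mask],
            self.residue_index[mask], self.chain_id[mask],
            self.title, self.time,
        )

    def atoms_of_type(self, *types: str) -> np.ndarray:
        """Boolean mask of atoms whose molecule type is in ``types``."""
        return np.isin(self.molecule_type, types)

    def molecules(self) -> dict[int, np.ndarray]:
        """molecule_id -> atom-index array, in file order."""
        out: dict[int, np.ndarray] = {}
        order = np.argsort(self.molecule_id, kind="stable")
        ids = self.molecule_id[order]
        bounds = np.flatnonzero(np.diff(ids)) + 1
        for chunk in np.split(order, bounds):
            out[int(self.molecule_id[chunk[0]])] = chunk
        return out


@dataclass
class Trajectory:
    """Ordered frames with constant topology and increasing times."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        n = self.frames[0].n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, expected {n}"
                )
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time if f.time is not None else i
                         for i, f in enumerate(self.frames)], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def trailing_window(self, span: float) -> list[Frame]:
        """Frames whose time falls within ``span`` of the final time."""
        times = self.times
        cutoff = times[-1] - span
        return [f for f, t in zip(self.frames, times) if t >= cutoff]


# ---------------------------------------------------------------------------
# molecule typing / chain detection

def _assign_molecules(
    resids: np.ndarray, resnames: Sequence[str],
    aliases: Mapping[str, str] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive (molecule_id, molecule_type, chain_id) from GRO residues.

    Non-protein molecules are one residue each (a new resid starts a
    new molecule).  Consecutive protein residues form one chain; a
    resid decrease or an intervening non-protein molecule starts the
    next chain (chains labelled A, B, C, ...).
    """
    n = len(resids)
    mol_type = np.array([classify_residue_name(r, aliases) for r in resnames])
    mol_id = np.zeros(n, dtype=int)
    chain = np.full(n, "", dtype=object)
    current = -1
    prev_resid = None
    prev_type = None
    chain_count = 0
    for i in range(n):
        new_residue = prev_resid is None or resids[i] != prev_resid or \
            mol_type[i] != prev_type
        if mol_type[i] == "protein":
            new_chain = prev_type != "protein" or (
                new_residue and resids[i] < prev_resid)
            if new_chain:
                current += 1
                chain_count += 1
            chain[i] = chr(ord("A") + (chain_count - 1) % 26)
        elif new_residue:
            current += 1
        mol_id[i] = current
        prev_resid = resids[i]
        prev_type = mol_type[i]
    return mol_id, mol_type.astype(object), chain


# ---------------------------------------------------------------------------
# GRO

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def _parse_gro_block(lines: list[str], aliases=None) -> Frame:
    title = lines[0].rstrip("\n")
    try:
        n_atoms = int(lines[1])
    except ValueError as exc:
        raise FormatError(f"bad atom-count line: {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise FormatError("truncated GRO frame (missing atoms or box line)")
    resids = np.empty(n_atoms, dtype=int)
    resnames: list[str] = []
    names: list[str] = []
    coords = np.empty((n_atoms, 3))
    for i, line in enumerate(lines[2:2 + n_atoms]):
        try:
            resids[i] = int(line[0:5])
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            coords[i] = (float(line[20:28]), float(line[28:36]),
                         float(line[36:44]))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"malformed GRO atom line {i + 3}: {line!r}") from exc
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) not in (3, 9):
        raise FormatError(f"bad box line: {lines[2 + n_atoms]!r}")
    box_vals = [float(x) for x in box_fields]
    if len(box_vals) == 9 and any(abs(v) > 1e-12 for v in box_vals[3:]):
        raise FormatError("triclinic boxes are not supported")
    box = np.array(box_vals[:3])
    mol_id, mol_type, chain = _assign_molecules(resids, resnames, aliases)
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else None
    return Frame(coords, box, np.array(names, dtype=object), mol_id, mol_type,
                 resids, chain, title=title, time=time)


def read_gro(path: str | Path, aliases: Mapping[str, str] | None = None) -> Frame:
    """Read a single-frame GRO file."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: not a GRO file (fewer than 3 lines)")
    return _parse_gro_block(lines, aliases)


def write_gro(frame: Frame, path: str | Path, resnames: Sequence[str] | None = None) -> None:
    """Write a frame in fixed-column GRO format (3-decimal nm).

    Residue names are reconstructed from molecule types unless given
    explicitly (protein residues are written as ``K18``).
    """
    if resnames is None:
        resnames = ["K18" if t == "protein" else t for t in frame.molecule_type]
    title = frame.title or "raftbind frame"
    if frame.time is not None and "t=" not in title:
        title = f"{title} t= {frame.time:g}"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write(f"{frame.n_atoms:5d}\n")
        for i in range(frame.n_atoms):
            x, y, z = frame.coordinates[i]
            fh.write(
                f"{int(frame.residue_index[i]) % 100000:5d}"
                f"{resnames[i][:5]:<5s}{frame.atom_names[i][:5]:>5s}"
                f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    dt: float | None = None,
    aliases: Mapping[str, str] | None = None,
) -> Trajectory:
    """Read a trajectory from one multi-frame GRO file or several files.

    Times come from ``t=`` tokens in the frame titles, or from ``dt``
    (uniform spacing from 0) when the titles carry none.
    """
    if isinstance(paths, (str, Path)):
        all_lines = Path(paths).read_text().splitlines()
        frames: list[Frame] = []
        pos = 0
        while pos < len(all_lines):
            if not all_lines[pos].strip() and pos == len(all_lines) - 1:
                break
            try:
                n_atoms = int(all_lines[pos + 1])
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"bad frame header at line {pos + 1}") from exc
            block = all_lines[pos:pos + n_atoms + 3]
            frames.append(_parse_gro_block(block, aliases))
            pos += n_atoms + 3
    else:
        frames = [read_gro(p, aliases) for p in paths]
    if dt is not None or any(f.time is None for f in frames):
        step = 1.0 if dt is None else float(dt)
        if step <= 0:
            raise ValueError("dt must be positive")
        for i, f in enumerate(frames):
            f.time = i * step
    first = frames[0]
    for i, f in enumerate(frames[1:], start=1):
        if not (np.array_equal(f.atom_names, first.atom_names)
                and np.array_equal(f.molecule_id, first.molecule_id)):
            raise FormatError(f"frame {i} topology differs from frame 0")
    return Trajectory(frames)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames as concatenated GRO blocks with ``t=`` time stamps."""
    with open(path, "w") as fh:
        for frame in traj:
            _write_block(frame, fh)


def _write_block(frame: Frame, fh) -> None:
    resnames = ["K18" if t == "protein" else t for t in frame.molecule_type]
    title = (frame.title or "raftbind frame").split(" t= ")[0]
    if frame.time is not None:
        title = f"{title} t= {frame.time:g}"
    fh.write(title + "\n")
    fh.write(f"{frame.n_atoms:5d}\n")
    for i in range(frame.n_atoms):
        x, y, z = frame.coordinates[i]
        fh.write(
            f"{int(frame.residue_index[i]) % 100000:5d}"
            f"{resnames[i][:5]:<5s}{frame.atom_names[i][:5]:>5s}"
            f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB (read only)

def read_pdb(path: str | Path, aliases: Mapping[str, str] | None = None) -> Frame:
    """Read ATOM/HETATM records from a PDB file; Angstrom -> nm.

    Uses CRYST1 for the box when present, else a bounding box with
    1 nm padding.
    """
    resids: list[int] = []
    resnames: list[str] = []
    names: list[str] = []
    coords: list[tuple[float, float, float]] = []
    box = None
    for line in Path(path).read_text().splitlines():
        rec = line[:6]
        if rec == "CRYST1":
            a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
            angles = (float(line[33:40]), float(line[40:47]), float(line[47:54]))
            if any(abs(ang - 90.0) > 1e-3 for ang in angles):
                raise FormatError("triclinic boxes are not supported")
            box = np.array([a, b, c]) / 10.0
        elif rec in ("ATOM  ", "HETATM"):
            try:
                resids.append(int(line[22:26]))
                # columns 18-21: 3-char standard names plus the 4-char
                # lipid resnames common in membrane PDBs
                resnames.append(line[17:21].strip())
                names.append(line[12:16].strip())
                coords.append((float(line[30:38]) / 10.0,
                               float(line[38:46]) / 10.0,
                               float(line[46:54]) / 10.0))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed PDB line: {line!r}") from exc
    if not coords:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    xyz = np.asarray(coords)
    if box is None:
        box = xyz.max(axis=0) - xyz.min(axis=0) + 1.0
    mol_id, mol_type, chain = _assign_molecules(
        np.asarray(resids), resnames, aliases)
    return Frame(xyz, box, np.array(names, dtype=object), mol_id, mol_type,
                 np.asarray(resids), chain, title=str(path))


# ---------------------------------------------------------------------------
# XVG energy tables

@dataclass
class EnergyTable:
    """Tabular energy time series (kJ/mol) with tagged columns.

    ``data`` holds the time column plus one column per energy series;
    ``tags`` maps a column name to its ``(species, term)`` pair, with
    term one of ``lennard_jones`` / ``coulomb``.
    """

    data: pd.DataFrame
    tags: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col, (species, term) in self.tags.items():
            if col not in self.data.columns:
                raise ValueError(f"tagged column {col!r} missing from table")
            if term not in ENERGY_TERMS:
                raise ValueError(f"unknown energy term {term!r}")

    @property
    def times(self) -> np.ndarray:
        return self.data.iloc[:, 0].to_numpy()

    def window(self, span: float) -> pd.DataFrame:
        """Rows whose time lies within ``span`` of the final time."""
        t = self.times
        return self.data[t >= t[-1] - span]


_LEGEND_RE = re.compile(r'@\s*s(\d+)\s+legend\s+"([^"]*)"')

_TERM_TOKENS = {
    "lj": "lennard_jones", "lj-sr": "lennard_jones",
    "lennard-jones": "lennard_jones", "vdw": "lennard_jones",
    "coul": "coulomb", "coul.": "coulomb", "coul-sr": "coulomb",
    "coulomb": "coulomb",
}


def _tag_from_legend(legend: str) -> tuple[str, str] | None:
    """Infer a (species, term) tag from a legend such as 'LJ-SR:Protein-DPPC'."""
    tokens = re.split(r"[\s:\-_()]+", legend)
    species = next((t.upper() for t in tokens if t.upper() in LIPID_TYPES), None)
    term = next((_TERM_TOKENS[t.lower()] for t in tokens
                 if t.lower() in _TERM_TOKENS), None)
    if species and term:
        return species, term
    return None


def read_xvg(path: str | Path) -> EnergyTable:
    """Read an XVG table; legend lines become column names and tags."""
    legends: dict[int, str] = {}
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("@"):
            m = _LEGEND_RE.match(stripped)
            if m:
                legends[int(m.group(1))] = m.group(2)
            continue
        try:
            rows.append([float(x) for x in stripped.split()])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric row") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: ragged rows")
    columns = ["time"]
    tags: dict[str, tuple[str, str]] = {}
    for j in range(1, width):
        legend = legends.get(j - 1)
        name = legend if legend else f"col{j}"
        columns.append(name)
        if legend:
            tag = _tag_from_legend(legend)
            if tag:
                tags[name] = tag
    df = pd.DataFrame(rows, columns=columns)
    return EnergyTable(df, tags)


def write_xvg(table: EnergyTable, path: str | Path) -> None:
    """Serialize an energy table back to XVG (legends preserved)."""
    with open(path, "w") as fh:
        fh.write("# raftbind energy table\n")
        for j, col in enumerate(table.data.columns[1:]):
            fh.write(f'@ s{j} legend "{col}"\n')
        for _, row in table.data.iterrows():
            fh.write(" ".join(f"{v:.6f}" for v in row.to_numpy()) + "\n")
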