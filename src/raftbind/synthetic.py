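"""Synthetic raft membranes and binding trajectories with planted truth.

The generator emulates the three raft systems used throughout the
pipeline - CO-raft (DPPC/DLPC/CHOL with coexisting Lo, Ld and Lod
domains), GM-raft (one-leaflet GM1 clusters) and PS-raft (one-leaflet
POPS clusters) - at their published molecule counts, plus K18 bead
chains approaching and binding the surface at a scripted time.

Lipids are coarse stick figures (one head bead plus a linear chain of
beads); no physics is simulated.  The lateral layout is planted so the
0.5 nm same-species contact rule recovers it:

* Lo core: DPPC on a dense square lattice (0.45 nm spacing) in a disc;
* Ld core: DLPC on an equally dense disc across the box;
* Lod: the remaining DPPC and DLPC interleaved on a sparse lattice
  (0.55 nm spacing, no same-species pair within 0.5 nm) surrounding
  the Lo core;
* CHOL: single beads riding just outside the head bead of a host PC,
  with hosts drawn from Lo/Ld/Lod at planted fractions (60/10/30 by
  default, the composition reported for the CO- and GM-rafts);
* GM1/POPS: a dense disc on the designated leaflet only.

Every molecule's planted label and leaflet are returned in a
:class:`GroundTruth` sidecar, index-aligned with the frame by
molecule id.  All randomness flows from the spec/script seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import Frame, Trajectory

#: published total molecule counts per raft system
RAFT_COUNTS: Mapping[str, Mapping[str, int]] = {
    "CO": {"DPPC": 828, "DLPC": 540, "CHOL": 576},
    "GM": {"GM1": 36, "DPPC": 709, "DLPC": 407, "CHOL": 410},
    "PS": {"POPS": 162, "DPPC": 666, "DLPC": 540, "CHOL": 576},
}

DENSE_SPACING = 0.45  # nm, guarantees same-species contact at the 0.5 nm rule
SPARSE_SPACING = 0.55  # nm, guarantees no same-species contact
REGION_GAP = 0.7  # nm clearance between planted regions
BASE_JITTER = 0.015  # nm, uniform per-lipid placement jitter
FRAME_JITTER = 0.005  # nm, uniform per-frame thermal jitter
CHAIN_STEP = 0.24  # nm z-spacing of chain beads
HEAD_DROP = 0.25  # nm from head bead to first chain bead
LEAFLET_OFFSET = 2.0  # nm from bilayer midplane to head-bead plane
MAGIC_COS2 = 1.0 / 3.0  # cos^2 of the magic angle, P2 = 0


@dataclass
class RaftSpec:
    """Recipe for one planted raft membrane."""

    counts: dict[str, int]
    box: tuple[float, float, float] = (22.0, 22.0, 20.0)
    lo_fraction_dppc: float = 0.33  # fraction of DPPC planted in the Lo core
    ld_fraction_dlpc: float = 0.25  # fraction of DLPC planted in the Ld core
    chol_fractions: tuple[float, float, float] = (0.60, 0.10, 0.30)  # Lo/Ld/Lod
    cluster_leaflet: str = "upper"  # leaflet carrying GM1/POPS
    n_chain_beads: int = 7
    with_water: bool = False
    n_water: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("molecule counts must be nonnegative")
        if self.cluster_leaflet not in ("upper", "lower"):
            raise ValueError("cluster_leaflet must be 'upper' or 'lower'")
        if not 0 <= self.lo_fraction_dppc <= 1 or not 0 <= self.ld_fraction_dlpc <= 1:
            raise ValueError("core fractions must be in [0, 1]")
        if abs(sum(self.chol_fractions) - 1.0) > 1e-9:
            raise ValueError("chol_fractions must sum to 1")


@dataclass
class BindingScript:
    """Scripted approach-and-bind motion of the protein."""

    binding_time: float | None = 5.0  # us; None = never binds
    initial_height: float = 5.0  # nm above the membrane surface
    lateral_offset: tuple[float, float] = (0.0, 0.0)  # nm from box center
    bound_mindist: float = 0.4  # nm protein-membrane gap once bound
    jitter: float = 0.05  # nm bound-state vertical jitter amplitude
    n_chains: int = 4
    chain_length: int = 130
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_height <= 0:
            raise ValueError("initial height must be positive")
        if self.bound_mindist <= 0:
            raise ValueError("bound mindist must be positive")


@dataclass
class GroundTruth:
    """Planted per-molecule truth, index-aligned with the frame."""

    domain_label: dict[int, str]  # molecule_id -> planted label
    leaflet: dict[int, str]  # molecule_id -> upper/lower
    species: dict[int, str]
    binding_time: float | None = None
    binding_frame: int | None = None
    order_targets: dict[str, np.ndarray] = field(default_factory=dict)


def raft_spec(kind: str, **overrides) -> RaftSpec:
    """RaftSpec for one of the published systems ('CO', 'GM', 'PS')."""
    kind = kind.upper()
    if kind not in RAFT_COUNTS:
        raise ValueError(f"unknown raft kind {kind!r}; choose from {list(RAFT_COUNTS)}")
    spec = RaftSpec(counts=dict(RAFT_COUNTS[kind]))
    if kind == "PS":
        spec = replace(spec, chol_fractions=(0.50, 0.15, 0.35))
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# lattice helpers

def _lattice_points(center: np.ndarray, n: int, spacing: float,
                    exclude: Sequence[tuple[np.ndarray, float]] = (),
                    box_xy: np.ndarray | None = None) -> np.ndarray:
    """``n`` square-lattice points nearest ``center``, radius-sorted.

    ``exclude`` lists (center, radius) discs the lattice must avoid;
    when ``box_xy`` is given the exclusion uses minimum-image lateral
    distances, so discs are avoided across periodic boundaries too.
    Coordinates are *not* wrapped; callers wrap into the box later.
    """
    if n == 0:
        return np.empty((0, 2))
    # generous candidate grid: area n * spacing^2 plus exclusion area
    area = n * spacing * spacing + sum(np.pi * r * r for _, r in exclude)
    radius = max(np.sqrt(area / np.pi) * 1.6, spacing * 2)
    k = int(np.ceil(radius / spacing))
    ticks = np.arange(-k, k + 1) * spacing
    gx, gy = np.meshgrid(ticks, ticks)
    pts = np.column_stack([gx.ravel(), gy.ravel()]) + center
    keep = np.ones(len(pts), dtype=bool)
    for c, r in exclude:
        d = pts - c
        if box_xy is not None:
            d = d - box_xy * np.round(d / box_xy)
        keep &= np.linalg.norm(d, axis=1) > r
    pts = pts[keep]
    order = np.argsort(np.linalg.norm(pts - center, axis=1), kind="stable")
    if len(order) < n:
        raise ValueError(
            f"cannot place {n} molecules at spacing {spacing} without overlap")
    return pts[order[:n]]


def _split_leaflets(count: int) -> tuple[int, int]:
    """Split a total count over (upper, lower), upper taking the odd one."""
    lower = count // 2
    return count - lower, lower


def sample_tilt_cos2(target_p2: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw cos^2(theta) values whose P2 expectation equals ``target_p2``.

    Uses a two-point mixture: for targets in [0, 1], between perfect
    alignment (P2 = 1) and the magic angle (P2 = 0); for targets in
    [-0.5, 0), between the magic angle and 90 degrees (P2 = -0.5).
    """
    if not -0.5 <= target_p2 <= 1.0:
        raise ValueError(f"target P2 {target_p2} outside [-0.5, 1]")
    if target_p2 >= 0:
        p = target_p2  # probability of perfect alignment
        aligned = rng.random(size) < p
        return np.where(aligned, 1.0, MAGIC_COS2)
    p = target_p2 / -0.5  # probability of 90-degree tilt
    flat = rng.random(size) < p
    return np.where(flat, 0.0, MAGIC_COS2)


def generate_chain_ensemble(
    target_p2: float | Sequence[float],
    n_chains: int,
    chain_length: int = 9,
    segment_length: float = 0.4,
    seed: int = 0,
) -> np.ndarray:
    """Chains whose per-carbon flanking-vector order matches a target.

    Returns coordinates of shape ``(n_chains, chain_length, 3)``.  The
    flanking vector of interior carbon ``i`` (the vector from bead
    ``i-1`` to bead ``i+1``) has tilt drawn so that the ensemble
    expectation of ``0.5 (3 cos^2 theta - 1)`` equals the target for
    that carbon.  ``target_p2`` may be a scalar or one value per
    interior carbon (``chain_length - 2`` values).

    The construction exploits that flanking vectors couple only beads
    of the same parity: even and odd beads form two interleaved
    subchains, so every flanking vector can be set independently.
    """
    targets = np.broadcast_to(
        np.asarray(target_p2, dtype=float), (chain_length - 2,)
    ).copy()
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_chains, chain_length, 3))
    coords[:, 1, 0] = 0.08  # seed the odd subchain slightly off-axis
    coords[:, 1, 2] = -0.5 * segment_length
    for i in range(1, chain_length - 1):  # interior carbons, 0-based
        cos2 = sample_tilt_cos2(targets[i - 1], n_chains, rng)
        cos_t = np.sqrt(cos2)
        sin_t = np.sqrt(1.0 - cos2)
        phi = rng.uniform(0, 2 * np.pi, n_chains)
        step = segment_length * np.column_stack(
            [sin_t * np.cos(phi), sin_t * np.sin(phi), -cos_t]
        )
        coords[:, i + 1] = coords[:, i - 1] + step
    return coords


# ---------------------------------------------------------------------------
# molecule builders

def _pc_atoms(xy: np.ndarray, z_head: float, sign: float, n_chain: int
              ) -> tuple[np.ndarray, list[str]]:
    """Head bead plus a vertical chain pointing toward the midplane."""
    n = n_chain + 1
    coords = np.tile(np.append(xy, z_head), (n, 1))
    for i in range(1, n):
        coords[i, 2] = z_head - sign * (HEAD_DROP + CHAIN_STEP * (i - 1))
    names = ["PO4"] + [f"C{i}" for i in range(1, n_chain + 1)]
    return coords, names


def _gm1_atoms(xy: np.ndarray, z_head: float, sign: float, n_chain: int
               ) -> tuple[np.ndarray, list[str]]:
    """GM1: bulky two-bead headgroup protruding outward, then a chain."""
    chain, names = _pc_atoms(xy, z_head, sign, n_chain)
    extra = np.append(xy, z_head + sign * 0.2)[None, :]
    return np.vstack([extra, chain]), ["GM0"] + names


def _chol_atoms(xy: np.ndarray, z_head: float, sign: float, stack: int
                ) -> tuple[np.ndarray, list[str]]:
    """Single ROH bead just outside its host PC's head bead."""
    z = z_head + sign * HEAD_DROP * (stack + 1)
    return np.array([[xy[0], xy[1], z]]), ["ROH"]


# ---------------------------------------------------------------------------
# raft generation

def generate_raft(spec: RaftSpec) -> tuple[Frame, GroundTruth]:
    """Build one membrane frame with planted domain ground truth."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    zmid = box[2] / 2.0
    center = box[:2] / 2.0
    ld_center = center + np.array([box[0] / 2.0, 0.0])
    cluster_center = center + np.array([0.0, box[1] / 2.0])

    cluster_species = next(
        (s for s in ("GM1", "POPS") if spec.counts.get(s, 0) > 0), None)

    n_dppc = spec.counts.get("DPPC", 0)
    n_dlpc = spec.counts.get("DLPC", 0)
    n_chol = spec.counts.get("CHOL", 0)
    n_cluster = spec.counts.get(cluster_species, 0) if cluster_species else 0

    records: list[dict] = []  # one per molecule, in emission order

    for leaflet, sign, z_head in (
        ("upper", +1.0, zmid + LEAFLET_OFFSET),
        ("lower", -1.0, zmid - LEAFLET_OFFSET),
    ):
        idx = 0 if leaflet == "upper" else 1
        dppc_here = _split_leaflets(n_dppc)[idx]
        dlpc_here = _split_leaflets(n_dlpc)[idx]
        chol_here = _split_leaflets(n_chol)[idx]
        cluster_here = n_cluster if leaflet == spec.cluster_leaflet else 0

        n_lo = round(spec.lo_fraction_dppc * dppc_here)
        n_ld = round(spec.ld_fraction_dlpc * dlpc_here)
        n_lod_dppc = dppc_here - n_lo
        n_lod_dlpc = dlpc_here - n_ld

        lo_pts = _lattice_points(center, n_lo, DENSE_SPACING)
        lo_radius = (np.linalg.norm(lo_pts - center, axis=1).max()
                     if len(lo_pts) else 0.0)
        ld_pts = _lattice_points(ld_center, n_ld, DENSE_SPACING)
        ld_radius = (np.linalg.norm(ld_pts - ld_center, axis=1).max()
                     if len(ld_pts) else 0.0)
        cluster_pts = _lattice_points(cluster_center, cluster_here, DENSE_SPACING)
        cluster_radius = (np.linalg.norm(cluster_pts - cluster_center, axis=1).max()
                          if len(cluster_pts) else 0.0)

        exclude = [(center, lo_radius + REGION_GAP),
                   (ld_center, ld_radius + REGION_GAP)]
        if cluster_species:
            # keep the cluster zone clear on both leaflets so AL shells
            # over the cluster see GM1/POPS, not underlying PCs
            exclude.append((cluster_center, cluster_radius + REGION_GAP))
        lod_pts = _lattice_points(center, n_lod_dppc + n_lod_dlpc,
                                  SPARSE_SPACING, exclude=exclude,
                                  box_xy=box[:2])
        # interleave species along the radius-sorted Lod sites
        lod_species = _interleave(n_lod_dppc, n_lod_dlpc)

        pc_records_here: list[dict] = []
        for xy in lo_pts:
            pc_records_here.append(dict(
                species="DPPC", label="Lo", leaflet=leaflet, xy=xy))
        for xy, sp in zip(lod_pts, lod_species):
            pc_records_here.append(dict(
                species=sp, label="Lod", leaflet=leaflet, xy=xy))
        for xy in ld_pts:
            pc_records_here.append(dict(
                species="DLPC", label="Ld", leaflet=leaflet, xy=xy))

        # cholesterol hosts, planted at the target Lo/Ld/Lod fractions
        by_label = {
            "Lo": [r for r in pc_records_here if r["label"] == "Lo"],
            "Ld": [r for r in pc_records_here if r["label"] == "Ld"],
            "Lod": [r for r in pc_records_here if r["label"] == "Lod"],
        }
        want = _chol_split(chol_here, spec.chol_fractions,
                           {k: len(v) for k, v in by_label.items()})
        chol_records_here: list[dict] = []
        for label, n_want in want.items():
            hosts = by_label[label]
            if n_want and not hosts:
                raise ValueError(
                    f"no {label} PC lipids available to host cholesterol")
            for j in range(n_want):
                host = hosts[j % len(hosts)]
                chol_records_here.append(dict(
                    species="CHOL", label=f"{label}-CHOL", leaflet=leaflet,
                    xy=host["xy"], stack=j // len(hosts)))

        cluster_records_here = [
            dict(species=cluster_species,
                 label="GM-cluster" if cluster_species == "GM1" else "PS-cluster",
                 leaflet=leaflet, xy=xy)
            for xy in cluster_pts
        ]

        for rec in pc_records_here + chol_records_here + cluster_records_here:
            rec["sign"] = sign
            rec["z_head"] = z_head
            records.append(rec)

    # emit atoms
    coords_list: list[np.ndarray] = []
    names: list[str] = []
    mol_id: list[int] = []
    mol_type: list[str] = []
    resid: list[int] = []
    chain_id: list[str] = []
    labels: dict[int, str] = {}
    leaflets: dict[int, str] = {}
    species_of: dict[int, str] = {}

    for m, rec in enumerate(records):
        jitter = rng.uniform(-BASE_JITTER, BASE_JITTER, 3)
        xy = np.asarray(rec["xy"], dtype=float)
        if rec["species"] == "CHOL":
            atoms, atom_names = _chol_atoms(
                xy, rec["z_head"], rec["sign"], rec.get("stack", 0))
        elif rec["species"] == "GM1":
            atoms, atom_names = _gm1_atoms(
                xy, rec["z_head"], rec["sign"], spec.n_chain_beads)
        else:
            atoms, atom_names = _pc_atoms(
                xy, rec["z_head"], rec["sign"], spec.n_chain_beads)
        atoms = atoms + jitter
        atoms[:, 0] %= box[0]
        atoms[:, 1] %= box[1]
        coords_list.append(atoms)
        names.extend(atom_names)
        mol_id.extend([m] * len(atoms))
        mol_type.extend([rec["species"]] * len(atoms))
        resid.extend([m + 1] * len(atoms))
        chain_id.extend([""] * len(atoms))
        labels[m] = rec["label"]
        leaflets[m] = rec["leaflet"]
        species_of[m] = rec["species"]

    next_mol = len(records)
    if spec.with_water:
        surface_z = max(c[:, 2].max() for c in coords_list)
        n_side = int(np.ceil(np.sqrt(spec.n_water / 3)))
        made = 0
        for layer in range(3):
            for i in range(n_side):
                for j in range(n_side):
                    if made >= spec.n_water:
                        break
                    pos = np.array([
                        (i + 0.5) * box[0] / n_side,
                        (j + 0.5) * box[1] / n_side,
                        surface_z + 0.8 + layer * 1.0,
                    ]) + rng.uniform(-0.05, 0.05, 3)
                    coords_list.append(pos[None, :])
                    names.append("W")
                    mol_id.append(next_mol)
                    mol_type.append("water")
                    resid.append(next_mol + 1)
                    chain_id.append("")
                    next_mol += 1
                    made += 1

    frame = Frame(
        np.vstack(coords_list), box, np.array(names, dtype=object),
        np.array(mol_id), np.array(mol_type, dtype=object),
        np.array(resid), np.array(chain_id, dtype=object),
        title="synthetic raft",
    )
    order = np.ones(max(spec.n_chain_beads - 2, 0))
    truth = GroundTruth(
        domain_label=labels, leaflet=leaflets, species=species_of,
        order_targets={s: order.copy()
                       for s in ("DPPC", "DLPC", "POPS", "GM1")
                       if spec.counts.get(s, 0) > 0},
    )
    return frame, truth


def _interleave(n_a: int, n_b: int) -> list[str]:
    """Mix n_a DPPC and n_b DLPC tokens as evenly as possible."""
    out: list[str] = []
    a = b = 0
    while a < n_a or b < n_b:
        # pick whichever species is most behind its target share
        if b >= n_b or (a < n_a and a * (n_b or 1) <= b * (n_a or 1)):
            out.append("DPPC")
            a += 1
        else:
            out.append("DLPC")
            b += 1
    return out


def _chol_split(total: int, fractions: tuple[float, float, float],
                available: Mapping[str, int]) -> dict[str, int]:
    """Integer CHOL counts per host domain at the planted fractions."""
    want = {
        "Lo": int(round(fractions[0] * total)),
        "Ld": int(round(fractions[1] * total)),
    }
    want["Lod"] = total - want["Lo"] - want["Ld"]
    for label in ("Lo", "Ld", "Lod"):
        if want[label] > 0 and available.get(label, 0) == 0:
            # fall back to Lod (then Lo) if a planted domain is absent
            target = "Lod" if label != "Lod" and available.get("Lod") else "Lo"
            want[target] = want.get(target, 0) + want[label]
            want[label] = 0
    return want


# ---------------------------------------------------------------------------
# protein and trajectories

def _protein_chains(n_chains: int, chain_length: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compact serpentine bead blob: coordinates, chain index, resid."""
    per_row = 12
    spacing = 0.35
    coords = np.zeros((n_chains * chain_length, 3))
    chain_idx = np.zeros(n_chains * chain_length, dtype=int)
    resids = np.zeros(n_chains * chain_length, dtype=int)
    k = 0
    for c in range(n_chains):
        for r in range(chain_length):
            row, col = divmod(r, per_row)
            if row % 2:
                col = per_row - 1 - col
            coords[k] = (col * spacing, row * spacing, c * 0.45)
            chain_idx[k] = c
            resids[k] = r + 1
            k += 1
    coords += rng.uniform(-0.03, 0.03, coords.shape)
    coords[:, :2] -= coords[:, :2].mean(axis=0)
    return coords, chain_idx, resids


def generate_trajectory(
    spec: RaftSpec,
    script: BindingScript,
    n_frames: int = 100,
    dt: float = 0.15,
) -> tuple[Trajectory, GroundTruth]:
    """Scripted binding trajectory: membrane plus descending protein.

    The protein hovers at ``initial_height`` above the membrane surface
    and drops abruptly to ``bound_mindist`` at the first frame whose
    time reaches ``script.binding_time``, staying there with bounded
    jitter.  Times are in the CG convention (microseconds).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    base, truth = generate_raft(spec)
    rng = np.random.default_rng(script.seed + 1)

    prot_xyz, chain_idx, prot_resids = _protein_chains(
        script.n_chains, script.chain_length, rng)
    lateral = base.box[:2] / 2.0 + np.asarray(script.lateral_offset)
    # script the gap against the PC head-bead plane; outward-protruding
    # beads (CHOL, GM1 headgroups) sit ~0.2-0.5 nm above it, so the
    # realized all-lipid mindist in the bound state can be slightly
    # below ``bound_mindist`` - still well inside the bound regime.
    head_mask = np.array([n == "PO4" for n in base.atom_names])
    surface_z = (base.coordinates[head_mask, 2].max() if head_mask.any()
                 else base.coordinates[:, 2].max())

    times = np.arange(n_frames) * dt
    if script.binding_time is None:
        binding_frame = None
    else:
        hits = np.flatnonzero(times >= script.binding_time)
        binding_frame = int(hits[0]) if len(hits) else None

    prot_bottom = prot_xyz[:, 2].min()
    n_mol_membrane = int(base.molecule_id.max()) + 1

    frames: list[Frame] = []
    for i in range(n_frames):
        mem = base.coordinates + rng.uniform(
            -FRAME_JITTER, FRAME_JITTER, base.coordinates.shape)
        if binding_frame is not None and i >= binding_frame:
            gap = script.bound_mindist + rng.uniform(0, script.jitter)
        else:
            gap = script.initial_height + rng.uniform(0, script.jitter)
        z_shift = surface_z + gap - prot_bottom
        shift = np.array([lateral[0], lateral[1], z_shift])
        prot = prot_xyz + shift + rng.uniform(-0.02, 0.02, 3)

        coords = np.vstack([mem, prot])
        frame = Frame(
            coords, base.box,
            np.concatenate([base.atom_names,
                            np.array(["BB"] * len(prot), dtype=object)]),
            np.concatenate([base.molecule_id, n_mol_membrane + chain_idx]),
            np.concatenate([base.molecule_type,
                            np.array(["protein"] * len(prot), dtype=object)]),
            np.concatenate([base.residue_index, prot_resids]),
            np.concatenate([base.chain_id,
                            np.array([chr(ord("A") + c) for c in chain_idx],
                                     dtype=object)]),
            title="synthetic binding trajectory",
            time=float(times[i]),
        )
        frames.append(frame)

    truth.binding_frame = binding_frame
    truth.binding_time = (float(times[binding_frame])
                          if binding_frame is not None else None)
    return Trajectory(frames), truth


def plant_chain_order(
    frame: Frame,
    molecule_ids: Sequence[int],
    target_p2: float | Sequence[float],
    seed: int = 0,
) -> Frame:
    """Rebuild the chain beads of selected lipids at a target P2 profile.

    Head beads stay in place; chain beads are regenerated with the
    interleaved-subchain construction so each interior carbon's
    flanking vector hits the requested order parameter in expectation.
    Note that tilted chains wander laterally, so planted *domain*
    labels are no longer guaranteed to be recoverable on the modified
    lipids - use this on fixtures probing order, not classification.
    """
    new = frame.select(np.ones(frame.n_atoms, dtype=bool))
    wanted = set(int(m) for m in molecule_ids)
    rng = np.random.default_rng(seed)
    for mol, atom_idx in new.molecules().items():
        if mol not in wanted:
            continue
        chain_mask = np.array(
            [str(new.atom_names[i]).startswith("C") for i in atom_idx])
        chain_atoms = atom_idx[chain_mask]
        if len(chain_atoms) < 3:
            continue
        head = atom_idx[~chain_mask][0]
        head_pos = new.coordinates[head]
        sign = 1.0 if head_pos[2] >= new.box[2] / 2.0 else -1.0
        chain = generate_chain_ensemble(
            target_p2, 1, chain_length=len(chain_atoms),
            segment_length=2 * CHAIN_STEP,
            seed=int(rng.integers(2**31)),
        )[0]
        chain[:, 2] *= sign  # point toward the midplane on either leaflet
        anchor = head_pos + np.array([0.0, 0.0, -sign * HEAD_DROP])
        new.coordinates[chain_atoms] = anchor + chain
    return new


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Tab-separated sidecar: molecule_id, species, planted label, leaflet."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tspecies\tlabel\tleaflet\n")
        for mol in sorted(truth.domain_label):
            fh.write(f"{mol}\t{truth.species[mol]}\t"
                     f"{truth.domain_label[mol]}\t{truth.leaflet[mol]}\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    labels: dict[int, str] = {}
    leaflets: dict[int, str] = {}
    species: dict[int, str] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        mol_s, sp, label, leaflet = line.split("\t")
        mol = int(mol_s)
        labels[mol] = label
        leaflets[mol] = leaflet
        species[mol] = sp
    return GroundTruth(domain_label=labels, leaflet=leaflets, species=species)
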