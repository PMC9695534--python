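"""Shared fixtures: small planted rafts and ad-hoc random frames."""

from __future__ import annotations

import numpy as np
import pytest

import raftbind as rb
from raftbind.io import Frame


SMALL_COUNTS = {"DPPC": 120, "DLPC": 80, "CHOL": 60}
SMALL_BOX = (14.0, 14.0, 20.0)


@pytest.fixture(scope="session")
def co_raft():
    """Full-size CO-raft frame with ground truth (published counts)."""
    return rb.generate_raft(rb.raft_spec("CO", seed=11))


@pytest.fixture(scope="session")
def small_raft():
    """Down-scaled CO-style raft for fast per-test generation."""
    spec = rb.raft_spec("CO", seed=5, counts=dict(SMALL_COUNTS), box=SMALL_BOX)
    return rb.generate_raft(spec)


@pytest.fixture(scope="session")
def binding_traj():
    """Scripted binding trajectory over the small raft's Lod annulus."""
    spec = rb.raft_spec("CO", seed=5, counts=dict(SMALL_COUNTS), box=SMALL_BOX)
    script = rb.BindingScript(binding_time=5.0, seed=5, n_chains=2,
                              lateral_offset=(2.5, 0.0))
    return rb.generate_trajectory(spec, script, n_frames=60, dt=0.15)


def make_frame(coords, mol_ids, species, box=(10.0, 10.0, 10.0),
               names=None, resids=None, chains=None, time=None) -> Frame:
    """Assemble a Frame from per-atom arrays with minimal boilerplate."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    mol_ids = np.asarray(mol_ids)
    species = np.asarray(species, dtype=object)
    if names is None:
        names = np.array(["PO4"] * n, dtype=object)
    if resids is None:
        resids = mol_ids + 1
    if chains is None:
        chains = np.array(
            ["A" if s == "protein" else "" for s in species], dtype=object)
    return Frame(coords, np.asarray(box, dtype=float), np.asarray(names, dtype=object),
                 mol_ids, species, np.asarray(resids), np.asarray(chains, dtype=object),
                 time=time)


def random_lipid_frame(rng: np.random.Generator, n_lipids: int,
                       box=(6.0, 6.0, 6.0), atoms_per_lipid=3,
                       with_protein=False) -> Frame:
    """Uniformly random multi-atom lipids (optionally plus protein beads)."""
    species_pool = ["DPPC", "DLPC", "CHOL"]
    coords, mols, species, names, resids, chains = [], [], [], [], [], []
    for m in range(n_lipids):
        sp = species_pool[rng.integers(len(species_pool))]
        base = rng.uniform([0, 0, 0], box)
        k = 1 if sp == "CHOL" else atoms_per_lipid
        for a in range(k):
            coords.append(base + rng.normal(0, 0.15, 3))
            mols.append(m)
            species.append(sp)
            names.append("ROH" if sp == "CHOL" else ("PO4" if a == 0 else f"C{a}"))
            resids.append(m + 1)
            chains.append("")
    if with_protein:
        m = n_lipids
        base = rng.uniform([0, 0, 0], box)
        for a in range(5):
            coords.append(base + rng.normal(0, 0.2, 3))
            mols.append(m)
            species.append("protein")
            names.append("BB")
            resids.append(a + 1)
            chains.append("A")
    return make_frame(coords, np.array(mols), species, box=box,
                      names=np.array(names, dtype=object),
                      resids=np.array(resids),
                      chains=np.array(chains, dtype=object))
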