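"""Domain classification rules, invariants and oracle equivalence."""

import numpy as np
import pytest

import raftbind as rb
from raftbind import domains

from conftest import make_frame, random_lipid_frame


def _two_dppc_one_isolated(box=(10.0, 10.0, 10.0)):
    # two DPPC 0.4 nm apart, one DPPC far away; all same leaflet
    coords = [[1.0, 1.0, 7.0], [1.4, 1.0, 7.0], [5.0, 5.0, 7.0],
              [1.0, 8.0, 3.0]]  # plus one lower-leaflet DPPC for a midplane
    mols = np.array([0, 1, 2, 3])
    species = ["DPPC"] * 4
    return make_frame(coords, mols, species, box=box)


class TestLeaflets:
    def test_planted_leaflets_recovered(self, co_raft):
        frame, truth = co_raft
        leaf = domains.assign_leaflets(frame)
        assert all(leaf[m] == truth.leaflet[m] for m in truth.leaflet)

    def test_flat_frame_rejected(self):
        coords = [[i, 0.0, 5.0] for i in range(4)]
        frame = make_frame(coords, np.arange(4), ["DPPC"] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            domains.assign_leaflets(frame)

    def test_no_lipids_rejected(self):
        frame = make_frame([[1, 1, 1]], np.array([0]), ["protein"],
                           names=np.array(["BB"], dtype=object))
        with pytest.raises(ValueError, match="no lipid"):
            domains.assign_leaflets(frame)

    def test_gm_raft_cluster_on_one_leaflet(self):
        frame, truth = rb.generate_raft(rb.raft_spec("GM", seed=6))
        leaf = domains.assign_leaflets(frame)
        gm1 = [m for m, s in truth.species.items() if s == "GM1"]
        assert {leaf[m] for m in gm1} == {"upper"}


class TestClassifyPc:
    def test_contact_rule_direct(self):
        frame = _two_dppc_one_isolated()
        a = domains.classify_pc(frame, cutoff=0.5)
        assert a.labels[0] == "Lo" and a.labels[1] == "Lo"
        assert a.labels[2] == "Lod"  # isolated on the upper leaflet

    def test_single_lipid_per_leaflet_is_lod(self):
        coords = [[1, 1, 7.0], [1, 1, 3.0]]
        frame = make_frame(coords, np.array([0, 1]), ["DPPC", "DPPC"])
        a = domains.classify_pc(frame, cutoff=0.5)
        assert a.labels[0] == "Lod" and a.labels[1] == "Lod"

    def test_cross_leaflet_contacts_excluded(self):
        # vertically adjacent DPPC on opposite leaflets stay Lod
        coords = [[1, 1, 5.2], [1, 1, 4.8], [8, 8, 5.2], [8, 8, 4.8]]
        frame = make_frame(coords, np.arange(4), ["DPPC"] * 4)
        a = domains.classify_pc(frame, cutoff=0.5)
        assert set(a.labels.values()) == {"Lod"}

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            domains.classify_pc(_two_dppc_one_isolated(), cutoff=0.0)

    def test_planted_co_raft_recovery(self, co_raft):
        frame, truth = co_raft
        a = rb.classify_frame(frame, 0.5)
        assert rb.label_agreement(a, truth.domain_label) >= 0.95

    def test_cutoff_monotonicity(self, small_raft):
        frame, _ = small_raft
        a_small = domains.classify_pc(frame, cutoff=0.4)
        a_large = domains.classify_pc(frame, cutoff=0.8)
        for label in ("Lo", "Ld"):
            small_set = {m for m, v in a_small.labels.items() if v == label}
            large_set = {m for m, v in a_large.labels.items() if v == label}
            assert small_set <= large_set

    def test_translation_by_box_vector_invariant(self, small_raft):
        frame, _ = small_raft
        shifted = frame.select(np.ones(frame.n_atoms, bool))
        shifted.coordinates = shifted.coordinates + shifted.box
        a = rb.classify_frame(frame, 0.5)
        b = rb.classify_frame(shifted, 0.5)
        assert a.labels == b.labels

    def test_label_partition_invariant(self, small_raft):
        frame, truth = small_raft
        a = rb.classify_frame(frame, 0.5)
        for m, sp in truth.species.items():
            label = a.labels[m]
            if sp == "DPPC":
                assert label in ("Lo", "Lod")
            elif sp == "DLPC":
                assert label in ("Ld", "Lod")
            elif sp == "CHOL":
                assert label in ("Lo-CHOL", "Ld-CHOL", "Lod-CHOL")


class TestAssignChol:
    def test_nearest_domain_wins(self):
        coords = [[1, 1, 7.0], [1.4, 1, 7.0],  # Lo pair
                  [5, 5, 7.0],  # Lod singleton
                  [1.2, 1.2, 7.3],  # CHOL near the Lo pair
                  [1, 8, 3.0]]  # lower-leaflet DPPC for midplane balance
        frame = make_frame(
            coords, np.arange(5), ["DPPC", "DPPC", "DPPC", "CHOL", "DPPC"],
            names=np.array(["PO4", "PO4", "PO4", "ROH", "PO4"], dtype=object))
        a = rb.classify_frame(frame, 0.5)
        assert a.labels[3] == "Lo-CHOL"

    def test_exact_tie_prefers_lo(self):
        # CHOL equidistant between an Lo pair member and an Ld pair member
        coords = [[2.0, 1, 7.0], [2.0, 1.4, 7.0],  # Lo pair
                  [4.0, 1, 7.0], [4.0, 1.4, 7.0],  # Ld pair
                  [3.0, 1, 7.0],  # CHOL, exactly 1.0 from each pair
                  [3.0, 5, 3.0]]  # lower-leaflet filler
        frame = make_frame(
            coords, np.arange(6),
            ["DPPC", "DPPC", "DLPC", "DLPC", "CHOL", "DPPC"],
            names=np.array(["PO4"] * 4 + ["ROH", "PO4"], dtype=object))
        a = rb.classify_frame(frame, 0.5)
        assert a.labels[4] == "Lo-CHOL"

    def test_distant_chol_flagged_but_labelled(self):
        coords = [[1, 1, 7.0], [1.4, 1, 7.0], [5, 5, 7.2], [1, 8, 3.0]]
        frame = make_frame(
            coords, np.arange(4), ["DPPC", "DPPC", "CHOL", "DPPC"],
            names=np.array(["PO4", "PO4", "ROH", "PO4"], dtype=object))
        a = rb.classify_frame(frame, 0.5)
        assert a.labels[2] == "Lo-CHOL"
        assert 2 in a.chol_flagged

    def test_frame_without_pc_rejected(self):
        frame = make_frame([[1, 1, 7.0], [1, 1, 3.0]], np.array([0, 1]),
                           ["CHOL", "CHOL"],
                           names=np.array(["ROH", "ROH"], dtype=object))
        pc = rb.DomainAssignment({}, {}, 0.5)
        with pytest.raises(ValueError, match="no PC"):
            domains.assign_chol(frame, pc)

    def test_planted_chol_split_recovered(self, co_raft):
        frame, truth = co_raft
        a = rb.classify_frame(frame, 0.5)
        chol = [m for m, s in truth.species.items() if s == "CHOL"]
        rec = {lab: 0 for lab in ("Lo-CHOL", "Ld-CHOL", "Lod-CHOL")}
        for m in chol:
            rec[a.labels[m]] += 1
        pct = {k: 100 * v / len(chol) for k, v in rec.items()}
        assert abs(pct["Lo-CHOL"] - 60) <= 5
        assert abs(pct["Ld-CHOL"] - 10) <= 5
        assert abs(pct["Lod-CHOL"] - 30) <= 5


class TestOracleEquivalence:
    def test_neighbor_search_equals_brute_force(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            frame = random_lipid_frame(rng, n_lipids=int(rng.integers(10, 60)))
            fast = rb.classify_frame(frame, 0.5)
            slow = rb.classify_frame(frame, 0.5, brute_force=True)
            assert fast.labels == slow.labels


class TestCompositionSummary:
    def test_single_frame_single_replicate_flags_sem(self, small_raft):
        frame, truth = small_raft
        a = rb.classify_frame(frame, 0.5)
        comp = domains.composition_summary([[a]], truth.species)
        assert not comp.sem_defined
        assert comp.n_replicates == 1

    def test_identical_replicates_zero_sem(self, small_raft):
        frame, truth = small_raft
        a = rb.classify_frame(frame, 0.5)
        comp = domains.composition_summary([[a], [a]], truth.species)
        assert comp.sem_defined
        for sp in comp.sem:
            for d in comp.sem[sp]:
                assert comp.sem[sp][d] == 0.0

    def test_per_species_percentages_sum_to_100(self, small_raft):
        frame, truth = small_raft
        a = rb.classify_frame(frame, 0.5)
        comp = domains.composition_summary([[a]], truth.species)
        for sp, by_domain in comp.percentages.items():
            assert sum(by_domain.values()) == pytest.approx(100.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            domains.composition_summary([], {})
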