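"""Generator contracts: composition, leaflets, determinism, planted order."""

import numpy as np
import pytest

import raftbind as rb
from raftbind.synthetic import RAFT_COUNTS, sample_tilt_cos2

from conftest import SMALL_BOX, SMALL_COUNTS


def _species_counts(truth):
    out = {}
    for sp in truth.species.values():
        out[sp] = out.get(sp, 0) + 1
    return out


class TestComposition:
    @pytest.mark.parametrize("kind", ["CO", "GM", "PS"])
    def test_counts_conserved_exactly(self, kind):
        spec = rb.raft_spec(kind, seed=2)
        _, truth = rb.generate_raft(spec)
        assert _species_counts(truth) == dict(RAFT_COUNTS[kind])

    def test_ps_raft_pops_single_leaflet(self):
        _, truth = rb.generate_raft(rb.raft_spec("PS", seed=4))
        pops = [m for m, s in truth.species.items() if s == "POPS"]
        assert len(pops) == 162
        assert all(truth.leaflet[m] == "upper" for m in pops)

    def test_gm_raft_gm1_single_leaflet(self):
        _, truth = rb.generate_raft(rb.raft_spec("GM", seed=4))
        gm1 = [m for m, s in truth.species.items() if s == "GM1"]
        assert len(gm1) == 36
        assert all(truth.leaflet[m] == "upper" for m in gm1)

    def test_zero_chol_spec_contains_no_chol(self):
        spec = rb.RaftSpec(counts={"DPPC": 40, "DLPC": 30, "CHOL": 0},
                           box=(10, 10, 14))
        frame, truth = rb.generate_raft(spec)
        assert not frame.atoms_of_type("CHOL").any()
        assert "CHOL" not in _species_counts(truth)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rb.RaftSpec(counts={"DPPC": -1})

    def test_overcrowded_spec_rejected(self):
        with pytest.raises(ValueError, match="cannot place"):
            rb.generate_raft(rb.RaftSpec(
                counts={"DPPC": 4000, "DLPC": 10, "CHOL": 0}, box=(6, 6, 10)))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = rb.RaftSpec(counts=dict(SMALL_COUNTS), box=SMALL_BOX, seed=9)
        f1, _ = rb.generate_raft(spec)
        f2, _ = rb.generate_raft(spec)
        np.testing.assert_array_equal(f1.coordinates, f2.coordinates)

    def test_distinct_seeds_distinct_jitter(self):
        a, _ = rb.generate_raft(rb.RaftSpec(counts=dict(SMALL_COUNTS),
                                            box=SMALL_BOX, seed=1))
        b, _ = rb.generate_raft(rb.RaftSpec(counts=dict(SMALL_COUNTS),
                                            box=SMALL_BOX, seed=2))
        assert not np.array_equal(a.coordinates, b.coordinates)

    def test_trajectory_deterministic_under_seed(self):
        spec = rb.RaftSpec(counts=dict(SMALL_COUNTS), box=SMALL_BOX, seed=3)
        script = rb.BindingScript(binding_time=2.0, seed=3, n_chains=1)
        t1, _ = rb.generate_trajectory(spec, script, n_frames=10, dt=0.5)
        t2, _ = rb.generate_trajectory(spec, script, n_frames=10, dt=0.5)
        np.testing.assert_array_equal(t1[-1].coordinates, t2[-1].coordinates)


class TestBindingScript:
    def test_mindist_regimes_around_scripted_time(self, binding_traj):
        traj, truth = binding_traj
        k = truth.binding_frame
        lipid = traj[0].atoms_of_type("DPPC", "DLPC", "CHOL")
        prot = traj[0].atoms_of_type("protein")
        from raftbind._geometry import min_cross_distance
        before = min_cross_distance(traj[k - 1].coordinates[prot],
                                    traj[k - 1].coordinates[lipid],
                                    traj[k - 1].box)
        after = min_cross_distance(traj[k].coordinates[prot],
                                   traj[k].coordinates[lipid], traj[k].box)
        assert before > 1.5
        assert after < 0.6

    def test_binding_beyond_end_never_binds(self):
        spec = rb.RaftSpec(counts=dict(SMALL_COUNTS), box=SMALL_BOX, seed=3)
        script = rb.BindingScript(binding_time=100.0, seed=3, n_chains=1)
        traj, truth = rb.generate_trajectory(spec, script, n_frames=10, dt=0.5)
        assert truth.binding_frame is None
        series = rb.mindist_series(traj, ("DPPC", "DLPC", "CHOL"))
        assert not rb.detect_binding_time(series).bound

    def test_bad_frame_parameters_rejected(self):
        spec = rb.RaftSpec(counts=dict(SMALL_COUNTS), box=SMALL_BOX)
        with pytest.raises(ValueError):
            rb.generate_trajectory(spec, rb.BindingScript(), n_frames=1, dt=0.5)
        with pytest.raises(ValueError):
            rb.generate_trajectory(spec, rb.BindingScript(), n_frames=10, dt=0)


class TestChainEnsemble:
    def test_perfect_alignment(self):
        chains = rb.generate_chain_ensemble(1.0, 20, chain_length=8, seed=1)
        _, s, _ = rb.order_from_chains(chains)
        np.testing.assert_allclose(s, 1.0)

    def test_magic_angle_gives_zero(self):
        chains = rb.generate_chain_ensemble(0.0, 20, chain_length=8, seed=1)
        _, s, _ = rb.order_from_chains(chains)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_intermediate_target_within_three_sem(self):
        chains = rb.generate_chain_ensemble(0.4, 5000, chain_length=9, seed=7)
        _, s, sem = rb.order_from_chains(chains)
        assert np.all(np.abs(s - 0.4) <= 3 * sem)

    def test_negative_target(self):
        chains = rb.generate_chain_ensemble(-0.5, 50, chain_length=8, seed=2)
        _, s, _ = rb.order_from_chains(chains)
        np.testing.assert_allclose(s, -0.5, atol=1e-12)

    def test_infeasible_target_rejected(self):
        rng = np.random.default_rng(0)
        for bad in (1.2, -0.6):
            with pytest.raises(ValueError):
                sample_tilt_cos2(bad, 10, rng)

    def test_per_carbon_targets(self):
        targets = [1.0, 0.0, 1.0, 0.0, 1.0]
        chains = rb.generate_chain_ensemble(targets, 30, chain_length=7, seed=3)
        _, s, _ = rb.order_from_chains(chains)
        np.testing.assert_allclose(s, targets, atol=1e-12)


class TestGroundTruthSidecar:
    def test_tsv_round_trip(self, small_raft, tmp_path):
        _, truth = small_raft
        path = tmp_path / "truth.tsv"
        from raftbind.synthetic import read_ground_truth, write_ground_truth
        write_ground_truth(truth, path)
        back = read_ground_truth(path)
        assert back.domain_label == truth.domain_label
        assert back.leaflet == truth.leaflet
        assert back.species == truth.species
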