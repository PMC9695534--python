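"""Mindist series, binding-time detection, residue spectra and dips."""

import numpy as np
import pytest

import raftbind as rb
from raftbind import kinetics
from raftbind.kinetics import MindistSeries

from conftest import make_frame


def _series(times, dists, contacts=None):
    contacts = np.zeros(len(times), int) if contacts is None else contacts
    return MindistSeries(np.asarray(times, float), np.asarray(dists, float),
                         contacts)


class TestMindistSeries:
    def test_coincident_atoms_give_zero(self):
        coords = [[1, 1, 1], [1, 1, 1], [4, 4, 4]]
        frame = make_frame(coords, np.array([0, 1, 1]),
                           ["DPPC", "protein", "protein"],
                           names=np.array(["PO4", "BB", "BB"], dtype=object),
                           resids=np.array([1, 1, 2]), time=0.0)
        frame2 = frame.select(np.ones(3, bool))
        frame2.time = 1.0
        traj = rb.Trajectory([frame, frame2])
        series = kinetics.mindist_series(traj, "DPPC")
        assert series.mindist[0] == pytest.approx(0.0, abs=1e-12)

    def test_scripted_crossing_at_binding_frame(self, binding_traj):
        traj, truth = binding_traj
        series = kinetics.mindist_series(traj, ("DPPC", "DLPC", "CHOL"))
        k = truth.binding_frame
        assert np.all(series.mindist[:k] > 0.6)
        assert np.all(series.mindist[k:] < 0.6)

    def test_brute_force_oracle_equivalence(self, binding_traj):
        traj, _ = binding_traj
        sub = rb.Trajectory(traj.frames[::20])
        fast = kinetics.mindist_series(sub, "DPPC")
        slow = kinetics.mindist_series(sub, "DPPC", brute_force=True)
        np.testing.assert_allclose(fast.mindist, slow.mindist, atol=1e-9)
        np.testing.assert_array_equal(fast.contacts, slow.contacts)

    def test_contact_count_monotone_in_threshold(self, binding_traj):
        traj, _ = binding_traj
        sub = rb.Trajectory(traj.frames[-3:])
        wide = kinetics.mindist_series(sub, "DPPC", contact_threshold=2.0)
        narrow = kinetics.mindist_series(sub, "DPPC", contact_threshold=1.0)
        assert np.all(narrow.contacts <= wide.contacts)

    def test_empty_group_rejected(self, binding_traj):
        traj, _ = binding_traj
        with pytest.raises(ValueError, match="no atoms"):
            kinetics.mindist_series(traj, "GM1")


class TestDetector:
    def test_constant_large_distance_unbound(self):
        ev = kinetics.detect_binding_time(_series(range(10), [5.0] * 10))
        assert not ev.bound and ev.time is None

    def test_step_series_binds_at_the_step(self):
        d = [5, 5, 5, 0.4, 0.4, 0.4, 0.4]
        ev = kinetics.detect_binding_time(_series(range(7), d),
                                          t_persist=2.0)
        assert ev.bound and ev.time == 3.0

    def test_transient_dip_rejected_by_persistence(self):
        d = [5, 0.4, 5, 5, 0.4, 0.4, 0.4, 0.4]
        ev = kinetics.detect_binding_time(_series(range(8), d), t_persist=2.0)
        assert ev.time == 4.0

    def test_persistence_past_series_end_flagged(self):
        d = [5, 5, 0.4]
        ev = kinetics.detect_binding_time(_series(range(3), d), t_persist=10.0)
        assert ev.bound and ev.truncated

    def test_offset_invariance_under_prepended_unbound_frames(self):
        d = [5, 5, 0.4, 0.4, 0.4, 0.4]
        base = kinetics.detect_binding_time(_series(range(6), d), t_persist=2.0)
        padded = kinetics.detect_binding_time(
            _series(range(9), [5, 5, 5] + d), t_persist=2.0)
        assert padded.time == base.time + 3.0

    def test_planted_recovery_over_seeded_scripts(self):
        """Detector lands within one frame of the scripted binding time."""
        hits = 0
        n_scripts = 20
        for seed in range(n_scripts):
            spec = rb.RaftSpec(counts={"DPPC": 60, "DLPC": 40, "CHOL": 20},
                               box=(10.0, 10.0, 20.0), seed=seed)
            script = rb.BindingScript(
                binding_time=float(1.0 + (seed % 7)), seed=seed, n_chains=1)
            traj, truth = rb.generate_trajectory(spec, script,
                                                 n_frames=40, dt=0.3)
            series = kinetics.mindist_series(traj, ("DPPC", "DLPC", "CHOL"))
            ev = kinetics.detect_binding_time(series)
            if ev.bound and abs(ev.time - truth.binding_time) <= 0.3:
                hits += 1
        assert hits >= 19


class TestResidueSpectrum:
    def test_static_frames_equal_single_frame_distances(self, binding_traj):
        traj, _ = binding_traj
        last = traj[-1]
        frames = []
        for i in range(3):
            f = last.select(np.ones(last.n_atoms, bool))
            f.time = float(i)
            frames.append(f)
        static = rb.Trajectory(frames)
        spec3 = kinetics.residue_spectrum(static, "DPPC", window=10.0)
        spec1 = kinetics.residue_spectrum(rb.Trajectory(frames[:1]), "DPPC",
                                          window=10.0)
        np.testing.assert_allclose(spec3.values, spec1.values)

    def test_length_is_chains_times_chain_length(self, binding_traj):
        traj, _ = binding_traj
        spec = kinetics.residue_spectrum(traj, "DPPC", window=2.0)
        assert len(spec) == 2 * 130
        assert spec.chain_bounds == (1, 131)

    def test_mindist_bounds_every_residue_distance(self, binding_traj):
        traj, _ = binding_traj
        sub = rb.Trajectory(traj.frames[-2:])
        series = kinetics.mindist_series(sub, "DPPC")
        spec = kinetics.residue_spectrum(sub, "DPPC", window=0.2)
        assert series.mindist.min() <= spec.values.min() + 1e-9

    def test_block_structure_matches_single_chain(self):
        spec = rb.RaftSpec(counts={"DPPC": 40, "DLPC": 30, "CHOL": 10},
                           box=(10, 10, 20), seed=8)
        tet_script = rb.BindingScript(binding_time=0.5, seed=8, n_chains=2,
                                      chain_length=20)
        traj, _ = rb.generate_trajectory(spec, tet_script, n_frames=6, dt=0.5)
        full = kinetics.residue_spectrum(traj, "DPPC", window=1.0,
                                         chain_length=20)
        assert len(full) == 40
        # restrict the trajectory to chain A only
        frames = []
        for f in traj:
            keep = (f.chain_id != "B")
            frames.append(f.select(keep))
        mono = kinetics.residue_spectrum(rb.Trajectory(frames), "DPPC",
                                         window=1.0, chain_length=20)
        np.testing.assert_allclose(full.values[:20], mono.values)


class TestDifferenceAndDips:
    def test_self_difference_is_zero(self, binding_traj):
        traj, _ = binding_traj
        spec = kinetics.residue_spectrum(traj, "DPPC", window=2.0)
        np.testing.assert_array_equal(kinetics.difference_spectrum(spec, spec),
                                      np.zeros(len(spec)))

    def test_length_mismatch_rejected(self):
        a = kinetics.ResidueSpectrum(np.zeros(5), (1,), (0, 1))
        b = kinetics.ResidueSpectrum(np.zeros(6), (1,), (0, 1))
        with pytest.raises(ValueError):
            kinetics.difference_spectrum(a, b)

    def test_single_local_minimum_found(self):
        x = np.array([2.0, 1.5, 0.5, 1.5, 2.0])
        assert list(kinetics.find_dips(x, threshold=1.0)) == [3]

    def test_dips_above_threshold_ignored(self):
        x = np.array([2.0, 1.5, 1.2, 1.5, 2.0])
        assert len(kinetics.find_dips(x, threshold=1.0)) == 0

    def test_planted_gap_shows_in_difference(self):
        rng = np.random.default_rng(4)
        base = 1.5 + rng.uniform(0, 0.05, 130)
        wt = base.copy()
        wt[65] = 0.5  # strong binding at local residue 66
        mbd = base.copy()
        diff = wt - mbd
        dips = kinetics.find_dips(diff, threshold=-0.3)
        assert 66 in dips
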