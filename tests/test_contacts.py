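"""Contact search correctness: oracle equivalence, cutoff semantics, windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_contacts, make_two_particle_system
from membmode.contacts import ContactConfig, contact_profile, frame_contacts, landing_frame
from membmode.errors import ConfigurationError, UsageError
from membmode.structio import Particle, Structure, Trajectory


def random_system(rng, n_protein, n_lipid, box=None, spread=2.0):
    particles = []
    for i in range(n_protein):
        particles.append(
            Particle(i, "CA", i + 1, "ALA", "protein", rng.uniform(0, spread, 3))
        )
    for j in range(n_lipid):
        particles.append(
            Particle(n_protein + j, "P", n_protein + j + 1, "POPC", "lipid",
                     rng.uniform(0, spread, 3))
        )
    return Structure(particles, box)


class TestFrameContacts:
    def test_strictly_below_cutoff_counts(self):
        s = make_two_particle_system([0, 0, 0.599])
        assert len(frame_contacts(s.positions, s)) == 1

    def test_exactly_at_cutoff_excluded(self):
        s = make_two_particle_system([0, 0, 0.600])
        assert len(frame_contacts(s.positions, s)) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            s = random_system(rng, 50, 200)
            frame = s.positions
            got = frame_contacts(frame, s)
            expected = brute_force_contacts(frame, s, 0.6)
            assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in expected]
            assert np.allclose([d for *_, d in got], [d for *_, d in expected])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), cutoff=st.floats(0.1, 1.5))
    def test_oracle_property_random_systems(self, seed, cutoff):
        rng = np.random.default_rng(seed)
        s = random_system(rng, rng.integers(1, 30), rng.integers(1, 60))
        cfg = ContactConfig(cutoff_nm=cutoff)
        got = [(a, b) for a, b, _ in frame_contacts(s.positions, s, cfg)]
        expected = [(a, b) for a, b, _ in brute_force_contacts(s.positions, s, cutoff)]
        assert got == expected

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        s = random_system(rng, 30, 80)
        frame = s.positions
        n0 = len(frame_contacts(frame, s))
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=5).as_matrix()
        moved = frame @ R.T + np.array([3.0, -1.0, 2.0])
        assert len(frame_contacts(moved, s)) == n0

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(9)
        s = random_system(rng, 20, 50)
        frame = s.positions
        small = {(a, b) for a, b, _ in frame_contacts(frame, s, ContactConfig(cutoff_nm=0.4))}
        large = {(a, b) for a, b, _ in frame_contacts(frame, s, ContactConfig(cutoff_nm=0.8))}
        assert small <= large

    def test_periodic_minimum_image(self):
        box = np.array([3.0, 3.0, 3.0])
        s = make_two_particle_system([2.9, 0.0, 0.0], box=box)
        frame = s.positions
        assert len(frame_contacts(frame, s, ContactConfig(periodic=False))) == 0
        pairs = frame_contacts(frame, s, ContactConfig(periodic=True))
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(0.1, abs=1e-12)

    def test_periodic_matches_brute_force(self):
        box = np.array([2.0, 2.0, 2.0])
        rng = np.random.default_rng(21)
        s = random_system(rng, 20, 60, box=box, spread=2.0)
        frame = s.positions
        got = [(a, b) for a, b, _ in frame_contacts(frame, s, ContactConfig(periodic=True))]
        exp = [(a, b) for a, b, _ in brute_force_contacts(frame, s, 0.6, periodic=True)]
        assert got == exp

    def test_periodic_without_box_is_configuration_error(self):
        s = make_two_particle_system([0, 0, 0.1])
        with pytest.raises(ConfigurationError):
            frame_contacts(s.positions, s, ContactConfig(periodic=True))

    def test_hydrogens_excluded_when_heavy_only(self):
        particles = [
            Particle(0, "CA", 1, "ALA", "protein", np.zeros(3)),
            Particle(1, "HA", 1, "ALA", "protein", np.array([0.0, 0.0, 0.05])),
            Particle(2, "P", 2, "POPC", "lipid", np.array([0.0, 0.0, 0.3])),
            Particle(3, "H1", 2, "POPC", "lipid", np.array([0.0, 0.0, 0.25])),
        ]
        s = Structure(particles)
        heavy = frame_contacts(s.positions, s, ContactConfig(heavy_only=True))
        allp = frame_contacts(s.positions, s, ContactConfig(heavy_only=False))
        assert {(a, b) for a, b, _ in heavy} == {(0, 2)}
        assert len(allp) == 4


class TestContactProfile:
    def make_blinking_trajectory(self, touching_frames, n_frames=10):
        s = make_two_particle_system([0, 0, 0.3])
        frames = []
        for k in range(n_frames):
            f = s.positions
            if k not in touching_frames:
                f[1, 2] = 5.0  # move the lipid far away
            frames.append(f)
        return Trajectory(s, frames)

    def test_fraction_counting(self):
        traj = self.make_blinking_trajectory(set(range(7)))
        profile = contact_profile(traj)
        assert profile.residue_contact_fraction[1] == pytest.approx(0.7)
        assert profile.stable_residues == {1}
        assert profile.per_frame_counts == [1] * 7 + [0] * 3

    def test_zero_contact_trajectory(self):
        traj = self.make_blinking_trajectory(set())
        profile = contact_profile(traj)
        assert profile.stable_residues == set()
        assert all(f == 0.0 for f in profile.residue_contact_fraction.values())

    def test_residue_counted_once_per_frame(self):
        # two beads of the same residue both touching must count as one residue
        particles = [
            Particle(0, "CA", 1, "ALA", "protein", np.zeros(3)),
            Particle(1, "CB", 1, "ALA", "protein", np.array([0.0, 0.0, 0.05])),
            Particle(2, "P", 2, "POPC", "lipid", np.array([0.0, 0.0, 0.3])),
        ]
        s = Structure(particles)
        traj = Trajectory(s, [s.positions])
        profile = contact_profile(traj)
        assert profile.residue_contact_fraction[1] == 1.0
        assert profile.per_frame_counts == [2]  # but the pair count sees both

    def test_empty_frame_range_rejected(self):
        traj = self.make_blinking_trajectory({0})
        with pytest.raises(UsageError):
            contact_profile(traj, frame_range=(5, 5))


class TestLandingFrame:
    def test_first_persistent_contact_frame(self):
        traj = TestContactProfile().make_blinking_trajectory(set(range(13, 20)), n_frames=20)
        assert landing_frame(traj, persistence=5) == 13

    def test_never_landing_returns_none(self):
        traj = TestContactProfile().make_blinking_trajectory(set(), n_frames=8)
        assert landing_frame(traj, persistence=2) is None

    def test_transient_touch_ignored(self):
        traj = TestContactProfile().make_blinking_trajectory({2} | set(range(10, 20)), n_frames=20)
        assert landing_frame(traj, persistence=5) == 10

    def test_synthetic_landing_window(self, mode1_traj):
        assert 18 <= landing_frame(mode1_traj, persistence=5) <= 22
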