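"""Fingerprints, similarity, mode clustering, region geometry, mobility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from membmode.contacts import ContactConfig, ContactProfile, contact_profile
from membmode.errors import UsageError
from membmode.modes import (
    ModeFingerprint,
    cluster_orientations,
    fingerprint,
    mobility,
    region_overlap,
    similarity,
)
from membmode.structio import Particle, Structure, Trajectory
from membmode.synthetic_data import (
    DEFAULT_MODE_RESIDUES,
    default_mode_spec,
    simulate_binding_trajectory,
)


def fp_from_support(support, n_residues=20, **kwargs):
    residues = np.arange(1, n_residues + 1)
    fractions = np.array([1.0 if r in support else 0.0 for r in residues])
    return ModeFingerprint(residues=residues, fractions=fractions, **kwargs)


class TestFingerprint:
    def test_zero_profile_gives_zero_vector(self):
        profile = ContactProfile(
            per_frame_counts=[0, 0],
            residue_contact_fraction={1: 0.0, 2: 0.0},
            stable_residues=set(),
            n_frames=2,
        )
        fp = fingerprint(profile)
        assert np.all(fp.fractions == 0.0)
        assert fp.support == frozenset()

    def test_planted_support_recovered(self, mode1_traj):
        land = mode1_traj.metadata["landing_frame"]
        profile = contact_profile(mode1_traj, ContactConfig(), frame_range=(land, None))
        fp = fingerprint(profile)
        assert fp.support == DEFAULT_MODE_RESIDUES[1]

    def test_same_spec_different_seeds_highly_similar(self, toy_protein, bilayer):
        spec = default_mode_spec(2)
        fps = []
        for seed in (1, 2):
            traj = simulate_binding_trajectory(toy_protein, bilayer, spec, 60, seed=seed)
            land = traj.metadata["landing_frame"]
            profile = contact_profile(traj, ContactConfig(), frame_range=(land, None))
            fps.append(fingerprint(profile))
        assert similarity(fps[0], fps[1], metric="cosine") >= 0.9


class TestSimilarity:
    def test_identical_is_one(self):
        a = fp_from_support({1, 2, 3})
        assert similarity(a, a, "jaccard") == 1.0
        assert similarity(a, a, "cosine") == pytest.approx(1.0)

    def test_disjoint_supports_are_zero_jaccard(self):
        a = fp_from_support({1, 2})
        b = fp_from_support({5, 6})
        assert similarity(a, b, "jaccard") == 0.0

    def test_partial_overlap_set_arithmetic(self):
        a = fp_from_support(set(range(1, 11)))
        b = fp_from_support(set(range(6, 16)))
        assert similarity(a, b, "jaccard") == pytest.approx(5 / 15)

    def test_zero_vector_cosine_is_zero_with_warning(self):
        a = fp_from_support(set())
        b = fp_from_support({1})
        with pytest.warns(UserWarning):
            assert similarity(a, b, "cosine") == 0.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 9999), metric=st.sampled_from(["jaccard", "cosine"]))
    def test_symmetric_and_bounded(self, seed, metric):
        rng = np.random.default_rng(seed)
        residues = np.arange(1, 16)
        a = ModeFingerprint(residues, rng.uniform(0, 1, 15))
        b = ModeFingerprint(residues, rng.uniform(0, 1, 15))
        s_ab = similarity(a, b, metric)
        assert s_ab == similarity(b, a, metric)
        assert 0.0 <= s_ab <= 1.0
        if np.linalg.norm(a.fractions) > 0:
            assert similarity(a, a, metric) == pytest.approx(1.0)


class TestClusterOrientations:
    def test_single_fingerprint_single_mode(self):
        a = cluster_orientations([fp_from_support({1, 2})])
        assert a.n_modes == 1
        assert list(a.labels.values()) == [1]

    def test_identical_fingerprints_merge_to_one(self):
        fps = [fp_from_support({1, 2, 3}, intensity=5.0) for _ in range(6)]
        assert cluster_orientations(fps).n_modes == 1

    def test_threshold_zero_single_mode(self):
        fps = [fp_from_support({1}), fp_from_support({9})]
        assert cluster_orientations(fps, threshold=0.0).n_modes == 1

    def test_threshold_above_one_splits_everything(self):
        fps = [fp_from_support({1, 2}, intensity=float(i)) for i in range(4)]
        assert cluster_orientations(fps, threshold=1.5).n_modes == 4

    def test_six_start_partition_and_mode_numbering(self):
        # planted start->mode mapping: 1->1, {2,4,5,6}->2, 3->3, with
        # intensity ordering mode1 > mode2 > mode3
        sets = {1: frozenset(range(1, 18)), 2: frozenset(range(20, 30)),
                3: frozenset(range(32, 38))}
        fps = [
            fp_from_support(sets[m], n_residues=40, intensity=float(50 - 10 * m),
                            trajectory_id=start)
            for start, m in [(1, 1), (2, 2), (3, 3), (4, 2), (5, 2), (6, 2)]
        ]
        a = cluster_orientations(fps)
        assert a.n_modes == 3
        assert a.labels == {1: 1, 2: 2, 3: 3, 4: 2, 5: 2, 6: 2}
        assert a.mode_members == {1: [1], 2: [2, 4, 5, 6], 3: [3]}

    def test_mode_order_tie_broken_by_lower_altitude(self):
        a = fp_from_support({1, 2}, intensity=5.0, mean_altitude=2.9, trajectory_id="hi")
        b = fp_from_support({8, 9}, intensity=5.0, mean_altitude=1.7, trajectory_id="lo")
        out = cluster_orientations([a, b])
        assert out.labels == {"lo": 1, "hi": 2}


class TestRegionOverlap:
    def test_shared_residue_is_overlapping(self, toy_protein):
        assert region_overlap({1, 2}, {2, 3}, toy_protein) == "overlapping"

    def test_default_mode_adjacency(self, toy_protein):
        m = DEFAULT_MODE_RESIDUES
        assert region_overlap(m[1], m[2], toy_protein) != "disjoint"
        assert region_overlap(m[2], m[3], toy_protein) != "disjoint"
        assert region_overlap(m[1], m[3], toy_protein) == "disjoint"

    def test_neighboring_by_distance(self):
        particles = [
            Particle(0, "CA", 1, "ALA", "protein", [0.0, 0.0, 0.0]),
            Particle(1, "CA", 2, "ALA", "protein", [0.5, 0.0, 0.0]),
            Particle(2, "CA", 3, "ALA", "protein", [5.0, 0.0, 0.0]),
        ]
        s = Structure(particles)
        assert region_overlap({1}, {2}, s) == "neighboring"
        assert region_overlap({1}, {3}, s) == "disjoint"

    def test_unknown_residue_rejected(self, small_protein):
        with pytest.raises(UsageError):
            region_overlap({1}, {999}, small_protein)


class TestMobility:
    def make_jitter_trajectory(self, n_frames, sd, seed=0, per_residue=None, rigid_motion=False):
        rng = np.random.default_rng(seed)
        base = make_grid_protein()
        n = base.n_particles
        sds = np.full(n, sd)
        if per_residue:
            for r, v in per_residue.items():
                sds[r - 1] = v
        frames = []
        for k in range(n_frames):
            f = base.positions + rng.normal(0, 1, (n, 3)) * sds[:, None]
            if rigid_motion:
                from scipy.spatial.transform import Rotation

                R = Rotation.from_euler("z", 10 * k, degrees=True).as_matrix()
                f = f @ R.T + np.array([0.1 * k, 0.0, 0.0])
            frames.append(f)
        return Trajectory(base, frames)

    def test_static_trajectory_zero_rmsf(self):
        traj = self.make_jitter_trajectory(5, 0.0)
        assert np.all(mobility(traj).rmsf_nm < 1e-12)

    def test_isotropic_jitter_closed_form(self):
        sigma = 0.05
        traj = self.make_jitter_trajectory(1000, sigma, seed=12)
        rmsf = mobility(traj).rmsf_nm
        assert np.allclose(rmsf.mean(), sigma * np.sqrt(3), rtol=0.05)

    def test_invariant_under_global_rigid_motion(self):
        a = mobility(self.make_jitter_trajectory(200, 0.05, seed=4))
        b = mobility(self.make_jitter_trajectory(200, 0.05, seed=4, rigid_motion=True))
        assert np.allclose(a.rmsf_nm, b.rmsf_nm, atol=2e-3)

    def test_planted_flexible_region_found(self, toy_protein, bilayer):
        flexible = {r: 0.25 for r in range(105, 116)}
        spec = default_mode_spec(1, mobility_sd_nm={**flexible})
        traj = simulate_binding_trajectory(toy_protein, bilayer, spec, 150, seed=6)
        land = traj.metadata["landing_frame"]
        prof = mobility(traj, frame_range=(land, None))
        assert 105 <= prof.residues[np.argmax(prof.rmsf_nm)] <= 115

    def test_single_frame_rejected(self):
        traj = self.make_jitter_trajectory(2, 0.0)
        with pytest.raises(UsageError):
            mobility(traj, frame_range=(0, 1))


def make_grid_protein(n_side=3, spacing=0.5):
    particles = []
    idx = 0
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                particles.append(
                    Particle(idx, "CA", idx + 1, "ALA", "protein",
                             np.array([i, j, k], dtype=float) * spacing)
                )
                idx += 1
    return Structure(particles)
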