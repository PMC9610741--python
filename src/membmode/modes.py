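"""Binding-mode classification from contact fingerprints, mode-region
geometry, and per-residue mobility.

Independent trajectories are summarised as fingerprints (per-residue
contact fractions over the post-landing window) and merged by
single-linkage agglomeration whenever their similarity reaches a
threshold.  Modes are numbered by descending contact intensity: mode 1 is
the orientation with the most protein–lipid contacts (the deepest-bound
state), ties broken by lower mean altitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .backmap import kabsch_fit
from .contacts import ContactProfile, _resolve_range
from .errors import UsageError
from .structio import Structure, Trajectory


@dataclass
class ModeFingerprint:
    """Per-residue contact fractions of one trajectory's bound state."""

    residues: np.ndarray
    fractions: np.ndarray
    stable_threshold: float = 0.5
    intensity: float = float("nan")  # mean contacts per frame
    mean_altitude: float = float("nan")
    trajectory_id: int | str | None = None

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int).reshape(-1)
        self.fractions = np.asarray(self.fractions, dtype=float).reshape(-1)
        if self.residues.shape != self.fractions.shape:
            raise UsageError("residues and fractions must have equal length")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise UsageError("contact fractions must lie in [0, 1]")

    @property
    def support(self) -> frozenset[int]:
        """Residues at or above the stable-contact threshold."""
        return frozenset(
            int(r) for r, f in zip(self.residues, self.fractions)
            if f >= self.stable_threshold
        )


@dataclass
class ModeAssignment:
    """Partition of trajectories into modes."""

    labels: dict
    n_modes: int
    similarity: np.ndarray
    trajectory_ids: list
    mode_members: dict[int, list] = field(default_factory=dict)
    mode_stable_residues: dict[int, frozenset[int]] = field(default_factory=dict)
    mode_intensity: dict[int, float] = field(default_factory=dict)
    mode_altitude: dict[int, float] = field(default_factory=dict)


@dataclass
class MobilityProfile:
    """Per-residue RMSF (nm) about the mean conformation after superposition."""

    residues: np.ndarray
    rmsf_nm: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int).reshape(-1)
        self.rmsf_nm = np.asarray(self.rmsf_nm, dtype=float).reshape(-1)
        if np.any(self.rmsf_nm < 0):
            raise UsageError("RMSF values must be >= 0")


def fingerprint(
    profile: ContactProfile,
    intensity: float | None = None,
    mean_altitude: float = float("nan"),
    trajectory_id=None,
) -> ModeFingerprint:
    """Contact-fraction vector of a profile (residues sorted ascending)."""
    residues = np.array(sorted(profile.residue_contact_fraction), dtype=int)
    fractions = np.array([profile.residue_contact_fraction[r] for r in residues])
    return ModeFingerprint(
        residues=residues,
        fractions=fractions,
        stable_threshold=profile.stable_fraction,
        intensity=profile.mean_contacts_per_frame if intensity is None else intensity,
        mean_altitude=mean_altitude,
        trajectory_id=trajectory_id,
    )


def similarity(a: ModeFingerprint, b: ModeFingerprint, metric: str = "jaccard") -> float:
    """Fingerprint similarity in [0, 1].

    ``"jaccard"`` compares the stable supports; ``"cosine"`` the raw
    fraction vectors.  Identical inputs give 1, disjoint supports 0; the
    cosine of a zero vector is defined as 0 (with a warning).
    """
    if not np.array_equal(a.residues, b.residues):
        raise UsageError("fingerprints cover different residue ranges")
    if metric == "jaccard":
        sa, sb = a.support, b.support
        if not sa and not sb:
            return 1.0
        union = len(sa | sb)
        return len(sa & sb) / union if union else 0.0
    if metric == "cosine":
        na = float(np.linalg.norm(a.fractions))
        nb = float(np.linalg.norm(b.fractions))
        if na == 0.0 or nb == 0.0:
            warnings.warn("cosine similarity of a zero fingerprint is defined as 0")
            return 0.0
        return float(np.clip(np.dot(a.fractions, b.fractions) / (na * nb), 0.0, 1.0))
    raise UsageError(f"unknown metric {metric!r} (expected 'jaccard' or 'cosine')")


def cluster_orientations(
    fingerprints: Sequence[ModeFingerprint],
    threshold: float = 0.5,
    metric: str = "jaccard",
) -> ModeAssignment:
    """Single-linkage merge of fingerprints with similarity >= threshold.

    Mode labels are assigned 1..n_modes by descending mean contact
    intensity (ties: lower mean altitude, then first trajectory order).
    """
    if len(fingerprints) == 0:
        raise UsageError("need at least one fingerprint")
    ids = [
        fp.trajectory_id if fp.trajectory_id is not None else i
        for i, fp in enumerate(fingerprints)
    ]
    n = len(fingerprints)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = similarity(fingerprints[i], fingerprints[j], metric)

    if n == 1:
        raw = np.array([1])
    elif threshold > 1.0:
        raw = np.arange(1, n + 1)  # nothing can merge
    else:
        dist = np.clip(1.0 - sim, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="single")
        raw = fcluster(Z, t=1.0 - threshold, criterion="distance")

    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)

    def finite_mean(values, default):
        finite = [v for v in values if np.isfinite(v)]
        return float(np.mean(finite)) if finite else default

    def sort_key(members: list[int]):
        mean_int = finite_mean([fingerprints[i].intensity for i in members], -np.inf)
        mean_alt = finite_mean([fingerprints[i].mean_altitude for i in members], np.inf)
        return (-mean_int, mean_alt, min(members))

    ordered = sorted(clusters.values(), key=sort_key)
    labels: dict = {}
    mode_members: dict[int, list] = {}
    mode_stable: dict[int, frozenset[int]] = {}
    mode_int: dict[int, float] = {}
    mode_alt: dict[int, float] = {}
    for mode, members in enumerate(ordered, start=1):
        mode_members[mode] = [ids[i] for i in members]
        supports = [fingerprints[i].support for i in members]
        mode_stable[mode] = frozenset.intersection(*supports) if supports else frozenset()
        mode_int[mode] = finite_mean(
            [fingerprints[i].intensity for i in members], float("nan")
        )
        mode_alt[mode] = finite_mean(
            [fingerprints[i].mean_altitude for i in members], float("nan")
        )
        for i in members:
            labels[ids[i]] = mode
    return ModeAssignment(
        labels=labels,
        n_modes=len(ordered),
        similarity=sim,
        trajectory_ids=ids,
        mode_members=mode_members,
        mode_stable_residues=mode_stable,
        mode_intensity=mode_int,
        mode_altitude=mode_alt,
    )


def region_overlap(
    mode_a_residues: set[int],
    mode_b_residues: set[int],
    structure: Structure,
    neighbor_cutoff_nm: float = 0.8,
) -> str:
    """Classify two mode contact regions as "overlapping" (shared residues),
    "neighboring" (any cross-pair of residue centres within the cutoff), or
    "disjoint"."""
    a = {int(r) for r in mode_a_residues}
    b = {int(r) for r in mode_b_residues}
    known = set(structure.protein_residues())
    unknown = (a | b) - known
    if unknown:
        raise UsageError(f"residues {sorted(unknown)} not in structure")
    if a & b:
        return "overlapping"
    centers: dict[int, list[np.ndarray]] = {}
    for p in structure.particles:
        if p.segment == "protein" and p.residue_index in (a | b):
            centers.setdefault(p.residue_index, []).append(p.position)
    pos_a = np.array([np.mean(centers[r], axis=0) for r in sorted(a)])
    pos_b = np.array([np.mean(centers[r], axis=0) for r in sorted(b)])
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    return "neighboring" if np.any(d < neighbor_cutoff_nm) else "disjoint"


def mobility(
    traj: Trajectory,
    frame_range: tuple[int | None, int | None] | None = None,
    n_iterations: int = 3,
) -> MobilityProfile:
    """Per-residue RMSF of the protein after optimal rigid superposition.

    Every frame is superposed (Kabsch) onto the running mean conformation;
    the mean is refined for a few iterations, then the fluctuation about it
    is averaged over the particles of each residue.
    """
    start, stop = _resolve_range(traj.n_frames, frame_range)
    if stop - start < 2:
        raise UsageError("mobility requires at least two frames")
    prot = traj.topology.segment_indices("protein")
    if len(prot) == 0:
        raise UsageError("no protein particles in topology")
    coords = np.stack([traj.frames[k][prot] for k in range(start, stop)])

    reference = coords[0]
    aligned = coords.copy()
    for _ in range(n_iterations):
        for f in range(aligned.shape[0]):
            fit = kabsch_fit(coords[f], reference)
            aligned[f] = fit.apply(coords[f])
        new_ref = aligned.mean(axis=0)
        if np.allclose(new_ref, reference, atol=1e-12):
            break
        reference = new_ref

    fluct = aligned - reference  # (F, N, 3)
    per_particle = np.sqrt(np.mean(np.sum(fluct**2, axis=2), axis=0))
    res_of = traj.topology.residue_indices()[prot]
    residues = np.array(sorted(set(int(r) for r in res_of)))
    rmsf = np.array([float(np.mean(per_particle[res_of == r])) for r in residues])
    return MobilityProfile(residues=residues, rmsf_nm=rmsf)
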