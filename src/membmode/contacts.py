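"""Protein–lipid contact analysis along a trajectory.

A contact is a protein–lipid particle pair at centre–centre distance
strictly below the cutoff (default 0.6 nm).  Solvent particles are never
contact partners; hydrogens can be excluded so that atomistic systems count
heavy-atom contacts only.  The per-residue contact fraction over the frames
is the "contact map" statistic; residues above a threshold fraction are the
stable-contact set, and the per-frame pair count is the contact intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, SelectionError, UsageError
from .structio import Structure, Trajectory


@dataclass
class ContactConfig:
    """Parameters of the contact search.

    cutoff_nm
        Pair distance threshold (strict ``<``), nm.
    periodic
        Use minimum-image distances in the topology box (orthorhombic).
    stable_fraction
        Fraction of frames above which a residue counts as a stable contact.
    heavy_only
        Ignore particles whose name starts with "H" (hydrogens).
    """

    cutoff_nm: float = 0.6
    periodic: bool = False
    stable_fraction: float = 0.5
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff_nm > 0:
            raise UsageError(f"cutoff_nm must be > 0, got {self.cutoff_nm}")
        if not 0 < self.stable_fraction <= 1:
            raise UsageError(
                f"stable_fraction must be in (0, 1], got {self.stable_fraction}"
            )


@dataclass
class ContactProfile:
    """Aggregated contact statistics over (a window of) a trajectory."""

    per_frame_counts: list[int]
    residue_contact_fraction: dict[int, float]
    stable_residues: set[int]
    n_frames: int
    stable_fraction: float = 0.5
    frame_range: tuple[int, int] | None = None

    @property
    def mean_contacts_per_frame(self) -> float:
        return float(np.mean(self.per_frame_counts))


def _partner_indices(topology: Structure, config: ContactConfig):
    def heavy(name: str) -> bool:
        return not name.upper().startswith("H")

    prot = np.array(
        [p.index for p in topology.particles
         if p.segment == "protein" and (not config.heavy_only or heavy(p.name))],
        dtype=int,
    )
    lip = np.array(
        [p.index for p in topology.particles
         if p.segment == "lipid" and (not config.heavy_only or heavy(p.name))],
        dtype=int,
    )
    return prot, lip


def frame_contacts(
    frame: np.ndarray,
    topology: Structure,
    config: ContactConfig = ContactConfig(),
) -> list[tuple[int, int, float]]:
    """All protein–lipid pairs with distance strictly below the cutoff.

    Returns ``(protein_particle_index, lipid_particle_index, distance_nm)``
    tuples.  Uses a k-d tree for the neighbour search; results are identical
    to the all-pairs computation (the tree only prunes, distances are
    recomputed and filtered with a strict inequality).
    """
    frame = np.asarray(frame, dtype=float)
    prot_idx, lip_idx = _partner_indices(topology, config)
    if len(prot_idx) == 0 or len(lip_idx) == 0:
        raise SelectionError("topology must contain protein and lipid particles")
    box = topology.box
    if config.periodic and box is None:
        raise ConfigurationError("periodic contact search requested but topology has no box")

    prot = frame[prot_idx]
    lip = frame[lip_idx]
    pairs: list[tuple[int, int, float]] = []
    if config.periodic:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(lip, box), boxsize=box)
        hits = tree.query_ball_point(np.mod(prot, box), r=config.cutoff_nm)
        for a, neighbours in enumerate(hits):
            for b in neighbours:
                d = prot[a] - lip[b]
                d -= box * np.round(d / box)
                dist = float(np.linalg.norm(d))
                if dist < config.cutoff_nm:
                    pairs.append((int(prot_idx[a]), int(lip_idx[b]), dist))
    else:
        tree = cKDTree(lip)
        hits = tree.query_ball_point(prot, r=config.cutoff_nm)
        for a, neighbours in enumerate(hits):
            for b in neighbours:
                dist = float(np.linalg.norm(prot[a] - lip[b]))
                if dist < config.cutoff_nm:
                    pairs.append((int(prot_idx[a]), int(lip_idx[b]), dist))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return pairs


def _resolve_range(n_frames: int, frame_range) -> tuple[int, int]:
    if frame_range is None:
        return 0, n_frames
    start, stop = frame_range
    start = 0 if start is None else int(start)
    stop = n_frames if stop is None else int(stop)
    if start < 0:
        start += n_frames
    if stop < 0:
        stop += n_frames
    stop = min(stop, n_frames)
    if stop <= start:
        raise UsageError(f"empty frame range ({start}, {stop})")
    return start, stop


def contact_profile(
    traj: Trajectory,
    config: ContactConfig = ContactConfig(),
    frame_range: tuple[int | None, int | None] | None = None,
) -> ContactProfile:
    """Per-frame contact counts and per-residue contact fractions.

    A residue counts once per frame no matter how many of its particles
    touch a lipid.  The fraction map covers every protein residue (zeros
    included); ``stable_residues`` is the set with fraction >=
    ``config.stable_fraction``.
    """
    start, stop = _resolve_range(traj.n_frames, frame_range)
    res_of = traj.topology.residue_indices()
    protein_residues = traj.topology.protein_residues()
    touched_frames = {r: 0 for r in protein_residues}
    counts = []
    for k in range(start, stop):
        pairs = frame_contacts(traj.frames[k], traj.topology, config)
        counts.append(len(pairs))
        for r in {int(res_of[a]) for a, _, _ in pairs}:
            touched_frames[r] += 1
    n = stop - start
    fractions = {r: touched_frames[r] / n for r in protein_residues}
    stable = {r for r, f in fractions.items() if f >= config.stable_fraction}
    return ContactProfile(
        per_frame_counts=counts,
        residue_contact_fraction=fractions,
        stable_residues=stable,
        n_frames=n,
        stable_fraction=config.stable_fraction,
        frame_range=(start, stop),
    )


def landing_frame(
    traj: Trajectory,
    config: ContactConfig = ContactConfig(),
    persistence: int = 5,
) -> int | None:
    """First frame from which the contact count stays positive for at least
    ``persistence`` consecutive frames; ``None`` if the protein never lands."""
    if persistence < 1:
        raise UsageError(f"persistence must be >= 1, got {persistence}")
    run_start = None
    run_len = 0
    for k in range(traj.n_frames):
        n = len(frame_contacts(traj.frames[k], traj.topology, config))
        if n > 0:
            if run_start is None:
                run_start = k
            run_len += 1
            if run_len >= persistence:
                return run_start
        else:
            run_start = None
            run_len = 0
    return None
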