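"""Rigid superposition (Kabsch) and coarse-grain-to-atomistic backmapping.

The atomistic pose is recovered from a coarse-grained frame by
least-squares fitting the reference structure's C-alpha atoms onto the
backbone (BB) beads and applying the resulting proper rotation and
translation to the whole reference — a single rigid body, justified when
the protein's internal structure barely changes during the coarse-grained
run.  The SVD-based solver sign-corrects the smallest singular vector so a
reflection is never returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, PairingError
from .structio import Structure


@dataclass
class RigidFit:
    """A proper rigid transform ``x -> rotation @ x + translation`` (nm)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_nm: float
    n_points: int

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise FitError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise FitError(f"rotation determinant {np.linalg.det(R)} != +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def kabsch_fit(moving: np.ndarray, target: np.ndarray) -> RigidFit:
    """Least-squares optimal proper rotation + translation of ``moving``
    onto ``target`` (both (N, 3), N >= 3, non-collinear)."""
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape != target.shape:
        raise FitError(f"point sets must both be (N, 3); got {moving.shape}, {target.shape}")
    n = moving.shape[0]
    if n < 3:
        raise FitError(f"need at least 3 point pairs, got {n}")
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    A = moving - cm
    B = target - ct
    scale = max(np.abs(A).max(), np.abs(B).max(), 1e-12)
    if (np.linalg.matrix_rank(A, tol=1e-8 * scale) < 2
            or np.linalg.matrix_rank(B, tol=1e-8 * scale) < 2):
        raise FitError("degenerate (collinear) point set")
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    diff = (moving @ R.T + t) - target
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return RigidFit(rotation=R, translation=t, rmsd_nm=rmsd, n_points=n)


def backmap_protein(
    fa_reference: Structure,
    cg_frame: np.ndarray,
    cg_topology: Structure,
    ca_name: str = "CA",
    bb_name: str = "BB",
) -> tuple[Structure, RigidFit]:
    """Pose the atomistic reference onto a coarse-grained frame.

    C-alpha atoms of ``fa_reference`` are paired with BB beads of
    ``cg_topology`` by residue index; the Kabsch transform of the C-alpha
    set onto the bead set is applied to every reference atom.  Returns the
    posed structure together with the fit report (post-fit CA<->BB rmsd).
    """
    cg_frame = np.asarray(cg_frame, dtype=float)
    ca = {p.residue_index: p for p in fa_reference.particles
          if p.segment == "protein" and p.name == ca_name}
    bb = {p.residue_index: p.index for p in cg_topology.particles
          if p.segment == "protein" and p.name == bb_name}
    only_fa = sorted(set(ca) - set(bb))
    only_cg = sorted(set(bb) - set(ca))
    if only_fa or only_cg:
        raise PairingError(
            f"residue mismatch between reference {ca_name} set and {bb_name} beads: "
            f"only in reference: {only_fa}; only in CG: {only_cg}"
        )
    residues = sorted(ca)
    moving = np.array([ca[r].position for r in residues])
    targets = np.array([cg_frame[bb[r]] for r in residues])
    fit = kabsch_fit(moving, targets)
    posed = fa_reference.with_positions(fit.apply(fa_reference.positions))
    return posed, fit
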