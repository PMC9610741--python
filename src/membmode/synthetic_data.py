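"""Synthetic structures, trajectories and AFM height fields with planted truth.

The generators emulate the statistical structure of a peripheral membrane
enzyme (a 134-residue secreted phospholipase A2 stand-in) bound to a POPC
bilayer in one of three orientations ("binding modes").  Each mode is
described by a :class:`ModeSpec`: the residue set in lipid contact, the
protein-top altitude over the phosphorus plane, and positional noise.
Defaults plant the experimentally characteristic values: mode altitudes
1.74 / 2.37 / 2.90 nm and occupancies (0.430, 0.346, 0.224) — the latter
derived from the 43 % occupancy of the deepest mode together with the
constraint that the 2→3 mode switch costs twice the energy of 1→2, i.e.
``ln(w2/w3) = 2·ln(w1/w2)``.

All generators are pure functions of their arguments including ``seed``
(NumPy PCG64); identical seeds reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import CapacityError, DataError, UsageError
from .structio import HeightField, Particle, Structure, Trajectory, concatenate

# ---------------------------------------------------------------------------
# Default planted ground truth
# ---------------------------------------------------------------------------

#: Planted protein-top altitudes above the phosphorus plane per mode, nm.
DEFAULT_MODE_ALTITUDES_NM = {1: 1.74, 2: 2.37, 3: 2.90}

#: Residues in lipid contact per mode.  Mode 1 is the canonical interfacial
#: binding surface (17 residues); mode 2 (10 residues, includes Trp128)
#: shares residue 134 with mode 1; mode 3 (6 residues from the 105–115
#: beta-loop) shares residue 112 with mode 2 and nothing with mode 1.
DEFAULT_MODE_RESIDUES = {
    1: frozenset({1, 2, 3, 4, 14, 23, 24, 55, 78, 81, 82, 85, 86, 91, 92, 110, 134}),
    2: frozenset({112, 118, 121, 124, 125, 127, 128, 130, 131, 134}),
    3: frozenset({105, 106, 107, 108, 109, 112}),
}

DEFAULT_ALTITUDE_SD_NM = 0.05
DEFAULT_MOBILITY_SD_NM = 0.05

#: Mapping of the six starting orientations to their final mode
#: (start 1 -> mode 1; starts 2, 4, 5, 6 -> mode 2; start 3 -> mode 3).
DEFAULT_START_TO_MODE = {1: 1, 2: 2, 3: 3, 4: 2, 5: 2, 6: 2}


def default_mixture_weights(w1: float = 0.430) -> np.ndarray:
    """Occupancies of the three modes given the deepest-mode weight.

    Solves ``w1 + w2 + w3 = 1`` with ``ln(w2/w3) = 2·ln(w1/w2)`` (the
    two-fold transition-energy constraint) by 1-D root finding on
    ``x = w2/w1``: ``x + x**3 = 1/w1 - 1``.
    """
    if not 0 < w1 < 1:
        raise UsageError(f"w1 must be in (0, 1), got {w1}")
    rhs = 1.0 / w1 - 1.0
    x = brentq(lambda v: v + v**3 - rhs, 1e-9, max(rhs, 1.0) + 1.0, xtol=1e-15)
    w = np.array([w1, w1 * x, w1 * x**3])
    return w / w.sum()


@dataclass
class ModeSpec:
    """Planted description of one binding mode."""

    label: int
    contact_residues: frozenset[int]
    altitude_nm: float
    altitude_sd_nm: float = DEFAULT_ALTITUDE_SD_NM
    mobility_sd_nm: float | Mapping[int, float] = DEFAULT_MOBILITY_SD_NM

    def __post_init__(self) -> None:
        self.contact_residues = frozenset(int(r) for r in self.contact_residues)
        if not self.contact_residues:
            raise UsageError("contact_residues must be non-empty")
        if min(self.contact_residues) < 1:
            raise UsageError("contact residues must be positive residue indices")
        if not self.altitude_sd_nm > 0:
            raise UsageError(f"altitude_sd_nm must be > 0, got {self.altitude_sd_nm}")
        if isinstance(self.mobility_sd_nm, Mapping):
            if any(v < 0 for v in self.mobility_sd_nm.values()):
                raise UsageError("per-residue mobility sd must be >= 0")
        elif self.mobility_sd_nm < 0:
            raise UsageError(f"mobility_sd_nm must be >= 0, got {self.mobility_sd_nm}")

    def mobility_sd_for(self, residue_index: int) -> float:
        if isinstance(self.mobility_sd_nm, Mapping):
            return float(self.mobility_sd_nm.get(residue_index, DEFAULT_MOBILITY_SD_NM))
        return float(self.mobility_sd_nm)


def default_mode_spec(label: int, **overrides) -> ModeSpec:
    """The default ModeSpec for mode 1, 2 or 3."""
    if label not in DEFAULT_MODE_RESIDUES:
        raise UsageError(f"no default mode {label}; choose 1, 2 or 3")
    kwargs = dict(
        label=label,
        contact_residues=DEFAULT_MODE_RESIDUES[label],
        altitude_nm=DEFAULT_MODE_ALTITUDES_NM[label],
    )
    kwargs.update(overrides)
    return ModeSpec(**kwargs)


@dataclass
class MixtureSpec:
    """A K-component 1-D Gaussian mixture (altitude populations)."""

    weights: np.ndarray
    means_nm: np.ndarray
    sds_nm: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        self.means_nm = np.asarray(self.means_nm, dtype=float).reshape(-1)
        self.sds_nm = np.asarray(self.sds_nm, dtype=float).reshape(-1)
        k = len(self.weights)
        if k < 1 or len(self.means_nm) != k or len(self.sds_nm) != k:
            raise UsageError("weights, means_nm, sds_nm must have equal length >= 1")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise UsageError("weights must be non-negative and sum to 1 within 1e-9")
        if np.any(self.sds_nm <= 0):
            raise UsageError("sds_nm must be positive")
        if np.any(np.diff(self.means_nm) <= 0):
            raise UsageError("means_nm must be strictly increasing")

    @property
    def n_components(self) -> int:
        return len(self.weights)


def default_mixture_spec(sd_nm: float = 0.15) -> MixtureSpec:
    """Three-component spec at the characteristic mode altitudes."""
    return MixtureSpec(
        weights=default_mixture_weights(),
        means_nm=np.array([DEFAULT_MODE_ALTITUDES_NM[k] for k in (1, 2, 3)]),
        sds_nm=np.full(3, sd_nm),
    )


# ---------------------------------------------------------------------------
# Structure generators
# ---------------------------------------------------------------------------


def _sample_in_shell(rng, r_lo, r_hi, cos_lo, cos_hi):
    """Uniform point in a spherical shell sector (radius and polar-cos bounds)."""
    u = rng.uniform()
    r = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)
    cos_t = rng.uniform(cos_lo, cos_hi)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), r * cos_t])


def make_toy_protein(
    n_residues: int = 134,
    seed: int = 0,
    radius_nm: float = 1.45,
    min_separation_nm: float = 0.3,
    patch_layout: bool | None = None,
) -> Structure:
    """A compact self-avoiding one-bead-per-residue globule, diameter ~3 nm.

    When ``patch_layout`` is active (default: on whenever ``n_residues``
    covers the default mode residue sets), the mode-1 contact residues are
    placed near the globule's south pole and the mode-3 (beta-loop core)
    residues near the north pole, so the planted mode regions reproduce the
    geometry of the three binding modes: modes 1/2 and 2/3 adjacent, modes
    1/3 on opposite faces (spatially disjoint at a 0.8 nm neighbor cutoff).
    """
    if n_residues < 2:
        raise UsageError(f"n_residues must be >= 2, got {n_residues}")
    rng = np.random.default_rng(seed)
    max_default = max(DEFAULT_MODE_RESIDUES[1] | DEFAULT_MODE_RESIDUES[3])
    if patch_layout is None:
        patch_layout = n_residues >= max_default

    south = DEFAULT_MODE_RESIDUES[1] if patch_layout else frozenset()
    north = (DEFAULT_MODE_RESIDUES[3] - DEFAULT_MODE_RESIDUES[1]) if patch_layout else frozenset()

    positions: list[np.ndarray] = []
    accepted = np.empty((0, 3))
    for res in range(1, n_residues + 1):
        if res in south:
            r_lo, r_hi, cos_lo, cos_hi = 0.70 * radius_nm, radius_nm, -1.0, np.cos(np.deg2rad(135.0))
        elif res in north:
            r_lo, r_hi, cos_lo, cos_hi = 0.70 * radius_nm, radius_nm, np.cos(np.deg2rad(45.0)), 1.0
        elif patch_layout:
            r_lo, r_hi, cos_lo, cos_hi = 0.0, radius_nm, np.cos(np.deg2rad(125.0)), np.cos(np.deg2rad(55.0))
        else:
            r_lo, r_hi, cos_lo, cos_hi = 0.0, radius_nm, -1.0, 1.0
        placed = False
        for _ in range(20000):
            cand = _sample_in_shell(rng, r_lo, r_hi, cos_lo, cos_hi)
            if accepted.size == 0 or np.min(
                np.linalg.norm(accepted - cand, axis=1)
            ) > min_separation_nm:
                positions.append(cand)
                accepted = np.vstack([accepted, cand])
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place residue {res} with min separation "
                f"{min_separation_nm} nm inside radius {radius_nm} nm"
            )
    particles = [
        Particle(i, "CA", i + 1, "ALA", "protein", positions[i]) for i in range(n_residues)
    ]
    return Structure(particles)


def make_bilayer_patch(
    nx: int = 15,
    ny: int = 15,
    spacing_nm: float = 0.8,
    seed: int = 0,
    half_thickness_nm: float = 2.0,
    jitter_sd_nm: float = 0.0,
    n_tail_beads: int = 2,
) -> Structure:
    """A flat two-leaflet lipid patch with one phosphorus bead per lipid.

    Each leaflet holds ``nx * ny`` lipids on a square lattice; each lipid
    contributes a "P" bead at z = ±half_thickness (plus optional Gaussian
    jitter) and ``n_tail_beads`` tail beads stacked toward the midplane at
    z = 0.  The mean z of the upper-leaflet P beads defines the interface.
    """
    if nx < 2 or ny < 2:
        raise UsageError(f"nx and ny must be >= 2, got {nx}, {ny}")
    rng = np.random.default_rng(seed)
    particles: list[Particle] = []
    residue = 0
    index = 0
    tail_step = half_thickness_nm / (n_tail_beads + 1)
    for leaflet in (+1, -1):
        for i in range(nx):
            for j in range(ny):
                residue += 1
                x = (i + 0.5) * spacing_nm
                y = (j + 0.5) * spacing_nm
                zp = leaflet * half_thickness_nm + (
                    rng.normal(0.0, jitter_sd_nm) if jitter_sd_nm > 0 else 0.0
                )
                particles.append(
                    Particle(index, "P", residue, "POPC", "lipid", np.array([x, y, zp]))
                )
                index += 1
                for k in range(1, n_tail_beads + 1):
                    zt = leaflet * (half_thickness_nm - k * tail_step)
                    particles.append(
                        Particle(index, f"C{k}", residue, "POPC", "lipid", np.array([x, y, zt]))
                    )
                    index += 1
    box = np.array([nx * spacing_nm, ny * spacing_nm, 6.0 * half_thickness_nm])
    return Structure(particles, box)


# ---------------------------------------------------------------------------
# Trajectory generator
# ---------------------------------------------------------------------------

#: Vertical gap between a contact residue bead and its anchor P bead, nm.
#: Must sit well inside the 0.6 nm contact cutoff with room for jitter.
CONTACT_GAP_NM = 0.35

#: Minimum clearance of non-contact residues above the phosphorus plane, nm
#: (beyond the cutoff, so they never register as contacts).
NONCONTACT_CLEARANCE_NM = 1.0


def landing_segment_length(n_frames: int) -> int:
    """Number of approach frames planted ahead of the bound segment."""
    return int(round(0.1 * n_frames))


def simulate_binding_trajectory(
    protein: Structure,
    bilayer: Structure,
    mode: ModeSpec,
    n_frames: int,
    seed: int = 0,
    timestep_ns: float = 0.1,
) -> Trajectory:
    """A rigid-body bound-state trajectory with a planted binding mode.

    The protein lands during the first ~10 % of frames (approach from
    >= 1 nm above the bound pose) and then stays bound with:

    * every ``mode.contact_residues`` bead anchored ~0.35 nm above a
      phosphorus bead (inside the 0.6 nm contact cutoff),
    * every other residue at least 1 nm above the phosphorus plane
      (outside the cutoff),
    * the protein-top altitude over the phosphorus plane drawn i.i.d. from
      N(mode.altitude_nm, mode.altitude_sd_nm) — the top is carried by a
      designated apex bead,
    * independent per-frame Gaussian jitter of sd ``mode.mobility_sd_nm``
      on every other protein bead.

    The bilayer is static.  Frames list protein beads first, then lipids.
    """
    if n_frames < 2:
        raise UsageError(f"n_frames must be >= 2, got {n_frames}")
    protein_residues = set(protein.protein_residues())
    missing = mode.contact_residues - protein_residues
    if missing:
        raise UsageError(
            f"contact residues {sorted(missing)} not present in protein "
            f"(residues 1..{max(protein_residues, default=0)})"
        )

    topology = concatenate(protein, bilayer)
    rng = np.random.default_rng(seed)

    # Interface: mean z of upper-leaflet phosphorus beads.
    p_mask = [p for p in bilayer.particles if p.name == "P"]
    p_z = np.array([p.position[2] for p in p_mask])
    mid = 0.5 * (p_z.min() + p_z.max())
    uppers = [p for p in p_mask if p.position[2] > mid]
    interface = float(np.mean([p.position[2] for p in uppers]))

    # Anchor each contact residue above a distinct upper-leaflet P bead,
    # choosing lipids nearest the patch centre.
    center = np.mean([p.position[:2] for p in uppers], axis=0)
    order = np.argsort([np.linalg.norm(p.position[:2] - center) for p in uppers])
    contact_sorted = sorted(mode.contact_residues)
    if len(contact_sorted) > len(uppers):
        raise UsageError("more contact residues than upper-leaflet lipids")
    anchors = {res: uppers[order[k]] for k, res in enumerate(contact_sorted)}

    # Base (bound) pose, built per residue.
    n_prot = protein.n_particles
    res_of = protein.residue_indices()
    in_pos = protein.positions
    non_contact = [i for i in range(n_prot) if res_of[i] not in mode.contact_residues]
    if not non_contact:
        raise UsageError("protein must have at least one non-contact residue (the apex)")
    apex = max(non_contact, key=lambda i: in_pos[i, 2])

    # Lateral spread of non-contact residues: recentre and cap at 1.2 nm.
    lateral = in_pos[:, :2] - in_pos[:, :2].mean(axis=0)
    max_r = np.max(np.linalg.norm(lateral, axis=1))
    if max_r > 0:
        lateral = lateral * min(1.0, 1.2 / max_r)
    # z band for non-contact, non-apex residues.
    z_lo = interface + NONCONTACT_CLEARANCE_NM
    z_hi = max(z_lo + 0.05, interface + mode.altitude_nm - 0.4)
    others = [i for i in non_contact if i != apex]
    zin = in_pos[:, 2]
    zin_lo, zin_hi = (zin[others].min(), zin[others].max()) if others else (0.0, 1.0)
    span = max(zin_hi - zin_lo, 1e-12)

    base = np.empty((n_prot, 3))
    sd = np.array([mode.mobility_sd_for(int(res_of[i])) for i in range(n_prot)])
    for i in range(n_prot):
        res = int(res_of[i])
        if res in mode.contact_residues:
            a = anchors[res].position
            base[i] = [a[0], a[1], a[2] + CONTACT_GAP_NM]
        elif i == apex:
            base[i] = [center[0], center[1], interface + mode.altitude_nm]
        else:
            frac = (zin[i] - zin_lo) / span
            base[i] = [center[0] + lateral[i, 0], center[1] + lateral[i, 1],
                       z_lo + frac * (z_hi - z_lo)]

    lipid_coords = bilayer.positions
    n_land = landing_segment_length(n_frames)
    frames = []
    for k in range(n_frames):
        alt = rng.normal(mode.altitude_nm, mode.altitude_sd_nm)
        jitter = rng.normal(0.0, 1.0, size=(n_prot, 3)) * sd[:, None]
        pos = base + jitter
        pos[apex, 2] = interface + alt  # apex z carries the planted altitude exactly
        if k < n_land:
            # approach: stay >= 0.5 nm above the bound pose so no contacts
            # form before the planted landing frame
            pos[:, 2] += 0.5 + (n_land - k) / n_land * 1.0
        frames.append(np.vstack([pos, lipid_coords]))

    return Trajectory(
        topology=topology,
        frames=frames,
        timestep=timestep_ns,
        metadata={
            "planted_mode": mode.label,
            "landing_frame": n_land,
            "interface_z": interface,
            "apex_particle": int(apex),
            "planted_altitude_nm": mode.altitude_nm,
            "planted_altitude_sd_nm": mode.altitude_sd_nm,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# AFM generators
# ---------------------------------------------------------------------------


@dataclass
class PlantedParticle:
    """Ground-truth record for one synthetic AFM globule."""

    x_nm: float
    y_nm: float
    peak_height_nm: float
    component: int


def sample_mixture(
    spec: MixtureSpec,
    n: int,
    seed: int = 0,
    return_components: bool = False,
):
    """I.i.d. draws from a Gaussian mixture; optionally with component labels."""
    if n < 1:
        raise UsageError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    comps = rng.choice(spec.n_components, size=n, p=spec.weights)
    samples = rng.normal(spec.means_nm[comps], spec.sds_nm[comps])
    if return_components:
        return samples, comps
    return samples


def simulate_afm_field(
    spec: MixtureSpec,
    n_particles: int,
    field_nm: float = 200.0,
    noise_sd_nm: float = 0.05,
    seed: int = 0,
    pixel_size_nm: float = 1.0,
    min_separation_nm: float = 10.0,
    lateral_sd_nm: float = 1.5,
) -> tuple[HeightField, list[PlantedParticle]]:
    """A flat background at height 0 plus Gaussian-cap globules.

    Peak heights are drawn from ``spec``; bumps are isotropic Gaussian caps
    of lateral sd ``lateral_sd_nm`` (an idealized tip-convolved globule).
    Additive pixel noise of sd ``noise_sd_nm`` is applied last.  Returns the
    field together with the planted particle table.
    """
    if n_particles < 0:
        raise UsageError("n_particles must be >= 0")
    rng = np.random.default_rng(seed)
    n_px = int(round(field_nm / pixel_size_nm))
    if n_px < 4:
        raise UsageError("field too small for the given pixel size")
    margin = 4.0 * lateral_sd_nm
    if field_nm - 2 * margin <= 0 and n_particles > 0:
        raise UsageError("field too small for any globule")

    centers = np.empty((0, 2))
    attempts = 0
    max_attempts = 2000 * max(n_particles, 1)
    while len(centers) < n_particles:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"placed only {len(centers)}/{n_particles} globules at "
                f"min separation {min_separation_nm} nm in a {field_nm} nm field"
            )
        cand = rng.uniform(margin, field_nm - margin, size=2)
        # snap to pixel centres so the planted peak height is exactly
        # representable on the sampled grid
        cand = (np.floor(cand / pixel_size_nm) + 0.5) * pixel_size_nm
        if len(centers) == 0 or np.min(
            np.linalg.norm(centers - cand, axis=1)
        ) >= min_separation_nm:
            centers = np.vstack([centers, cand])

    heights, comps = (np.empty(0), np.empty(0, dtype=int))
    if n_particles > 0:
        heights, comps = sample_mixture(spec, n_particles, seed=rng.integers(2**31),
                                        return_components=True)
        heights = np.maximum(heights, 1e-6)

    grid = np.zeros((n_px, n_px))
    axis = (np.arange(n_px) + 0.5) * pixel_size_nm
    xx, yy = np.meshgrid(axis, axis, indexing="xy")  # row=y, col=x
    truth = []
    for k in range(n_particles):
        cx, cy = centers[k]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        bump = heights[k] * np.exp(-r2 / (2.0 * lateral_sd_nm**2))
        bump[r2 > (4.0 * lateral_sd_nm) ** 2] = 0.0
        grid += bump
        truth.append(PlantedParticle(float(cx), float(cy), float(heights[k]), int(comps[k])))
    if noise_sd_nm > 0:
        grid += rng.normal(0.0, noise_sd_nm, size=grid.shape)
    return HeightField(grid, pixel_size_nm), truth


def simulate_afm_batch(
    spec: MixtureSpec,
    n_particles_total: int,
    n_fields: int,
    seed: int = 0,
    **field_kwargs,
) -> tuple[list[HeightField], list[list[PlantedParticle]]]:
    """Several fields of view sharing one mixture spec (particles split evenly)."""
    if n_fields < 1:
        raise UsageError("n_fields must be >= 1")
    per = [n_particles_total // n_fields] * n_fields
    for i in range(n_particles_total % n_fields):
        per[i] += 1
    rng = np.random.default_rng(seed)
    fields, truths = [], []
    for n_k in per:
        f, t = simulate_afm_field(spec, n_k, seed=int(rng.integers(2**31)), **field_kwargs)
        fields.append(f)
        truths.append(t)
    return fields, truths
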