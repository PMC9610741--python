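"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from membmode import (
    default_mode_spec,
    make_bilayer_patch,
    make_toy_protein,
    simulate_binding_trajectory,
)
from membmode.structio import Particle, Structure


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_protein(134, seed=11)


@pytest.fixture(scope="session")
def small_protein():
    return make_toy_protein(10, seed=2)


@pytest.fixture(scope="session")
def bilayer():
    return make_bilayer_patch(nx=15, ny=15, seed=3)


@pytest.fixture(scope="session")
def mode1_traj(toy_protein, bilayer):
    """A 200-frame mode-1 trajectory (landing segment = frames 0..19)."""
    return simulate_binding_trajectory(
        toy_protein, bilayer, default_mode_spec(1), n_frames=200, seed=42
    )


def make_two_particle_system(lipid_offset, box=None):
    """One protein bead at the origin and one lipid bead at a given offset."""
    particles = [
        Particle(0, "CA", 1, "ALA", "protein", np.zeros(3)),
        Particle(1, "P", 2, "POPC", "lipid", np.asarray(lipid_offset, dtype=float)),
    ]
    return Structure(particles, box)


def brute_force_contacts(frame, topology, cutoff, periodic=False, heavy_only=True):
    """All-pairs reference implementation of the contact search."""
    def heavy(name):
        return not name.upper().startswith("H")

    prot = [p.index for p in topology.particles
            if p.segment == "protein" and (not heavy_only or heavy(p.name))]
    lip = [p.index for p in topology.particles
           if p.segment == "lipid" and (not heavy_only or heavy(p.name))]
    out = []
    for a in prot:
        for b in lip:
            d = frame[a] - frame[b]
            if periodic:
                d = d - topology.box * np.round(d / topology.box)
            dist = float(np.linalg.norm(d))
            if dist < cutoff:
                out.append((a, b, dist))
    out.sort(key=lambda t: (t[0], t[1]))
    return out
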