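"""Boltzmann energetics of binding-mode populations and transition paths.

Given equilibrium occupancies p_i of the modes at temperature T, the energy
of state j relative to state i is dE_ij = -kB*T*ln(p_j/p_i).  The diagram
stores energies relative to the most populated mode (set to zero).  The
allowed transition path between the deepest and shallowest modes runs
through mode pairs whose contact regions overlap or neighbour each other,
minimizing the summed uphill energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import UsageError

#: Boltzmann constant in kJ/(mol*K).
KB_KJ_PER_MOL_K = 0.0083144626

#: Coarse-grained simulation temperature, K.
DEFAULT_TEMPERATURE_K = 295.0


@dataclass
class EnergyDiagram:
    """Per-mode Boltzmann energies relative to the most populated mode."""

    temperature_K: float
    populations: np.ndarray
    energies_kJmol: np.ndarray
    kB: float = KB_KJ_PER_MOL_K

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=float).reshape(-1)
        self.energies_kJmol = np.asarray(self.energies_kJmol, dtype=float).reshape(-1)
        if len(self.populations) != len(self.energies_kJmol):
            raise UsageError("populations and energies must have equal length")
        if np.any(self.energies_kJmol < -1e-12):
            raise UsageError("energies must be >= 0 relative to the ground mode")
        p_max = self.populations.max()
        expected = -self.kB * self.temperature_K * np.log(self.populations / p_max)
        if not np.allclose(self.energies_kJmol, expected, atol=1e-9):
            raise UsageError("energies inconsistent with populations (Boltzmann relation)")

    @property
    def n_modes(self) -> int:
        return len(self.populations)

    @property
    def energies_kT(self) -> np.ndarray:
        return self.energies_kJmol / (self.kB * self.temperature_K)

    def delta_energy(self, i: int, j: int) -> float:
        """dE(i -> j) in kJ/mol for 1-based mode labels (antisymmetric)."""
        return float(self.energies_kJmol[j - 1] - self.energies_kJmol[i - 1])


def boltzmann_energies(
    populations: Sequence[float],
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> EnergyDiagram:
    """Energy diagram from mode occupancies.

    Populations must be positive; they are renormalized (with a warning when
    their sum deviates from 1 by more than 1e-6).
    """
    p = np.asarray(populations, dtype=float).reshape(-1)
    if len(p) < 1:
        raise UsageError("need at least one population")
    if np.any(p <= 0):
        raise UsageError(f"populations must be strictly positive, got {p}")
    if not temperature_K > 0:
        raise UsageError(f"temperature must be positive, got {temperature_K}")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        import warnings

        warnings.warn(f"populations sum to {total:.6g}; renormalizing")
    p = p / total
    energies = -KB_KJ_PER_MOL_K * temperature_K * np.log(p / p.max())
    energies[np.argmax(p)] = 0.0  # exact zero at the ground mode
    energies = np.maximum(energies, 0.0)
    return EnergyDiagram(
        temperature_K=temperature_K, populations=p, energies_kJmol=energies
    )


def transition_path(
    diagram: EnergyDiagram,
    adjacency: Mapping[tuple[int, int], str],
) -> list[int] | None:
    """Ordered mode sequence from mode 1 to mode K along connected pairs.

    A pair is traversable when its contact regions are "overlapping" or
    "neighboring"; the path minimizes the sum of uphill (positive) energy
    steps.  Returns ``None`` when the end modes are disconnected.
    """
    k = diagram.n_modes
    if k == 1:
        return [1]
    g = nx.Graph()
    g.add_nodes_from(range(1, k + 1))
    for (i, j), kind in adjacency.items():
        if not (1 <= i <= k and 1 <= j <= k):
            raise UsageError(f"adjacency pair ({i}, {j}) outside modes 1..{k}")
        if kind not in ("overlapping", "neighboring", "disjoint"):
            raise UsageError(f"unknown adjacency kind {kind!r}")
        if kind != "disjoint":
            g.add_edge(i, j)
    for i in range(1, k + 1):
        for j in range(i + 1, k + 1):
            if (i, j) not in adjacency and (j, i) not in adjacency:
                raise UsageError(f"adjacency does not cover mode pair ({i}, {j})")

    def uphill(u, v, _attrs):
        return max(diagram.delta_energy(u, v), 0.0)

    try:
        return [int(m) for m in nx.dijkstra_path(g, 1, k, weight=uphill)]
    except nx.NetworkXNoPath:
        return None
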