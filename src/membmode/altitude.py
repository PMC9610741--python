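"""Membrane interface estimation and protein altitude distributions.

The membrane interface (altitude zero) is the mean z of the phosphorus
particles, by default of the upper leaflet only, since a peripheral protein
binds one face.  The protein altitude is measured either from the topmost
protein particle ("top", the AFM-like top-surface height) or from the
protein centre of geometry ("com").  Which protein point the altitude
refers to is the largest numeric ambiguity in matching simulation to AFM
numbers, so it is a configuration choice, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError, UsageError
from .structio import Structure, Trajectory
from .contacts import _resolve_range


@dataclass
class AltitudeConfig:
    """reference: "top" (max protruding particle) or "com" (centre of
    geometry); leaflet: "upper" or "both" phosphorus selection."""

    reference: str = "top"
    leaflet: str = "upper"

    def __post_init__(self) -> None:
        if self.reference not in ("top", "com"):
            raise UsageError(f"reference must be 'top' or 'com', got {self.reference!r}")
        if self.leaflet not in ("upper", "both"):
            raise UsageError(f"leaflet must be 'upper' or 'both', got {self.leaflet!r}")


@dataclass
class AltitudeDistribution:
    """Per-frame altitudes (nm) with summary statistics."""

    samples: np.ndarray
    mean: float
    sd: float
    frame_range: tuple[int, int]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if abs(self.mean - float(np.mean(self.samples))) > 1e-9:
            raise UsageError("mean inconsistent with samples")
        if abs(self.sd - float(np.std(self.samples))) > 1e-9:
            raise UsageError("sd inconsistent with samples")


def _phosphorus_indices(topology: Structure) -> np.ndarray:
    idx = np.array(
        [p.index for p in topology.particles if p.segment == "lipid" and p.name == "P"],
        dtype=int,
    )
    if len(idx) == 0:
        raise SelectionError("no phosphorus ('P') lipid particles in topology")
    return idx


def interface_z(
    frame: np.ndarray,
    topology: Structure,
    config: AltitudeConfig = AltitudeConfig(),
) -> float:
    """Mean z of the (selected-leaflet) phosphorus particles, nm.

    The upper leaflet is the set of P particles above the midpoint of the
    minimum and maximum P z — robust for flat patches.
    """
    frame = np.asarray(frame, dtype=float)
    z = frame[_phosphorus_indices(topology), 2]
    if config.leaflet == "upper":
        mid = 0.5 * (z.min() + z.max())
        upper = z[z > mid]
        if len(upper) == 0:  # degenerate flat single-leaflet input
            upper = z
        return float(np.mean(upper))
    return float(np.mean(z))


def frame_altitude(
    frame: np.ndarray,
    topology: Structure,
    config: AltitudeConfig = AltitudeConfig(),
) -> float:
    """Protein altitude over the phosphorus plane for one frame, nm.

    ``reference="top"``: max protein z minus interface; ``"com"``: protein
    centre-of-geometry z minus interface.  Negative when the protein sits
    below the plane.
    """
    frame = np.asarray(frame, dtype=float)
    prot = topology.segment_indices("protein")
    if len(prot) == 0:
        raise SelectionError("no protein particles in topology")
    ref = interface_z(frame, topology, config)
    z = frame[prot, 2]
    if config.reference == "top":
        return float(z.max() - ref)
    return float(z.mean() - ref)


def altitude_distribution(
    traj: Trajectory,
    config: AltitudeConfig = AltitudeConfig(),
    frame_range: tuple[int | None, int | None] | None = None,
) -> AltitudeDistribution:
    """Altitude of every frame in the (optional) range, with mean and sd."""
    start, stop = _resolve_range(traj.n_frames, frame_range)
    samples = np.array(
        [frame_altitude(traj.frames[k], traj.topology, config) for k in range(start, stop)]
    )
    return AltitudeDistribution(
        samples=samples,
        mean=float(np.mean(samples)),
        sd=float(np.std(samples)),
        frame_range=(start, stop),
    )
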