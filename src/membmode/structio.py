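"""Domain containers and file I/O for structures, trajectories and height fields.

All coordinates are stored in nanometres internally, whatever the on-disk
unit of the source format (PDB angstrom values are converted on read and
write).  The membrane normal is the z axis by convention.

Parsing of the standard molecular formats (PDB, GRO, XYZ) is delegated to
MDAnalysis; this module only wraps the results into the package's plain
containers and applies the nm unit convention and segment classification.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError, ParseError, UsageError

SEGMENTS = ("protein", "lipid", "solvent", "other")

#: Standard amino-acid residue names (3-letter), used for segment classification.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Default residue-name allow-lists for segment classification on file read.
DEFAULT_LIPID_RESNAMES = frozenset({"POPC", "POPE", "DPPC", "DOPC", "DOPE", "POP", "LIP"})
DEFAULT_SOLVENT_RESNAMES = frozenset(
    {"W", "WF", "HOH", "SOL", "TIP3", "TIP", "NA", "CL", "CA", "NA+", "CL-", "ION", "K", "MG"}
)

_NM_PER_ANGSTROM = 0.1


def classify_segment(
    residue_name: str,
    lipid_resnames: Iterable[str] = DEFAULT_LIPID_RESNAMES,
    solvent_resnames: Iterable[str] = DEFAULT_SOLVENT_RESNAMES,
) -> str:
    """Classify a residue name into protein / lipid / solvent / other."""
    rn = residue_name.strip().upper()
    if rn in lipid_resnames:
        return "lipid"
    if rn in solvent_resnames:
        return "solvent"
    if rn in AMINO_ACIDS:
        return "protein"
    return "other"


@dataclass
class Particle:
    """One atom or coarse-grained bead.

    Attributes
    ----------
    index : int
        0-based position in the parent structure.
    name : str
        Particle name, e.g. ``"CA"``, ``"P"``, ``"BB"``.
    residue_index : int
        1-based residue number.
    residue_name : str
        Residue name (up to 4 characters in practice).
    segment : str
        One of ``"protein"``, ``"lipid"``, ``"solvent"``, ``"other"``.
    position : (3,) ndarray
        Cartesian position in nm.
    """

    index: int
    name: str
    residue_index: int
    residue_name: str
    segment: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise DataError(f"particle {self.index}: non-finite position {self.position}")
        if self.index < 0:
            raise DataError(f"negative particle index {self.index}")
        if self.residue_index < 1:
            raise DataError(
                f"particle {self.index}: residue_index must be >= 1, got {self.residue_index}"
            )
        if self.segment not in SEGMENTS:
            raise DataError(f"particle {self.index}: unknown segment {self.segment!r}")


@dataclass
class Structure:
    """An ordered set of particles, optionally with an orthorhombic box (nm)."""

    particles: list[Particle]
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        indices = [p.index for p in self.particles]
        if indices != list(range(len(self.particles))):
            raise DataError("particle indices must be unique and consecutive from 0")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise DataError(f"box components must be positive, got {self.box}")

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of positions in nm (a copy)."""
        return np.array([p.position for p in self.particles], dtype=float).reshape(-1, 3)

    def segment_indices(self, segment: str) -> np.ndarray:
        """Particle indices belonging to one segment class."""
        return np.array([p.index for p in self.particles if p.segment == segment], dtype=int)

    def residue_indices(self) -> np.ndarray:
        """Per-particle residue index array."""
        return np.array([p.residue_index for p in self.particles], dtype=int)

    def protein_residues(self) -> list[int]:
        """Sorted unique residue indices of the protein segment."""
        return sorted({p.residue_index for p in self.particles if p.segment == "protein"})

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_particles, 3):
            raise UsageError(
                f"positions shape {positions.shape} != ({self.n_particles}, 3)"
            )
        new = [
            Particle(p.index, p.name, p.residue_index, p.residue_name, p.segment, positions[i])
            for i, p in enumerate(self.particles)
        ]
        return Structure(new, None if self.box is None else self.box.copy())


def concatenate(first: Structure, second: Structure, offset_residues: bool = True) -> Structure:
    """Concatenate two structures, reindexing particles (and residues of the
    second block, so residue indices stay unique across the join)."""
    offset = max((p.residue_index for p in first.particles), default=0) if offset_residues else 0
    particles = [
        Particle(p.index, p.name, p.residue_index, p.residue_name, p.segment, p.position.copy())
        for p in first.particles
    ]
    n0 = len(particles)
    for p in second.particles:
        particles.append(
            Particle(n0 + p.index, p.name, p.residue_index + offset, p.residue_name,
                     p.segment, p.position.copy())
        )
    box = first.box if first.box is not None else second.box
    return Structure(particles, None if box is None else np.array(box, dtype=float))


@dataclass
class Trajectory:
    """A topology plus a stack of per-frame coordinate arrays (nm).

    ``timestep`` is informational (ns per frame).  ``metadata`` carries
    generator provenance (planted mode, landing frame, ...) and does not
    affect equality-sensitive analyses.
    """

    topology: Structure
    frames: list[np.ndarray]
    timestep: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise DataError("trajectory must contain at least one frame")
        n = self.topology.n_particles
        cleaned = []
        for i, f in enumerate(self.frames):
            arr = np.asarray(f, dtype=float)
            if arr.shape != (n, 3):
                raise DataError(
                    f"frame {i}: expected {n} particles, got shape {arr.shape}"
                )
            cleaned.append(arr)
        self.frames = cleaned

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """(n_frames, N, 3) stacked coordinate array."""
        return np.stack(self.frames)


@dataclass
class HeightField:
    """A rectangular AFM-style height image in nm."""

    heights: np.ndarray
    pixel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise DataError("height grid must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.heights)):
            raise DataError("height grid contains non-finite values")
        if not self.pixel_size > 0:
            raise DataError(f"pixel_size must be positive, got {self.pixel_size}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


# ---------------------------------------------------------------------------
# MDAnalysis-backed readers / writers
# ---------------------------------------------------------------------------


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _universe_to_structure(u, lipid_resnames, solvent_resnames) -> Structure:
    atoms = u.atoms
    if len(atoms) == 0:
        raise ParseError("file contains no particles")
    try:
        resnames = atoms.resnames
    except AttributeError:
        resnames = np.array(["UNK"] * len(atoms))
    try:
        names = atoms.names
    except AttributeError:
        names = np.array(["X"] * len(atoms))
    resids = atoms.resids
    positions = atoms.positions * _NM_PER_ANGSTROM
    particles = []
    for i in range(len(atoms)):
        rname = str(resnames[i])
        particles.append(
            Particle(
                index=i,
                name=str(names[i]),
                residue_index=max(int(resids[i]), 1),
                residue_name=rname,
                segment=classify_segment(rname, lipid_resnames, solvent_resnames),
                position=positions[i],
            )
        )
    box = None
    dims = u.dimensions
    if dims is not None and np.all(np.asarray(dims[:3]) > 0):
        box = np.asarray(dims[:3], dtype=float) * _NM_PER_ANGSTROM
    return Structure(particles, box)


def read_structure(
    path: str | Path,
    format: str | None = None,
    lipid_resnames: Iterable[str] = DEFAULT_LIPID_RESNAMES,
    solvent_resnames: Iterable[str] = DEFAULT_SOLVENT_RESNAMES,
) -> Structure:
    """Read a single-frame structure from a PDB or GRO file.

    Coordinates are converted to nm.  Segment labels are assigned from the
    residue name against the configurable lipid/solvent allow-lists.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("pdb", "gro"):
        raise UsageError(f"unknown structure format {format!r} (expected 'pdb' or 'gro')")
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    mda = _import_mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=format)
    except Exception as exc:  # MDAnalysis raises many concrete types here
        raise ParseError(f"{path}: could not parse as {format.upper()}: {exc}") from exc
    return _universe_to_structure(u, lipid_resnames, solvent_resnames)


def _structure_to_universe(structure: Structure, positions_nm: np.ndarray):
    """Build an in-memory MDAnalysis Universe mirroring a Structure."""
    mda = _import_mda()
    n = structure.n_particles
    resids_per_particle = structure.residue_indices()
    # residues ordered by first appearance
    seen: dict[int, int] = {}
    atom_resindex = np.empty(n, dtype=int)
    resids, resnames = [], []
    for i, p in enumerate(structure.particles):
        key = p.residue_index
        if key not in seen:
            seen[key] = len(seen)
            resids.append(p.residue_index)
            resnames.append(p.residue_name)
        atom_resindex[i] = seen[key]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=len(resids), atom_resindex=atom_resindex, trajectory=True
        )
        u.add_TopologyAttr("names", [p.name for p in structure.particles])
        u.add_TopologyAttr("resids", resids)
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("elements", [(p.name[:1] or "X") for p in structure.particles])
        u.atoms.positions = np.asarray(positions_nm, dtype=float) / _NM_PER_ANGSTROM
        if structure.box is not None:
            u.dimensions = np.array(
                [*(structure.box / _NM_PER_ANGSTROM), 90.0, 90.0, 90.0], dtype=float
            )
    return u


def write_structure(structure: Structure, path: str | Path, format: str | None = None) -> None:
    """Write a structure to PDB or GRO (coordinates converted from nm)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("pdb", "gro"):
        raise UsageError(f"unknown structure format {format!r}")
    u = _structure_to_universe(structure, structure.positions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _split_gro_frames(text: str) -> list[str]:
    """Split a concatenated multi-frame GRO file into single-frame chunks."""
    lines = text.splitlines()
    chunks = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip() and pos == len(lines) - 1:
            break
        if pos + 1 >= len(lines):
            raise ParseError(f"truncated GRO frame starting at line {pos + 1}")
        try:
            natoms = int(lines[pos + 1].strip())
        except ValueError as exc:
            raise ParseError(
                f"line {pos + 2}: expected particle count, got {lines[pos + 1]!r}"
            ) from exc
        end = pos + 2 + natoms + 1  # title + count + atoms + box
        if end > len(lines):
            raise ParseError(f"truncated GRO frame starting at line {pos + 1}")
        chunks.append("\n".join(lines[pos:end]) + "\n")
        pos = end
    if not chunks:
        raise ParseError("empty GRO file")
    return chunks


def read_trajectory(
    path: str | Path,
    format: str,
    topology: Structure,
) -> Trajectory:
    """Read a multi-frame coordinate file against a known topology.

    Supported formats: ``"multi-pdb"`` (MODEL records), ``"multi-gro"``
    (concatenated frames), ``"xyz"``.  Frames are returned in file order, nm.
    """
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    n = topology.n_particles
    mda = _import_mda()
    frames: list[np.ndarray] = []
    if format == "multi-pdb":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(str(path), format="pdb")
        except Exception as exc:
            raise ParseError(f"{path}: could not parse as multi-model PDB: {exc}") from exc
        if len(u.atoms) != n:
            raise DataError(
                f"frame 0: file has {len(u.atoms)} particles, topology has {n}"
            )
        for i, ts in enumerate(u.trajectory):
            frames.append(ts.positions.astype(float) * _NM_PER_ANGSTROM)
    elif format == "multi-gro":
        chunks = _split_gro_frames(path.read_text())
        from MDAnalysis.lib.util import NamedStream

        for i, chunk in enumerate(chunks):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stream = NamedStream(io.StringIO(chunk), "frame.gro")
                    u = mda.Universe(stream, format="gro")
            except Exception as exc:
                raise ParseError(f"{path}: frame {i}: {exc}") from exc
            if len(u.atoms) != n:
                raise DataError(
                    f"frame {i}: file has {len(u.atoms)} particles, topology has {n}"
                )
            frames.append(u.atoms.positions.astype(float) * _NM_PER_ANGSTROM)
    elif format == "xyz":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reader = mda.coordinates.XYZ.XYZReader(str(path))
        except Exception as exc:
            raise ParseError(f"{path}: could not parse as XYZ: {exc}") from exc
        if reader.n_atoms != n:
            raise DataError(
                f"frame 0: file has {reader.n_atoms} particles, topology has {n}"
            )
        try:
            for i, ts in enumerate(reader):
                frames.append(ts.positions.astype(float) * _NM_PER_ANGSTROM)
        except Exception as exc:
            raise DataError(f"{path}: frame {len(frames)}: {exc}") from exc
    else:
        raise UsageError(
            f"unknown trajectory format {format!r} (expected 'multi-pdb', 'multi-gro' or 'xyz')"
        )
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(traj: Trajectory, path: str | Path, format: str) -> None:
    """Write a trajectory as multi-model PDB, concatenated GRO, or XYZ."""
    path = Path(path)
    mda = _import_mda()
    if format == "multi-pdb":
        u = _structure_to_universe(traj.topology, traj.frames[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=traj.topology.n_particles, multiframe=True) as w:
                for frame in traj.frames:
                    u.atoms.positions = frame / _NM_PER_ANGSTROM
                    w.write(u.atoms)
    elif format == "xyz":
        u = _structure_to_universe(traj.topology, traj.frames[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=traj.topology.n_particles, format="xyz") as w:
                for frame in traj.frames:
                    u.atoms.positions = frame / _NM_PER_ANGSTROM
                    w.write(u.atoms)
    elif format == "multi-gro":
        import tempfile

        parts = []
        with tempfile.TemporaryDirectory() as tmp:
            tmp_file = Path(tmp) / "frame.gro"
            for frame in traj.frames:
                u = _structure_to_universe(traj.topology, frame)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    u.atoms.write(str(tmp_file))
                parts.append(tmp_file.read_text())
        path.write_text("".join(parts))
    else:
        raise UsageError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Height-field TSV dialect
# ---------------------------------------------------------------------------


def read_heightfield(path: str | Path) -> HeightField:
    """Read the package's height-field TSV dialect.

    The first two lines are ``# pixel_size_nm=<x>`` and
    ``# origin_nm=<x> <y>``; the rest is a tab-separated numeric matrix.
    """
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    header = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line.lstrip("# ").partition("=")
        header[key.strip()] = value.strip()
    else:
        raise ParseError(f"{path}: no data rows")
    if "pixel_size_nm" not in header:
        raise ParseError(f"{path}: missing '# pixel_size_nm=' header line")
    try:
        pixel_size = float(header["pixel_size_nm"])
        origin = np.array(
            [float(v) for v in header.get("origin_nm", "0 0").split()], dtype=float
        )
    except ValueError as exc:
        raise ParseError(f"{path}: malformed header: {exc}") from exc
    rows = []
    width = None
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        try:
            row = [float(v) for v in line.split("\t")]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value") from exc
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ParseError(
                f"{path}: line {lineno}: row has {len(row)} columns, expected {width}"
            )
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return HeightField(np.array(rows, dtype=float), pixel_size, origin)


def write_heightfield(field: HeightField, path: str | Path, precision: int = 6) -> None:
    """Write a height field in the TSV dialect read by :func:`read_heightfield`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# pixel_size_nm={float(field.pixel_size)!r}\n")
        fh.write(f"# origin_nm={float(field.origin[0])!r} {float(field.origin[1])!r}\n")
        np.savetxt(fh, field.heights, fmt=f"%.{precision}f", delimiter="\t")
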