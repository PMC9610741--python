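"""End-to-end orchestration of the MD and AFM analysis branches.

The MD branch takes (or synthesizes) a set of independent binding
trajectories and reduces them to binding modes: contact profiles and
altitude distributions per trajectory, fingerprint clustering, per-mode
stable residue sets, mode-region adjacency, occupancy-based Boltzmann
energies and the allowed transition path.  The AFM branch pools globule
altitudes over a batch of height fields, deconvolves them into K Gaussian
populations and derives the same energy diagram.

Reports carry full provenance (config echo, seeds, thresholds) because the
analysis thresholds — stable-contact fraction, altitude reference — are
choices that must be auditable.  Given (config, seed) the reports are
byte-identical across reruns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .afm import analyze_fields
from .altitude import AltitudeConfig, altitude_distribution
from .contacts import ContactConfig, contact_profile, landing_frame
from .energetics import DEFAULT_TEMPERATURE_K, boltzmann_energies, transition_path
from .errors import UsageError
from .modes import cluster_orientations, fingerprint, region_overlap
from .structio import read_heightfield, read_structure, read_trajectory
from .synthetic_data import (
    DEFAULT_START_TO_MODE,
    default_mixture_spec,
    default_mode_spec,
    make_bilayer_patch,
    make_toy_protein,
    simulate_afm_batch,
    simulate_binding_trajectory,
)


@dataclass
class RunConfig:
    """Analysis configuration (see ``RunConfig.from_yaml`` for the file form).

    ``md`` and ``afm`` are nested parameter blocks; each either names input
    files or a ``simulate`` block with generator parameters.
    """

    seed: int = 0
    outdir: str | None = None
    md: dict = dc_field(default_factory=dict)
    afm: dict = dc_field(default_factory=dict)
    contact: dict = dc_field(default_factory=dict)
    altitude: dict = dc_field(default_factory=dict)
    cluster: dict = dc_field(default_factory=dict)
    energy: dict = dc_field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise UsageError(f"no such config file: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise UsageError(f"{path}: config must be a mapping")
        cfg = cls.from_dict(data)
        cfg._check_paths()
        return cfg

    def _check_paths(self) -> None:
        for block in (self.md, self.afm):
            for item in block.get("paths", []):
                p = item["path"] if isinstance(item, dict) else item
                if not Path(p).exists():
                    raise UsageError(f"referenced path does not exist: {p}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_report(report: dict, outdir: str | None, name: str) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / name).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def _simulate_md_inputs(config: RunConfig):
    sim = config.md.get("simulate", {})
    n_frames = int(sim.get("n_frames", 200))
    n_residues = int(sim.get("n_residues", 134))
    start_to_mode = {
        int(k): int(v) for k, v in sim.get("start_to_mode", DEFAULT_START_TO_MODE).items()
    }
    protein = make_toy_protein(n_residues, seed=config.seed)
    bilayer = make_bilayer_patch(
        nx=int(sim.get("nx", 15)), ny=int(sim.get("ny", 15)), seed=config.seed + 1
    )
    trajectories = []
    for start, mode_label in sorted(start_to_mode.items()):
        spec = default_mode_spec(mode_label)
        traj = simulate_binding_trajectory(
            protein, bilayer, spec, n_frames, seed=config.seed + 101 * start
        )
        trajectories.append((f"start{start}", traj))
    return trajectories


def _load_md_inputs(config: RunConfig):
    trajectories = []
    for item in config.md["paths"]:
        topo = read_structure(item["topology"])
        traj = read_trajectory(item["path"], item.get("format", "multi-pdb"), topo)
        trajectories.append((str(item.get("id", Path(item["path"]).stem)), traj))
    return trajectories


def run_md_branch(config: RunConfig) -> dict:
    """Contact / mode / altitude / energetics analysis of >= 1 trajectory."""
    collected_warnings: list[str] = []
    if "paths" in config.md:
        trajectories = _load_md_inputs(config)
    else:
        trajectories = _simulate_md_inputs(config)
    if not trajectories:
        raise UsageError("MD branch requires at least one trajectory")

    contact_cfg = ContactConfig(**config.contact)
    alt_cfg = AltitudeConfig(**config.altitude)
    persistence = int(config.md.get("persistence", 5))

    fingerprints = []
    per_traj = {}
    for tid, traj in trajectories:
        land = landing_frame(traj, contact_cfg, persistence=persistence)
        if land is None:
            collected_warnings.append(f"{tid}: protein never landed; using all frames")
            window = None
        else:
            window = (land + persistence, None)
        profile = contact_profile(traj, contact_cfg, frame_range=window)
        alt = altitude_distribution(traj, alt_cfg, frame_range=window)
        fp = fingerprint(profile, mean_altitude=alt.mean, trajectory_id=tid)
        fingerprints.append(fp)
        per_traj[tid] = {
            "landing_frame": land,
            "n_frames_analyzed": profile.n_frames,
            "mean_contacts_per_frame": profile.mean_contacts_per_frame,
            "stable_residues": sorted(profile.stable_residues),
            "altitude_mean_nm": alt.mean,
            "altitude_sd_nm": alt.sd,
        }

    assignment = cluster_orientations(
        fingerprints,
        threshold=float(config.cluster.get("threshold", 0.5)),
        metric=str(config.cluster.get("metric", "jaccard")),
    )

    structure = trajectories[0][1].topology
    overlap = {}
    path = None
    energies = None
    if assignment.n_modes >= 2:
        adjacency = {}
        for i in range(1, assignment.n_modes + 1):
            for j in range(i + 1, assignment.n_modes + 1):
                kind = region_overlap(
                    assignment.mode_stable_residues[i],
                    assignment.mode_stable_residues[j],
                    structure,
                    neighbor_cutoff_nm=float(config.cluster.get("neighbor_cutoff_nm", 0.8)),
                )
                adjacency[(i, j)] = kind
                overlap[f"{i}-{j}"] = kind
        counts = np.array(
            [len(assignment.mode_members[m]) for m in range(1, assignment.n_modes + 1)],
            dtype=float,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diagram = boltzmann_energies(
                counts / counts.sum(),
                temperature_K=float(config.energy.get("temperature_K", DEFAULT_TEMPERATURE_K)),
            )
        energies = {
            "temperature_K": diagram.temperature_K,
            "populations": diagram.populations,
            "energies_kJmol": diagram.energies_kJmol,
            "energies_kT": diagram.energies_kT,
        }
        path = transition_path(diagram, adjacency)
        if path is None:
            collected_warnings.append("mode graph disconnected; no transition path")

    report = {
        "branch": "md",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "contact": {"cutoff_nm": contact_cfg.cutoff_nm,
                        "periodic": contact_cfg.periodic,
                        "stable_fraction": contact_cfg.stable_fraction},
            "altitude": {"reference": alt_cfg.reference, "leaflet": alt_cfg.leaflet},
            "cluster": dict(config.cluster),
            "persistence": persistence,
        },
        "trajectories": per_traj,
        "labels": assignment.labels,
        "n_modes": assignment.n_modes,
        "modes": {
            str(m): {
                "members": assignment.mode_members[m],
                "stable_residues": sorted(assignment.mode_stable_residues[m]),
                "mean_contacts_per_frame": assignment.mode_intensity[m],
                "altitude_mean_nm": assignment.mode_altitude[m],
            }
            for m in range(1, assignment.n_modes + 1)
        },
        "region_overlap": overlap,
        "energetics": energies,
        "transition_path": path,
        "warnings": collected_warnings,
    }
    _write_report(report, config.outdir, "md_report.json")
    if config.outdir is not None:
        out = Path(config.outdir)
        rows = []
        for fp in fingerprints:
            for r, f in zip(fp.residues, fp.fractions):
                rows.append({"trajectory": fp.trajectory_id, "residue": int(r),
                             "contact_fraction": float(f)})
        pd.DataFrame(rows).to_csv(out / "contact_fractions.tsv", sep="\t", index=False)
    return report


def run_afm_branch(config: RunConfig) -> dict:
    """Globule detection + mixture deconvolution + energetics on height fields."""
    collected_warnings: list[str] = []
    if "paths" in config.afm:
        fields = [read_heightfield(p) for p in config.afm["paths"]]
    else:
        sim = config.afm.get("simulate", {})
        spec = default_mixture_spec(float(sim.get("sd_nm", 0.15)))
        fields, _truth = simulate_afm_batch(
            spec,
            n_particles_total=int(sim.get("n_particles", 600)),
            n_fields=int(sim.get("n_fields", 8)),
            seed=config.seed,
            field_nm=float(sim.get("field_nm", 400.0)),
            noise_sd_nm=float(sim.get("noise_sd_nm", 0.05)),
        )
    k = int(config.afm.get("K", 3))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        measurements, fit = analyze_fields(
            fields,
            K=k,
            min_altitude_nm=float(config.afm.get("min_altitude_nm", 0.5)),
            min_separation_nm=float(config.afm.get("min_separation_nm", 4.0)),
            n_restarts=int(config.afm.get("n_restarts", 10)),
            seed=config.seed,
        )
    collected_warnings.extend(str(w.message) for w in caught)

    energies = None
    fit_block = None
    if fit is not None:
        fit_block = {
            "K": fit.K,
            "means_nm": fit.means_nm,
            "sds_nm": fit.sds_nm,
            "weights": fit.weights,
            "log_likelihood": fit.log_likelihood,
            "converged": fit.converged,
            "n_samples": fit.n_samples,
        }
        diagram = boltzmann_energies(
            fit.weights,
            temperature_K=float(config.energy.get("temperature_K", DEFAULT_TEMPERATURE_K)),
        )
        energies = {
            "temperature_K": diagram.temperature_K,
            "populations": diagram.populations,
            "energies_kJmol": diagram.energies_kJmol,
            "energies_kT": diagram.energies_kT,
        }
    if not measurements:
        collected_warnings.append("no particles detected in any field")

    report = {
        "branch": "afm",
        "version": __version__,
        "seed": config.seed,
        "config": {k2: v for k2, v in config.afm.items() if k2 != "paths"},
        "n_fields": len(fields),
        "n_particles": len(measurements),
        "altitudes_nm": [m.peak_altitude_nm for m in measurements],
        "mixture_fit": fit_block,
        "energetics": energies,
        "warnings": collected_warnings,
    }
    _write_report(report, config.outdir, "afm_report.json")
    if config.outdir is not None and measurements:
        pd.DataFrame(
            {
                "x_nm": [m.position[0] for m in measurements],
                "y_nm": [m.position[1] for m in measurements],
                "peak_altitude_nm": [m.peak_altitude_nm for m in measurements],
                "footprint_px": [m.footprint_px for m in measurements],
            }
        ).to_csv(Path(config.outdir) / "afm_particles.tsv", sep="\t", index=False)
    return report
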