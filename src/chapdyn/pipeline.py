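"""Pipeline orchestration: run all analysis stages from a single config.

The config is a flat key-value INI file with sections ``[inputs]``,
``[selections]``, ``[stages]``, ``[parameters]``, ``[output]`` (see
``chapdyn.synthetic.write_scene`` for a complete example).  ``run``
executes the requested stages in dependency order (io -> energetics /
gbsa / fluctuations / cavity / comparative), writes a manifest (inputs
hashed, package version, seed, parameters) and a single JSON summary.
Stage failures are recorded in the manifest; independent stages continue.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chapdyn import __version__
from chapdyn.cavity import (
    luminal_cavity,
    make_cavity_grids,
    occupancy_fraction,
    write_cavity_pdb,
)
from chapdyn.comparative import protomer_asymmetry, segment_descriptors
from chapdyn.core_io import read_frames, read_structure, write_structure
from chapdyn.fluctuations import fit_frames, normalize_bfactors, pca, rmsf
from chapdyn.gbsa import GBParams, mmgbsa_binding
from chapdyn.pair_energetics import (
    aggregate_replicas,
    export_heatmap_table,
    rank_and_partition,
    residue_pair_matrix,
    EnergyMatrix,
)
from chapdyn.params import load_parameters
from chapdyn.selection import apply_selection, parse_selection

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "validate", "run"]

STAGES = ("decompose", "gbsa", "fluct", "pca", "cavity", "compare")


@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    base_dir: Path
    inputs: dict = field(default_factory=dict)
    selections: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    out_dir: Path = Path("out")

    def input_path(self, key: str) -> Path | None:
        if key not in self.inputs:
            return None
        p = Path(self.inputs[key])
        return p if p.is_absolute() else self.base_dir / p

    def param(self, key: str, default, cast=float):
        return cast(self.parameters.get(key, default))


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise FileNotFoundError(f"config file {path} not found or unreadable")
    cfg = RunConfig(base_dir=path.parent)
    cfg.inputs = dict(cp["inputs"]) if cp.has_section("inputs") else {}
    cfg.selections = dict(cp["selections"]) if cp.has_section("selections") else {}
    if cp.has_section("stages"):
        cfg.stages = {k: cp.getboolean("stages", k) for k in cp["stages"]}
    cfg.parameters = dict(cp["parameters"]) if cp.has_section("parameters") else {}
    out = cp.get("output", "dir", fallback="out")
    out_path = Path(out)
    cfg.out_dir = out_path if out_path.is_absolute() else cfg.base_dir / out_path
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate(config: RunConfig) -> list[dict]:
    """Config diagnostics: missing files, unresolvable or empty selections,
    missing parameter rows.  Error-level findings make ``chapdyn validate``
    exit nonzero."""
    diags: list[dict] = []
    structure = None
    for key in config.inputs:
        p = config.input_path(key)
        if not p.exists():
            diags.append({"level": "error", "message": f"input {key!r}: file {p} does not exist"})
    sp = config.input_path("structure")
    if sp is not None and sp.exists():
        try:
            structure, _ = read_structure(sp)
        except ValueError as exc:
            diags.append({"level": "error", "message": f"structure: {exc}"})
    for name, expr in config.selections.items():
        try:
            sel = parse_selection(expr)
        except ValueError as exc:
            diags.append({"level": "error", "message": f"selection {name!r}: {exc}"})
            continue
        if structure is not None:
            import warnings as _warnings

            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                idx = sel.indices(structure)
            for w in caught:
                diags.append({"level": "warning", "message": f"selection {name!r}: {w.message}"})
            if idx.size == 0:
                diags.append({"level": "warning", "message": f"selection {name!r} matches no atoms"})
    pp = config.input_path("parameters")
    if structure is not None and pp is not None and pp.exists():
        try:
            load_parameters(structure, pp, config.input_path("bonds"))
        except ValueError as exc:
            diags.append({"level": "error", "message": f"parameters: {exc}"})
    return diags


def _read_region_map(path: Path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["residue"], df["label"]))


def _matrix_to_json(mat: np.ndarray) -> list:
    return np.asarray(mat).round(6).tolist()


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dict.

    Writes ``manifest.json``, ``summary.json`` and per-stage artifacts
    under the configured output directory.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seed = config.param("seed", 0, int)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": dict(config.parameters),
        "selections": dict(config.selections),
        "inputs": {},
        "stages": {},
    }
    for key in config.inputs:
        p = config.input_path(key)
        if p.exists():
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
    summary: dict = {"seed": seed}

    structure = trajectory = system = None
    region_map: dict = {}
    try:
        structure, traj_from_pdb = read_structure(config.input_path("structure"))
        fp = config.input_path("frames")
        trajectory = read_frames(fp, structure) if fp else traj_from_pdb
        pp = config.input_path("parameters")
        if pp is not None:
            system = load_parameters(structure, pp, config.input_path("bonds"))
        rp = config.input_path("regions")
        if rp is not None:
            region_map = _read_region_map(rp)
        manifest["stages"]["io"] = {"status": "ok", "n_atoms": structure.n_atoms,
                                    "n_frames": trajectory.n_frames if trajectory else 0}
    except Exception as exc:  # noqa: BLE001 - io failure recorded, nothing else can run
        manifest["stages"]["io"] = {"status": "error", "message": str(exc)}
        _write_reports(out, manifest, summary)
        return summary

    def sel(name: str) -> np.ndarray:
        return apply_selection(structure, config.selections[name])

    enabled = {s: config.stages.get(s, False) for s in STAGES}

    if enabled["decompose"]:
        try:
            walls, client = sel("walls"), sel("client")
            per_replica = [
                residue_pair_matrix(system, trajectory, walls, client,
                                    frame_indices=trajectory.frames_of_replica(r))
                for r in trajectory.replicas
            ]
            stats = aggregate_replicas(per_replica)
            mean_matrix = EnergyMatrix(rows=stats.rows, cols=stats.cols,
                                       coulomb=stats.mean["coulomb"], vdw=stats.mean["vdw"])
            k = config.param("top_k", 5, int)
            report = rank_and_partition(mean_matrix, k, region_map)
            for comp in ("coulomb", "vdw", "total"):
                export_heatmap_table(mean_matrix, out / f"pair_energy_{comp}.tsv",
                                     clip=config.param("clip", 1.0), component=comp)
            summary["decompose"] = {
                "top_pairs": report.top_pairs,
                "block_sums": {c: report.block_sums[c].to_dict() for c in report.block_sums},
                "protomer_asymmetry_total": report.asymmetry("protomerA", "protomerB"),
                "n_replicas": stats.n_replicas,
                "sem_max": None if stats.sem is None else float(np.max(stats.sem["total"])),
            }
            manifest["stages"]["decompose"] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["decompose"] = {"status": "error", "message": str(exc)}

    if enabled["gbsa"]:
        try:
            walls, client = sel("walls"), sel("client")
            max_frames = config.param("gbsa_max_frames", 2, int)
            frames = []
            for r in trajectory.replicas:
                frames.extend(trajectory.frames_of_replica(r)[:max_frames].tolist())
            gb_params = GBParams(n_sphere_points=config.param("sphere_points", 960, int))
            report = mmgbsa_binding(system, trajectory, walls, client,
                                    gb_params, frame_indices=frames)
            report.per_frame.to_csv(out / "mmgbsa_per_frame.csv", index=False)
            summary["gbsa"] = report.summary
            manifest["stages"]["gbsa"] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["gbsa"] = {"status": "error", "message": str(exc)}

    aligned = None
    if enabled["fluct"] or enabled["pca"]:
        try:
            fit_sel = sel("fit") if "fit" in config.selections else None
            aligned = fit_frames(trajectory, fit_sel)
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["fit"] = {"status": "error", "message": str(exc)}

    if enabled["fluct"] and aligned is not None:
        try:
            profile = normalize_bfactors([rmsf(aligned)])[0]
            df = pd.DataFrame({"atom": profile.labels, "rmsf_A": profile.rmsf,
                               "B_raw_A2": profile.b_raw, "B_norm": profile.b_norm})
            df.to_csv(out / "rmsf_bfactors.tsv", sep="\t", index=False, float_format="%.4f")
            write_structure(structure, out / "structure_bnorm.pdb", profile.b_norm)
            summary["fluct"] = {
                "rmsf_mean_A": float(profile.rmsf.mean()),
                "rmsf_max_A": float(profile.rmsf.max()),
                "b_raw_max_A2": float(profile.b_raw.max()),
            }
            manifest["stages"]["fluct"] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["fluct"] = {"status": "error", "message": str(exc)}

    if enabled["pca"] and aligned is not None:
        try:
            ca = apply_selection(structure, "name CA")
            modes = pca(aligned, ca if ca.size else None, n_modes=config.param("n_modes", 5, int))
            spectrum = {
                "eigenvalues_A2": modes.eigenvalues.tolist(),
                "variance_fractions": modes.variance_fractions.tolist(),
            }
            (out / "pca_spectrum.json").write_text(json.dumps(spectrum, indent=2))
            summary["pca"] = {
                "pc1_variance_fraction": float(modes.variance_fractions[0]) if modes.n_modes else None,
                "n_modes": modes.n_modes,
            }
            manifest["stages"]["pca"] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["pca"] = {"status": "error", "message": str(exc)}

    if enabled["cavity"]:
        try:
            walls, client = sel("walls"), sel("client")
            h = config.param("grid_spacing", 0.5)
            probe = config.param("probe_radius", 1.4)
            radii = system.rmin_half()[walls] if system is not None else None
            grids = make_cavity_grids(structure, walls, h, probe, radii)
            seed_pt_cfg = config.parameters.get("cavity_seed", "auto")
            if seed_pt_cfg == "auto":
                lum = sel("luminal") if "luminal" in config.selections else client
                seed_pt = structure.coords[lum].mean(axis=0)
            else:
                seed_pt = np.array([float(v) for v in seed_pt_cfg.split(",")])
            result = luminal_cavity(*grids, seed_pt)
            client_radii = system.rmin_half()[client] if system is not None else None
            occupancy_fraction(result, structure, client, client_radii)
            write_cavity_pdb(result, out / "cavity_voxels.pdb")
            summary["cavity"] = {
                "cavity_volume_A3": result.cavity_volume,
                "client_volume_A3": result.client_volume,
                "occupancy": result.occupancy,
                "seed_point": result.seed_point.round(3).tolist(),
            }
            manifest["stages"]["cavity"] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["cavity"] = {"status": "error", "message": str(exc)}

    if enabled["compare"]:
        try:
            chain_a = config.selections.get("protomer_a", "chain A").split()[-1]
            chain_b = config.selections.get("protomer_b", "chain B").split()[-1]
            sup, aln = protomer_asymmetry(structure, chain_a, chain_b)
            comp = {
                "protomer_rmsd_A": sup.rmsd,
                "n_matched": sup.n_matched,
                "percent_identity": aln.percent_identity,
                "percent_similarity": aln.percent_similarity,
                "max_pair_deviation_A": float(sup.per_pair_deviation.max()),
            }
            client_chain = config.selections.get("client", "chain C").split()[-1]
            seq = structure.chain_sequence(client_chain)
            if seq and all(c in "ACDEFGHIKLMNPQRSTVWY" for c in seq):
                d = segment_descriptors(seq)
                comp["client_descriptors"] = {
                    "sequence": d.sequence, "gravy": d.gravy,
                    "percent_hydrophobic": d.percent_hydrophobic,
                    "isoelectric_point": d.isoelectric_point,
                }
            summary["compare"] = comp
            manifest["stages"]["compare"] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["compare"] = {"status": "error", "message": str(exc)}

    _write_reports(out, manifest, summary)
    return summary


def _write_reports(out: Path, manifest: dict, summary: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
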