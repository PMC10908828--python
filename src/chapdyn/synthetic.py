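"""Synthetic-data generators.

Every analysis stage of the package can be exercised without downloads:

- parameterized toy complexes (chains of pseudo-residues with a known
  charge pattern and a single Lennard-Jones class, so oracles stay
  hand-computable),
- multi-replica Gaussian trajectories with planted fluctuation modes,
- cavity phantoms (a rectangular pseudo-atom shell around a void of known
  analytic volume, optionally holding a client of known volume),
- a threaded-dimer end-to-end scene: two C2-symmetric protomer walls with
  a sealed interfacial channel, a 9-residue client peptide threaded
  through it, and charges/LJ classes placed to create one known strongest
  coulombic pair and one known strongest van der Waals pair.

All generators are bit-deterministic under their seed; replica seeds are
``master_seed + replica_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chapdyn.core_io import (
    AtomRecord,
    MolecularStructure,
    Trajectory,
    write_frames,
    write_structure,
)
from chapdyn.params import ParameterizedSystem, load_parameters

__all__ = [
    "LJ_CLASS",
    "ToyComplexSpec",
    "PlantedModeSpec",
    "ThreadedDimerScene",
    "make_toy_complex",
    "make_ion_pair",
    "make_gaussian_trajectory",
    "make_cavity_phantom",
    "spheres_on_line_volume",
    "make_threaded_dimer",
    "write_toy_complex",
    "write_scene",
]

# the single pseudo-atom LJ class: sigma (A), epsilon (kcal/mol),
# intrinsic Born radius (A), GB screening factor
LJ_CLASS = {"sigma_A": 3.4, "epsilon_kcal": 0.1, "born_radius_A": 1.7, "gb_screen": 0.8}


def _param_row(res_name: str, charge: float = 0.0, epsilon: float | None = None) -> dict:
    row = {"res_name": res_name, "atom_name": "CA", "charge_e": charge}
    row.update(LJ_CLASS)
    if epsilon is not None:
        row["epsilon_kcal"] = epsilon
    return row


def _atom(serial, chain, res_seq, xyz, res_name="GLY", name="CA") -> AtomRecord:
    return AtomRecord(
        serial=serial, name=name, res_name=res_name, chain_id=chain,
        res_seq=res_seq, xyz=np.asarray(xyz, dtype=float), element="C",
    )


@dataclass
class ToyComplexSpec:
    """Recipe for a small parameterized multi-chain complex.

    ``charge_pattern``: 'zero', 'alternating' (+q/-q along each chain) or
    'ion-pair' (two single-atom chains, +1 and -1, ``separation`` apart).
    """

    n_chains: int = 2
    residues_per_chain: int = 5
    geometry: str = "slab"  # 'slab' (straight strands) or 'helix'
    charge_pattern: str = "zero"
    charge_magnitude: float = 0.2
    spacing: float = 3.8  # A between consecutive residues
    chain_gap: float = 8.0  # A between chains
    separation: float = 3.320637  # A, ion-pair distance
    seed: int = 0


def make_toy_complex(spec: ToyComplexSpec) -> tuple[MolecularStructure, pd.DataFrame]:
    """Build (structure, parameter table) from a spec, deterministically.

    Chains are labelled A, B, ...; the first chain is the designated
    'receptor' and the last the 'ligand' for binding-energy tests.
    """
    if spec.charge_pattern == "ion-pair":
        atoms = [
            _atom(1, "A", 1, (0.0, 0.0, 0.0), "POS"),
            _atom(2, "B", 1, (spec.separation, 0.0, 0.0), "NEG"),
        ]
        table = pd.DataFrame([_param_row("POS", +1.0), _param_row("NEG", -1.0)])
        return MolecularStructure(atoms), table

    atoms = []
    serial = 1
    res_names = set()
    for c in range(spec.n_chains):
        chain = chr(ord("A") + c)
        for r in range(spec.residues_per_chain):
            if spec.geometry == "helix":
                ang = 2.0 * np.pi * r / 3.6
                xyz = (2.3 * np.cos(ang), 2.3 * np.sin(ang) + c * spec.chain_gap, 1.5 * r)
            else:
                xyz = (r * spec.spacing, c * spec.chain_gap, 0.0)
            if spec.charge_pattern == "alternating":
                sign = 1 if r % 2 == 0 else -1
                res_name = "POS" if sign > 0 else "NEG"
            else:
                res_name = "GLY"
            res_names.add(res_name)
            atoms.append(_atom(serial, chain, r + 1, xyz, res_name))
            serial += 1
    rows = []
    for rn in sorted(res_names):
        q = {"POS": spec.charge_magnitude, "NEG": -spec.charge_magnitude}.get(rn, 0.0)
        rows.append(_param_row(rn, q))
    return MolecularStructure(atoms), pd.DataFrame(rows)


def make_ion_pair(separation: float = 3.320637) -> tuple[MolecularStructure, pd.DataFrame]:
    """A +1/-1 pseudo-atom pair at the given separation (A)."""
    return make_toy_complex(ToyComplexSpec(charge_pattern="ion-pair", separation=separation))


@dataclass
class PlantedModeSpec:
    """Gaussian trajectory recipe: frames are the base structure displaced
    along orthonormalized planted 3N directions with normal amplitudes
    sigma_k, plus isotropic noise sigma_0."""

    directions: list = field(default_factory=list)  # each a (3N,) array
    amplitudes: list = field(default_factory=list)  # sigma_k, A
    noise_sigma: float = 0.0  # sigma_0, A per coordinate
    n_frames: int = 100  # per replica
    n_replicas: int = 1
    seed: int = 0


def _orthonormalize(directions: list, dim: int) -> np.ndarray:
    if not directions:
        return np.zeros((0, dim))
    mat = np.array([np.asarray(d, dtype=float) for d in directions])
    if mat.shape[1] != dim:
        raise ValueError(f"planted directions must have dimension {dim}")
    q, _ = np.linalg.qr(mat.T)
    return q.T[: len(directions)]


def make_gaussian_trajectory(
    structure: MolecularStructure, spec: PlantedModeSpec
) -> Trajectory:
    """Multi-replica trajectory with planted Gaussian fluctuation modes.

    frame = base + sum_k eta_k sigma_k d_k + isotropic noise, with
    eta ~ N(0, 1); replica r uses rng seed ``spec.seed + r``.
    """
    base = structure.coords.reshape(-1)
    dim = base.size
    dirs = _orthonormalize(spec.directions, dim)
    sigmas = np.asarray(spec.amplitudes, dtype=float)
    if len(sigmas) != len(dirs):
        raise ValueError("one amplitude per planted direction required")
    if np.any(sigmas <= 0) and len(sigmas):
        raise ValueError("planted amplitudes must be > 0")
    frames = []
    replica_ids = []
    for rep in range(spec.n_replicas):
        rng = np.random.default_rng(spec.seed + rep)
        eta = rng.standard_normal((spec.n_frames, len(dirs)))
        block = base[None, :] + (eta * sigmas[None, :]) @ dirs if len(dirs) else np.tile(base, (spec.n_frames, 1))
        if spec.noise_sigma > 0:
            block = block + spec.noise_sigma * rng.standard_normal(block.shape)
        frames.append(block)
        replica_ids.extend([rep] * spec.n_frames)
    coords = np.concatenate(frames).reshape(-1, dim // 3, 3)
    return Trajectory(coords=coords, template=structure, replica_ids=np.array(replica_ids))


def _sym_grid(limit: float, spacing: float) -> np.ndarray:
    """Odd multiples of spacing/2 within [-limit, limit] (no point at 0)."""
    m = int(np.floor(limit / spacing + 0.5))
    return (np.arange(-m, m) + 0.5) * spacing


def _shell_lattice(void_half: np.ndarray, radius: float, thickness: float, spacing: float):
    """Pseudo-atom positions forming a sealed box shell around the void.

    Each face is a slab of lattice planes whose innermost plane sits
    exactly at ``void_half + radius``, so the atoms' vdW surfaces graze
    the requested void boundary and the realized void volume equals the
    nominal one (up to the inter-atom scallop, O(spacing^2/radius)).
    Tangential positions are odd multiples of spacing/2, so the point set
    is symmetric under coordinate negation and no atom lies on a mirror
    plane.
    """
    inner = void_half + radius
    outer = inner + thickness
    n_layers = max(1, int(np.ceil(thickness / spacing)))
    pts = set()
    for d in range(3):
        e, f = [a for a in range(3) if a != d]
        grid_e = _sym_grid(outer[e], spacing)
        grid_f = _sym_grid(outer[f], spacing)
        for j in range(n_layers):
            for sign in (1.0, -1.0):
                c = sign * (inner[d] + j * spacing)
                for ve in grid_e:
                    for vf in grid_f:
                        p = [0.0, 0.0, 0.0]
                        p[d], p[e], p[f] = c, ve, vf
                        pts.add((round(p[0], 6), round(p[1], 6), round(p[2], 6)))
    return np.array(sorted(pts))


def make_cavity_phantom(
    void_dims: tuple = (10.0, 10.0, 10.0),
    wall_thickness: float = 1.2,
    atom_spacing: float = 0.6,
    radius: float = 1.7,
    client_volume: float | None = None,
    solid: bool = False,
) -> tuple[MolecularStructure, dict]:
    """Rectangular pseudo-atom shell enclosing a void of known volume.

    Returns (structure, ground_truth); chains: W = wall, C = optional
    client (a single pseudo-atom at the center whose vdW sphere has the
    requested ``client_volume``).  ``solid=True`` fills the whole box
    instead (no cavity).  Raises on wall specs that would leak.
    """
    if atom_spacing >= np.sqrt(2.0) * radius:
        raise ValueError("leaky wall: atom_spacing must be < sqrt(2) * radius to seal the shell")
    if wall_thickness < atom_spacing:
        raise ValueError("leaky wall: wall_thickness must cover at least one atom layer")
    void_half = np.asarray(void_dims, dtype=float) / 2.0
    if solid:
        void_half = np.zeros(3)
    pts = _shell_lattice(void_half, radius, wall_thickness, atom_spacing)
    atoms = [
        _atom(i + 1, "W", i + 1, p, "WAL") for i, p in enumerate(pts)
    ]
    truth = {
        "void_volume_A3": float(np.prod(2.0 * void_half)),
        "n_wall_atoms": len(atoms),
        "wall_radius_A": radius,
    }
    if client_volume is not None:
        r_client = (3.0 * client_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        serial = len(atoms) + 1
        atoms.append(_atom(serial, "C", 1, (0.0, 0.0, 0.0), "CLI"))
        truth["client_volume_A3"] = float(client_volume)
        truth["client_radius_A"] = float(r_client)
        truth["occupancy"] = float(client_volume / truth["void_volume_A3"]) if not solid else 0.0
    return MolecularStructure(atoms), truth


def spheres_on_line_volume(centers_x: np.ndarray, radius: float, dx: float = 1e-3) -> float:
    """Volume of a union of equal spheres with collinear centers.

    The cross-section at x is a disk of squared radius
    ``max_i (r^2 - (x - x_i)^2)``; integrating it in 1D gives the union
    volume without inclusion-exclusion.  Serves as an independent oracle
    for client volumes of threaded peptides.
    """
    xs = np.asarray(centers_x, dtype=float)
    grid = np.arange(xs.min() - radius, xs.max() + radius + dx, dx)
    r2 = np.max(radius**2 - (grid[:, None] - xs[None, :]) ** 2, axis=1)
    return float(np.pi * np.sum(np.clip(r2, 0.0, None)) * dx)


@dataclass
class ThreadedDimerScene:
    """End-to-end synthetic scene mimicking a client threaded through the
    interfacial channel of a two-protomer chaperone, with documented
    planted ground truths."""

    structure: MolecularStructure
    param_table: pd.DataFrame
    system: ParameterizedSystem
    trajectory: Trajectory
    region_map: dict
    ground_truth: dict
    selections: dict
    seed: int


def make_threaded_dimer(
    seed: int = 0,
    planted: bool = True,
    n_frames: int = 10,
    n_replicas: int = 2,
    jitter_sigma: float = 0.03,
) -> ThreadedDimerScene:
    """Two protomer walls (chains A and B, exact C2 copies about the x
    axis) sealing a 12 x 8 x 8 A channel, with a 9-residue client peptide
    (chain C) threaded along the axis.

    With ``planted=True`` the scene carries a known strongest coulombic
    pair (client POS residue 5 against a -1 wall atom in protomer B) and a
    known strongest van der Waals pair (client residue 9 against a
    high-epsilon wall atom in protomer A).  ``planted=False`` yields the
    neutral control used for binding-energy comparisons.
    """
    void = np.array([12.0, 8.0, 8.0])
    # wall geometry uses the analysis vdW radius (LJ R_min/2 of the single class)
    radius = LJ_CLASS["sigma_A"] * 2.0 ** (1.0 / 6.0) / 2.0
    spacing, thickness = 0.8, 0.8
    pts = _shell_lattice(void / 2.0, radius, thickness, spacing)
    half_a = pts[pts[:, 1] > 0]
    order = np.lexsort((half_a[:, 2], half_a[:, 1], half_a[:, 0]))
    half_a = half_a[order]
    # protomer B is the exact C2 (180 deg about x) image of protomer A
    half_b = half_a * np.array([1.0, -1.0, -1.0])

    # planted special atoms: NEG on the protomer-B floor under the client
    # center, BIG on the protomer-A ceiling over client residue 7
    neg_target = np.array([0.0, -(void[1] / 2.0 + radius), 0.0])
    big_target = np.array([2.2, void[1] / 2.0 + radius, 0.0])
    i_big = int(np.argmin(np.linalg.norm(half_a - big_target, axis=1)))
    i_neg = int(np.argmin(np.linalg.norm(half_b - neg_target, axis=1)))

    atoms = []
    serial = 1
    for c, coords in (("A", half_a), ("B", half_b)):
        for r, p in enumerate(coords):
            res_name = "WAL"
            if planted and c == "A" and r == i_big:
                res_name = "BIG"
            if planted and c == "B" and r == i_neg:
                res_name = "NEG"
            atoms.append(_atom(serial, c, r + 1, p, res_name))
            serial += 1
    client_x = (np.arange(9) - 4) * 1.1
    for r, x in enumerate(client_x):
        res_name = "POS" if (planted and r == 4) else "CLI"
        atoms.append(_atom(serial, "C", r + 1, (x, 0.0, 0.0), res_name))
        serial += 1
    structure = MolecularStructure(atoms)

    table = pd.DataFrame(
        [
            _param_row("WAL"),
            _param_row("CLI"),
            _param_row("BIG", epsilon=16.0),
            _param_row("NEG", charge=-1.0),
            _param_row("POS", charge=+1.0),
        ]
    )
    system = load_parameters(structure, table)

    traj = make_gaussian_trajectory(
        structure,
        PlantedModeSpec(
            directions=[], amplitudes=[], noise_sigma=jitter_sigma,
            n_frames=n_frames, n_replicas=n_replicas, seed=seed,
        ),
    )

    def label(i: int) -> str:
        a = structure.atoms[i]
        return f"{a.chain_id}:{a.res_key}:{a.res_name}"

    region_map = {}
    for i, a in enumerate(structure.atoms):
        if a.chain_id == "A":
            region_map[label(i)] = "protomerA"
        elif a.chain_id == "B":
            region_map[label(i)] = "protomerB"
        else:
            region_map[label(i)] = "luminal"

    n_wall = len(half_a)
    big_atom = i_big
    neg_atom = n_wall + i_neg
    pos_atom = 2 * n_wall + 4  # client residue 5
    vdw_client_atom = 2 * n_wall + 6  # client residue 7, nearest to BIG
    client_union = spheres_on_line_volume(client_x, radius)
    void_volume = float(np.prod(void))
    truth = {
        "planted": planted,
        "cavity_volume_A3": void_volume,
        "cavity_volume_tol": 0.12,  # voxelization + wall-scallop allowance
        "client_volume_A3": client_union,
        "occupancy": client_union / void_volume,
        "occupancy_tol": 0.25,
        "asymmetry_rmsd_A": 0.0,
        "luminal_residues": [label(2 * n_wall + r) for r in range(9)],
        # binding of the client to the walls is favorable overall, and the
        # planted contacts add favorable *direct* (gas-phase) interaction
        # relative to the neutral control; the generalized-Born desolvation
        # penalty of the buried salt bridge is larger than its Coulomb gain,
        # so total dG is deliberately not claimed to be monotone in planting
        "binding_favorable": True,
        "planted_gas_interaction_more_favorable": planted,
    }
    if planted:
        truth["strongest_coulomb_pair"] = sorted([label(neg_atom), label(pos_atom)])
        truth["strongest_vdw_pair"] = sorted([label(big_atom), label(vdw_client_atom)])

    selections = {
        "protomer_a": "chain A",
        "protomer_b": "chain B",
        "client": "chain C",
        "walls": "chain A or chain B",
        "luminal": "chain C",
    }
    return ThreadedDimerScene(
        structure=structure, param_table=table, system=system, trajectory=traj,
        region_map=region_map, ground_truth=truth, selections=selections, seed=seed,
    )


def write_toy_complex(spec: ToyComplexSpec, out_dir: str | Path) -> dict:
    """Write structure.pdb + params.tsv for a toy complex; byte-identical
    for identical specs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure, table = make_toy_complex(spec)
    write_structure(structure, out / "structure.pdb")
    table.to_csv(out / "params.tsv", sep="\t", index=False, float_format="%.6f")
    return {"structure": str(out / "structure.pdb"), "params": str(out / "params.tsv")}


def write_scene(scene: ThreadedDimerScene, out_dir: str | Path) -> dict:
    """Write a threaded-dimer scene as pipeline-ready files: structure.pdb,
    params.tsv, frames.dat, regions.tsv, ground_truth.json, config.ini."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_structure(scene.structure, out / "structure.pdb")
    scene.param_table.to_csv(out / "params.tsv", sep="\t", index=False, float_format="%.6f")
    write_frames(scene.trajectory, out / "frames.dat")
    with open(out / "regions.tsv", "w") as fh:
        fh.write("residue\tlabel\n")
        for res, lab in scene.region_map.items():
            fh.write(f"{res}\t{lab}\n")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(scene.ground_truth, fh, indent=2, sort_keys=True)
    config = f"""[inputs]
structure = structure.pdb
frames = frames.dat
parameters = params.tsv
regions = regions.tsv

[selections]
protomer_a = {scene.selections['protomer_a']}
protomer_b = {scene.selections['protomer_b']}
client = {scene.selections['client']}
walls = {scene.selections['walls']}
luminal = {scene.selections['luminal']}

[stages]
decompose = true
gbsa = true
fluct = true
pca = true
cavity = true
compare = true

[parameters]
seed = {scene.seed}
grid_spacing = 0.5
probe_radius = 1.4
gbsa_max_frames = 2
sphere_points = 240
top_k = 5

[output]
dir = out
"""
    (out / "config.ini").write_text(config)
    return {"dir": str(out)}
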