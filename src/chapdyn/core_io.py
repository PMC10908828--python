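"""Structure, trajectory, sequence, and parameter-file I/O.

Reads and writes fixed-column PDB (v3.3 ATOM/HETATM/MODEL/ENDMDL), a plain
whitespace-delimited frames format for synthetic trajectories, and FASTA
(through Biopython).  Multi-model PDB files double as a trajectory dialect:
frame 1 of the returned trajectory equals the structure's coordinates.

Author (PDB) residue numbering is preserved verbatim; insertion codes are
appended to the residue key as a string suffix so identity is lossless.
When alternate locations are present only the highest-occupancy conformer
is kept (ties broken by file order), since downstream energetics need a
single conformer per atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "Trajectory",
    "read_structure",
    "write_structure",
    "write_trajectory",
    "read_frames",
    "write_frames",
    "read_fasta",
]


@dataclass
class AtomRecord:
    """One atom of a molecular structure (PDB ATOM/HETATM line)."""

    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    xyz: np.ndarray  # shape (3,), Angstrom
    i_code: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    tempfactor: float = 0.0
    element: str = ""
    het: bool = False  # True for HETATM records (ligands, ions)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom serial {self.serial}: coordinates must be a finite 3-vector")

    @property
    def res_key(self) -> str:
        """Author residue number with insertion-code suffix, e.g. '52' or '52A'."""
        return f"{self.res_seq}{self.i_code}"

    @property
    def res_uid(self) -> tuple[str, str]:
        """(chain_id, res_key): unique residue identity within a model."""
        return (self.chain_id, self.res_key)


class MolecularStructure:
    """Ordered atom list with a chain/residue index.

    Residue spans are contiguous, disjoint, and cover all atoms; atom order
    is stable under read -> write -> read.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        self._build_index()

    def _build_index(self) -> None:
        self.residue_index: dict[tuple[str, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self.residue_index.setdefault(a.res_uid, []).append(i)
        seen: set[tuple[tuple[str, str], str]] = set()
        for a in self.atoms:
            key = (a.res_uid, a.name)
            if key in seen:
                raise ValueError(
                    f"duplicate atom {a.name} in residue {a.res_uid} "
                    "(alternate locations must be resolved before construction)"
                )
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array (a copy)."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape ({self.n_atoms}, 3), got {coords.shape}")
        return MolecularStructure([replace(a, xyz=coords[i].copy()) for i, a in enumerate(self.atoms)])

    def subset(self, indices: Sequence[int]) -> "MolecularStructure":
        return MolecularStructure([self.atoms[i] for i in indices])

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self) -> Iterator[tuple[tuple[str, str], list[int]]]:
        yield from self.residue_index.items()

    def residue_uids(self, atom_indices: Sequence[int] | None = None) -> list[tuple[str, str]]:
        """Residue uids in atom order (deduplicated), optionally restricted."""
        idx = range(self.n_atoms) if atom_indices is None else atom_indices
        out: list[tuple[str, str]] = []
        seen = set()
        for i in idx:
            uid = self.atoms[i].res_uid
            if uid not in seen:
                seen.add(uid)
                out.append(uid)
        return out

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain (unknown residue names become X)."""
        out = []
        for a in self.atoms:
            if a.chain_id == chain_id and a.name == "CA" and not a.het:
                out.append(_THREE_TO_ONE.get(a.res_name, "X"))
        return "".join(out)

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        return (
            f"<MolecularStructure {self.n_atoms} atoms, "
            f"{len(self.residue_index)} residues, chains {self.chains}>"
        )


@dataclass
class Trajectory:
    """F frames x N atoms x 3 coordinates (Angstrom) over a fixed atom list.

    ``replica_ids`` labels each frame with the replica it came from so that
    per-replica and cross-replica statistics can be formed downstream.
    """

    coords: np.ndarray
    template: MolecularStructure
    replica_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_time_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (F, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.template.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"template ({self.template.n_atoms})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory contains non-finite coordinates")
        if self.replica_ids is None:
            self.replica_ids = np.zeros(self.n_frames, dtype=int)
        self.replica_ids = np.asarray(self.replica_ids, dtype=int)
        if self.replica_ids.shape != (self.n_frames,):
            raise ValueError("replica_ids must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def replicas(self) -> list[int]:
        return sorted(set(self.replica_ids.tolist()))

    def frames_of_replica(self, rid: int) -> np.ndarray:
        return np.nonzero(self.replica_ids == rid)[0]

    def __repr__(self) -> str:
        return f"<Trajectory F={self.n_frames} N={self.n_atoms} replicas={self.replicas}>"


# one-letter codes for the 20 standard amino acids plus common variants
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "SEP": "S", "TPO": "T", "PTR": "Y", "MSE": "M", "HSD": "H", "HSE": "H",
}


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise ValueError(f"line {lineno}: ATOM/HETATM record shorter than coordinate fields")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        i_code = line[26].strip()
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        temp = float(line[60:66]) if len(line) >= 66 and line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed fixed-column PDB record ({exc})") from exc
    if not element:
        element = name[:1]
    return AtomRecord(
        serial=serial, name=name, res_name=res_name, chain_id=chain_id,
        res_seq=res_seq, xyz=xyz, i_code=i_code, altloc=altloc,
        occupancy=occ, tempfactor=temp, element=element,
        het=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[int]:
    """Indices of atoms to keep: highest-occupancy conformer per atom identity."""
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.res_uid, a.name)
        if key not in best or a.occupancy > atoms[best[key]].occupancy:
            best[key] = i
    kept = sorted(best.values())
    dropped = len(atoms) - len(kept)
    if dropped:
        logger.info("dropped %d alternate-location conformers", dropped)
    return kept


def read_structure(
    path: str | Path, dialect: str = "pdb"
) -> tuple[MolecularStructure, Trajectory | None]:
    """Read a PDB file; multi-model files additionally yield a Trajectory.

    HETATM records (ATP, Mg, ...) are retained and flagged with ``het=True``.
    Raises ValueError naming the line number on malformed fixed-column lines,
    and on inconsistent atom counts across models.
    """
    if dialect not in ("pdb", "pdb-multimodel"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ValueError(f"{path}: no ATOM/HETATM records found")

    counts = {len(m) for m in models}
    if len(counts) > 1:
        raise ValueError(f"{path}: inconsistent atom count across models: {sorted(counts)}")

    kept = _resolve_altlocs(models[0])
    structure = MolecularStructure([replace(models[0][i], altloc="") for i in kept])
    if len(models) == 1:
        return structure, None
    coords = np.stack([np.array([m[i].xyz for i in kept]) for m in models])
    return structure, Trajectory(coords=coords, template=structure)


def _format_atom_line(a: AtomRecord, serial: int, bfac: float) -> str:
    rec = "HETATM" if a.het else "ATOM  "
    name = a.name if len(a.name) == 4 else f" {a.name:<3}"
    return (
        f"{rec}{serial % 100000:>5} {name}{a.altloc or ' '}{a.res_name:>3} "
        f"{a.chain_id}{a.res_seq:>4}{a.i_code or ' '}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{bfac:6.2f}          {a.element:>2}\n"
    )


def _broadcast_scalar(structure: MolecularStructure, scalar: np.ndarray | None) -> np.ndarray:
    """Per-atom scalar column; per-residue values are broadcast to atoms."""
    if scalar is None:
        return np.array([a.tempfactor for a in structure.atoms])
    scalar = np.asarray(scalar, dtype=float)
    if not np.all(np.isfinite(scalar)):
        raise ValueError("scalar per-atom values must be finite")
    if scalar.shape == (structure.n_atoms,):
        return scalar
    n_res = len(structure.residue_index)
    if scalar.shape == (n_res,):
        out = np.empty(structure.n_atoms)
        for r, (_, span) in enumerate(structure.residues()):
            out[span] = scalar[r]
        return out
    raise ValueError(
        f"scalar length {scalar.shape} matches neither atom count "
        f"({structure.n_atoms}) nor residue count ({n_res})"
    )


def write_structure(
    structure: MolecularStructure,
    path: str | Path,
    scalar_per_atom: np.ndarray | None = None,
) -> None:
    """Write a single-model PDB; ``scalar_per_atom`` fills the B-factor column.

    A per-residue vector is accepted and broadcast to each residue's atoms.
    Round-trips coordinates to 3 decimals and the scalar column to 2 decimals
    (PDB fixed-format precision).
    """
    bfac = _broadcast_scalar(structure, scalar_per_atom)
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms):
            fh.write(_format_atom_line(a, a.serial, bfac[i]))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:>8}\n")
            for i, a in enumerate(traj.template.atoms):
                fh.write(_format_atom_line(replace(a, xyz=traj.coords[f, i]), a.serial, a.tempfactor))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_frames(traj: Trajectory, path: str | Path) -> None:
    """Write the plain-text frames dialect: header line 'F N', then F blocks
    of N rows of x y z; replica labels preserved in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# replica_ids: {' '.join(map(str, traj.replica_ids.tolist()))}\n")
        fh.write(f"{traj.n_frames} {traj.n_atoms}\n")
        for f in range(traj.n_frames):
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_frames(path: str | Path, template: MolecularStructure) -> Trajectory:
    """Read the plain-text frames dialect against an atom template."""
    replica_ids = None
    rows: list[list[float]] = []
    header: tuple[int, int] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# replica_ids:"):
                    replica_ids = np.array(line.split(":", 1)[1].split(), dtype=int)
                continue
            parts = line.split()
            if header is None:
                if len(parts) != 2:
                    raise ValueError(f"{path}: expected header line 'F N'")
                header = (int(parts[0]), int(parts[1]))
                continue
            rows.append([float(p) for p in parts])
    if header is None:
        raise ValueError(f"{path}: empty frames file")
    f_count, n_atoms = header
    if n_atoms != template.n_atoms:
        raise ValueError(f"{path}: atom count {n_atoms} does not match template ({template.n_atoms})")
    arr = np.asarray(rows, dtype=float)
    if arr.shape != (f_count * n_atoms, 3):
        raise ValueError(f"{path}: expected {f_count * n_atoms} coordinate rows, got {arr.shape[0]}")
    coords = arr.reshape(f_count, n_atoms, 3)
    return Trajectory(coords=coords, template=template, replica_ids=replica_ids)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
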