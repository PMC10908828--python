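"""Per-atom force-field parameter tables and exclusion topology.

Parameters (partial charge, Lennard-Jones sigma/epsilon, intrinsic Born
radius, GB screening factor) are *inputs* read from a plain TSV table, never
derived here.  The table is keyed by (res_name, atom_name), or per atom
serial when a ``serial`` column is present.  A bond list (TSV of serial
pairs) defines the exclusion topology: 1-2 and 1-3 pairs are excluded from
nonbonded sums, 1-4 pairs are scaled (electrostatics by 1/1.2, LJ by 1/2.0,
the convention of the Amber fixed-charge force-field family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chapdyn.core_io import MolecularStructure

__all__ = [
    "SCALE14_ELEC",
    "SCALE14_LJ",
    "ParameterizedSystem",
    "read_parameter_table",
    "read_bonds",
    "build_exclusions",
    "load_parameters",
]

SCALE14_ELEC = 1.0 / 1.2
SCALE14_LJ = 0.5

PARAM_COLUMNS = ["res_name", "atom_name", "charge_e", "sigma_A", "epsilon_kcal", "born_radius_A", "gb_screen"]


@dataclass
class ParameterizedSystem:
    """A structure plus per-atom nonbonded parameters and exclusion topology.

    Pairs in ``exclusions`` (1-2 and 1-3 neighbours) contribute nothing to
    nonbonded sums; pairs in ``pairs14`` are scaled.  Both sets store
    ``(i, j)`` with ``i < j`` over internal atom indices.
    """

    structure: MolecularStructure
    charge: np.ndarray  # e
    sigma: np.ndarray  # Angstrom
    epsilon: np.ndarray  # kcal/mol
    born_radius: np.ndarray  # Angstrom (intrinsic)
    gb_screen: np.ndarray  # dimensionless
    exclusions: set = field(default_factory=set)
    pairs14: set = field(default_factory=set)
    scale14_elec: float = SCALE14_ELEC
    scale14_lj: float = SCALE14_LJ

    def __post_init__(self) -> None:
        n = self.structure.n_atoms
        for name in ("charge", "sigma", "epsilon", "born_radius", "gb_screen"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per atom ({n})")
            setattr(self, name, arr)
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be >= 0")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")
        if np.any(self.born_radius <= 0):
            raise ValueError("born_radius must be > 0")
        for pair_set in (self.exclusions, self.pairs14):
            for i, j in pair_set:
                if i == j:
                    raise ValueError("exclusion lists must not contain self-pairs")
        self.exclusions = {(min(p), max(p)) for p in self.exclusions}
        self.pairs14 = {(min(p), max(p)) for p in self.pairs14}

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def is_excluded(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.exclusions

    def is_scaled14(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.pairs14

    def rmin_half(self) -> np.ndarray:
        """LJ R_min/2 per atom (the default vdW radius set for SASA)."""
        return self.sigma * (2.0 ** (1.0 / 6.0)) / 2.0

    def subset_arrays(self, idx: np.ndarray):
        """(charge, sigma, epsilon, born_radius, gb_screen) restricted to idx."""
        return (
            self.charge[idx], self.sigma[idx], self.epsilon[idx],
            self.born_radius[idx], self.gb_screen[idx],
        )


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a parameter TSV.  Required columns: res_name, atom_name,
    charge_e, sigma_A, epsilon_kcal, born_radius_A, gb_screen; an optional
    ``serial`` column switches to explicit per-atom assignment."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PARAM_COLUMNS if c not in df.columns and c not in ("res_name", "atom_name")]
    if "serial" not in df.columns:
        missing += [c for c in ("res_name", "atom_name") if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table {path} lacks required columns: {missing}")
    return df


def read_bonds(path: str | Path) -> list[tuple[int, int]]:
    """Read a bond list TSV with columns serial_i, serial_j."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"serial_i", "serial_j"} <= set(df.columns):
        raise ValueError(f"bond table {path} must have columns serial_i, serial_j")
    return [(int(a), int(b)) for a, b in zip(df["serial_i"], df["serial_j"])]


def build_exclusions(
    n_atoms: int, bonds: list[tuple[int, int]]
) -> tuple[set, set]:
    """From a bond list over internal indices, derive (exclusions, pairs14).

    Exclusions are all 1-2 and 1-3 pairs; pairs14 are atoms exactly three
    bonds apart that are not also 1-2 or 1-3 through a shorter path.
    """
    nbr: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        if i == j:
            raise ValueError("bond list contains a self-bond")
        nbr[i].add(j)
        nbr[j].add(i)
    excl: set = set()
    p14: set = set()
    for i in range(n_atoms):
        two = set()
        for j in nbr[i]:
            excl.add((min(i, j), max(i, j)))
            two |= nbr[j]
        two -= {i} | nbr[i]
        for k in two:
            excl.add((min(i, k), max(i, k)))
        three = set()
        for k in two:
            three |= nbr[k]
        three -= {i} | nbr[i] | two
        for m in three:
            p14.add((min(i, m), max(i, m)))
    p14 -= excl
    return excl, p14


def load_parameters(
    structure: MolecularStructure,
    table: "str | Path | pd.DataFrame",
    bonds: "str | Path | list | None" = None,
) -> ParameterizedSystem:
    """Attach parameters from a TSV table (and optional bond list) to a
    structure.  Raises ValueError listing every atom without a parameter row.

    ``table`` may be a TSV path or an in-memory DataFrame with the same
    columns; ``bonds`` a TSV path or a list of (serial_i, serial_j) pairs.
    """
    df = table if isinstance(table, pd.DataFrame) else read_parameter_table(table)
    n = structure.n_atoms
    cols = ("charge_e", "sigma_A", "epsilon_kcal", "born_radius_A", "gb_screen")
    values = {c: np.empty(n) for c in cols}

    if "serial" in df.columns:
        by_serial = {int(r.serial): r for r in df.itertuples()}
        missing = [a for a in structure.atoms if a.serial not in by_serial]
        if missing:
            raise ValueError(
                "missing parameter rows for atoms (by serial): "
                + ", ".join(f"{a.serial} {a.res_name}:{a.name}" for a in missing[:20])
            )
        for i, a in enumerate(structure.atoms):
            row = by_serial[a.serial]
            for c in cols:
                values[c][i] = getattr(row, c)
    else:
        by_key = {(r.res_name, r.atom_name): r for r in df.itertuples()}
        missing = [a for a in structure.atoms if (a.res_name, a.name) not in by_key]
        if missing:
            raise ValueError(
                "missing parameter rows for atoms: "
                + ", ".join(f"{a.chain_id}:{a.res_key} {a.res_name}:{a.name}" for a in missing[:20])
            )
        for i, a in enumerate(structure.atoms):
            row = by_key[(a.res_name, a.name)]
            for c in cols:
                values[c][i] = getattr(row, c)

    excl: set = set()
    p14: set = set()
    if bonds is not None:
        serial_to_idx = {a.serial: i for i, a in enumerate(structure.atoms)}
        bonds_serial = bonds if isinstance(bonds, list) else read_bonds(bonds)
        try:
            bonds = [(serial_to_idx[i], serial_to_idx[j]) for i, j in bonds_serial]
        except KeyError as exc:
            raise ValueError(f"bond list references unknown atom serial {exc.args[0]}") from exc
        excl, p14 = build_exclusions(n, bonds)

    return ParameterizedSystem(
        structure=structure,
        charge=values["charge_e"],
        sigma=values["sigma_A"],
        epsilon=values["epsilon_kcal"],
        born_radius=values["born_radius_A"],
        gb_screen=values["gb_screen"],
        exclusions=excl,
        pairs14=p14,
    )
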