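"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chapdyn.core_io import AtomRecord, MolecularStructure
from chapdyn.params import ParameterizedSystem
from chapdyn.synthetic import make_threaded_dimer


PDB_5ATOMS = """\
ATOM      1  N   ALA A 340      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A 340      11.639   6.071  -5.147  1.00 11.00           C
ATOM      3  C   ALA A 340      12.750   7.092  -4.905  1.00 12.00           C
ATOM      4  CA  GLY A 341      14.856   7.960  -4.014  1.00 13.00           C
ATOM      5  CA  SER B  10      16.093   7.643  -1.555  1.00 14.00           C
END
"""


@pytest.fixture
def five_atom_pdb(tmp_path):
    p = tmp_path / "five.pdb"
    p.write_text(PDB_5ATOMS)
    return p


@pytest.fixture
def multimodel_pdb(tmp_path):
    """Three models of the same 5 atoms, coordinates shifted per model."""
    lines = []
    for m in range(3):
        lines.append(f"MODEL {m + 1:>8}\n")
        for raw in PDB_5ATOMS.splitlines():
            if raw.startswith("ATOM"):
                x = float(raw[30:38]) + m
                lines.append(raw[:30] + f"{x:8.3f}" + raw[38:] + "\n")
        lines.append("ENDMDL\n")
    lines.append("END\n")
    p = tmp_path / "multi.pdb"
    p.write_text("".join(lines))
    return p


def simple_structure(positions, charges=None, names=None, chain="A"):
    """Build a one-atom-per-residue structure at given positions."""
    atoms = []
    for i, xyz in enumerate(positions):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name="CA",
                res_name=(names[i] if names else "GLY"),
                chain_id=chain if isinstance(chain, str) else chain[i],
                res_seq=i + 1,
                xyz=np.asarray(xyz, dtype=float),
                element="C",
            )
        )
    return MolecularStructure(atoms)


def simple_system(
    positions,
    charges,
    sigma=3.4,
    epsilon=0.1,
    rho=1.7,
    screen=0.8,
    chain="A",
    exclusions=(),
    pairs14=(),
):
    """ParameterizedSystem over single-atom residues with uniform LJ class."""
    n = len(positions)
    structure = simple_structure(positions, chain=chain)
    return ParameterizedSystem(
        structure=structure,
        charge=np.asarray(charges, dtype=float),
        sigma=np.full(n, sigma),
        epsilon=np.full(n, epsilon),
        born_radius=np.full(n, rho),
        gb_screen=np.full(n, screen),
        exclusions=set(exclusions),
        pairs14=set(pairs14),
    )


@pytest.fixture(scope="session")
def dimer_scene():
    """The threaded-dimer scene (expensive to build; shared read-only)."""
    return make_threaded_dimer(seed=7)


@pytest.fixture
def param_table_df():
    rows = [
        {"res_name": rn, "atom_name": "CA", "charge_e": q, "sigma_A": 3.4,
         "epsilon_kcal": 0.1, "born_radius_A": 1.7, "gb_screen": 0.8}
        for rn, q in [("GLY", 0.0), ("ALA", 0.0), ("SER", 0.0)]
    ]
    rows.append({"res_name": "ALA", "atom_name": "N", "charge_e": -0.3, "sigma_A": 3.3,
                 "epsilon_kcal": 0.17, "born_radius_A": 1.55, "gb_screen": 0.79})
    rows.append({"res_name": "ALA", "atom_name": "C", "charge_e": 0.5, "sigma_A": 3.4,
                 "epsilon_kcal": 0.086, "born_radius_A": 1.7, "gb_screen": 0.72})
    return pd.DataFrame(rows)
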