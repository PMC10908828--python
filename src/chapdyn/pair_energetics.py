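"""Residue-pair nonbonded interaction-energy decomposition.

Frame-wise Coulomb and 12-6 Lennard-Jones interaction energies between two
atom groups, summed per residue pair and averaged over frames.  This is a
*post-hoc* decomposition of trajectory snapshots: there is no distance
cutoff (every atom pair contributes), which makes the conservation
invariant exact — the sum of all residue-pair entries equals the directly
computed inter-group nonbonded energy.

Conventions:

- Coulomb: ``E = k_e q_i q_j / (eps_in * r)`` with
  ``k_e = 332.0637 kcal*A/(mol*e^2)`` and interior dielectric ``eps_in = 1``
  for gas-phase decomposition entries.
- Lennard-Jones: ``E = 4 eps_ij [(sigma_ij/r)^12 - (sigma_ij/r)^6]`` with
  arithmetic-mean sigma and geometric-mean epsilon (Lorentz-Berthelot).
- 1-2/1-3 pairs contribute zero; 1-4 pairs are scaled (1/1.2 elec, 1/2 LJ).
- Negative energies are favorable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chapdyn.core_io import MolecularStructure, Trajectory
from chapdyn.params import ParameterizedSystem

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyMatrix",
    "ReplicaStats",
    "RankReport",
    "pair_energy",
    "residue_pair_matrix",
    "direct_intergroup_energy",
    "aggregate_replicas",
    "rank_and_partition",
    "export_heatmap_table",
]

COULOMB_CONSTANT = 332.0637  # kcal*A/(mol*e^2)

MIN_DISTANCE = 0.1  # Angstrom; anything below signals a clash / corrupt frame


def residue_label(structure: MolecularStructure, atom_index: int) -> str:
    a = structure.atoms[atom_index]
    return f"{a.chain_id}:{a.res_key}:{a.res_name}"


@dataclass
class EnergyMatrix:
    """Residue-group x residue-group interaction energies (kcal/mol).

    ``coulomb`` and ``vdw`` are (nA, nB) frame-averaged component matrices;
    ``total`` is their elementwise sum.  Row/column identities are
    ``chain:resseq:resname`` labels.
    """

    rows: list[str]
    cols: list[str]
    coulomb: np.ndarray
    vdw: np.ndarray
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.coulomb = np.asarray(self.coulomb, dtype=float)
        self.vdw = np.asarray(self.vdw, dtype=float)
        shape = (len(self.rows), len(self.cols))
        if self.coulomb.shape != shape or self.vdw.shape != shape:
            raise ValueError("component matrices must be (n_rows, n_cols)")
        if not (np.all(np.isfinite(self.coulomb)) and np.all(np.isfinite(self.vdw))):
            raise ValueError("energy matrix entries must be finite")

    @property
    def total(self) -> np.ndarray:
        return self.coulomb + self.vdw

    def component(self, name: str) -> np.ndarray:
        if name == "coulomb":
            return self.coulomb
        if name == "vdw":
            return self.vdw
        if name == "total":
            return self.total
        raise KeyError(f"unknown component {name!r}")

    def to_frame(self, component: str = "total") -> pd.DataFrame:
        return pd.DataFrame(self.component(component), index=self.rows, columns=self.cols)


@dataclass
class ReplicaStats:
    """Cross-replica statistics of per-replica mean energy matrices.

    ``sem = sd / sqrt(R)`` where ``sd`` is the standard deviation (ddof=1)
    of the per-replica means.  With a single replica, sd/sem are None.
    """

    rows: list[str]
    cols: list[str]
    per_replica: dict  # component -> (R, nA, nB) array
    mean: dict  # component -> (nA, nB)
    sd: dict | None
    sem: dict | None
    n_replicas: int = 0


def _lj_mix(sigma_i, sigma_j, eps_i, eps_j):
    return 0.5 * (sigma_i + sigma_j), np.sqrt(eps_i * eps_j)


def pair_energy(
    system: ParameterizedSystem,
    coords: np.ndarray,
    i: int,
    j: int,
    eps_in: float = 1.0,
) -> tuple[float, float]:
    """(E_coulomb, E_vdw) in kcal/mol for one atom pair in one frame.

    Excluded pairs contribute (0, 0); 1-4 pairs are scaled.  Distances
    below 0.1 A raise (clash or corrupt frame).
    """
    if i == j:
        raise ValueError("pair energy requires two distinct atoms")
    if system.is_excluded(i, j):
        return 0.0, 0.0
    r = float(np.linalg.norm(coords[i] - coords[j]))
    if r < MIN_DISTANCE:
        raise ValueError(f"atoms {i} and {j} at distance {r:.4f} A (< {MIN_DISTANCE} A): clash or corrupt frame")
    e_coul = COULOMB_CONSTANT * system.charge[i] * system.charge[j] / (eps_in * r)
    sig, eps = _lj_mix(system.sigma[i], system.sigma[j], system.epsilon[i], system.epsilon[j])
    sr6 = (sig / r) ** 6
    e_vdw = 4.0 * eps * (sr6 * sr6 - sr6)
    if system.is_scaled14(i, j):
        e_coul *= system.scale14_elec
        e_vdw *= system.scale14_lj
    return e_coul, e_vdw


def _pair_grids(system: ParameterizedSystem, idx_a: np.ndarray, idx_b: np.ndarray):
    """Precompute charge products, LJ mixes and exclusion/scale masks for
    the A x B atom grid."""
    qq = np.outer(system.charge[idx_a], system.charge[idx_b])
    sig = 0.5 * (system.sigma[idx_a][:, None] + system.sigma[idx_b][None, :])
    eps = np.sqrt(np.outer(system.epsilon[idx_a], system.epsilon[idx_b]))
    scale_c = np.ones_like(qq)
    scale_v = np.ones_like(qq)
    pos_a = {int(v): k for k, v in enumerate(idx_a)}
    pos_b = {int(v): k for k, v in enumerate(idx_b)}
    for (i, j) in system.exclusions:
        for (x, y) in ((i, j), (j, i)):
            if x in pos_a and y in pos_b:
                scale_c[pos_a[x], pos_b[y]] = 0.0
                scale_v[pos_a[x], pos_b[y]] = 0.0
    for (i, j) in system.pairs14:
        for (x, y) in ((i, j), (j, i)):
            if x in pos_a and y in pos_b:
                scale_c[pos_a[x], pos_b[y]] = system.scale14_elec
                scale_v[pos_a[x], pos_b[y]] = system.scale14_lj
    return qq, sig, eps, scale_c, scale_v


def _frame_energies(coords, idx_a, idx_b, qq, sig, eps, scale_c, scale_v, eps_in):
    diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    active = (scale_c != 0.0) | (scale_v != 0.0)
    if np.any(r[active] < MIN_DISTANCE):
        raise ValueError(f"inter-group atom distance below {MIN_DISTANCE} A: clash or corrupt frame")
    with np.errstate(divide="ignore", invalid="ignore"):
        ec = np.where(active, COULOMB_CONSTANT * qq / (eps_in * np.where(r > 0, r, 1.0)), 0.0) * scale_c
        sr6 = np.where(active, (sig / np.where(r > 0, r, 1.0)) ** 6, 0.0)
        ev = 4.0 * eps * (sr6 * sr6 - sr6) * scale_v
    return ec, ev


def _residue_grouping(structure: MolecularStructure, idx: np.ndarray):
    uids = structure.residue_uids(idx)
    uid_to_row = {u: k for k, u in enumerate(uids)}
    row_of_atom = np.array([uid_to_row[structure.atoms[i].res_uid] for i in idx])
    labels = []
    for u in uids:
        first = structure.residue_index[u][0]
        labels.append(residue_label(structure, first))
    return labels, row_of_atom


def residue_pair_matrix(
    system: ParameterizedSystem,
    trajectory: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    eps_in: float = 1.0,
    stride: int = 1,
    frame_indices: Sequence[int] | None = None,
) -> EnergyMatrix:
    """Frame-averaged residue-pair interaction energy matrix between two
    disjoint atom selections, with no distance cutoff.

    Entry (a, b) is the mean over frames of the sum of pair energies over
    all atom pairs spanning residues a and b.
    """
    idx_a = np.asarray(sel_a, dtype=int)
    idx_b = np.asarray(sel_b, dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("empty selection in residue_pair_matrix")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("selections must be disjoint at the atom level")

    structure = system.structure
    rows, row_of = _residue_grouping(structure, idx_a)
    cols, col_of = _residue_grouping(structure, idx_b)
    qq, sig, eps, sc, sv = _pair_grids(system, idx_a, idx_b)

    frames = frame_indices if frame_indices is not None else range(0, trajectory.n_frames, stride)
    frames = list(frames)
    acc_c = np.zeros((len(rows), len(cols)))
    acc_v = np.zeros((len(rows), len(cols)))
    row_grid = row_of[:, None] * len(cols) + col_of[None, :]
    for f in frames:
        ec, ev = _frame_energies(trajectory.coords[f], idx_a, idx_b, qq, sig, eps, sc, sv, eps_in)
        acc_c += np.bincount(row_grid.ravel(), weights=ec.ravel(), minlength=acc_c.size).reshape(acc_c.shape)
        acc_v += np.bincount(row_grid.ravel(), weights=ev.ravel(), minlength=acc_v.size).reshape(acc_v.shape)
    n = len(frames)
    return EnergyMatrix(rows=rows, cols=cols, coulomb=acc_c / n, vdw=acc_v / n, n_frames=n)


def direct_intergroup_energy(
    system: ParameterizedSystem,
    coords: np.ndarray,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    eps_in: float = 1.0,
) -> tuple[float, float]:
    """Total (Coulomb, vdW) inter-group energy of one frame, by direct sum
    over the atom-pair grid (independent of the residue bookkeeping)."""
    idx_a = np.asarray(sel_a, dtype=int)
    idx_b = np.asarray(sel_b, dtype=int)
    qq, sig, eps, sc, sv = _pair_grids(system, idx_a, idx_b)
    ec, ev = _frame_energies(coords, idx_a, idx_b, qq, sig, eps, sc, sv, eps_in)
    return float(ec.sum()), float(ev.sum())


def aggregate_replicas(matrices: Sequence[EnergyMatrix]) -> ReplicaStats:
    """Cross-replica statistics over per-replica mean matrices.

    Returns per-replica means, the cross-replica mean (equal to the average
    of per-replica means), the standard deviation of the per-replica means,
    and the SEM (= sd / sqrt(R)).  With R < 2, sd and sem are None.
    """
    if not matrices:
        raise ValueError("no replica matrices given")
    rows, cols = matrices[0].rows, matrices[0].cols
    for m in matrices[1:]:
        if m.rows != rows or m.cols != cols:
            raise ValueError("replica matrices must share row/column identities")
    comps = ("coulomb", "vdw", "total")
    per = {c: np.stack([m.component(c) for m in matrices]) for c in comps}
    mean = {c: per[c].mean(axis=0) for c in comps}
    r = len(matrices)
    if r >= 2:
        sd = {c: per[c].std(axis=0, ddof=1) for c in comps}
        sem = {c: sd[c] / np.sqrt(r) for c in comps}
    else:
        sd = sem = None
    return ReplicaStats(rows=rows, cols=cols, per_replica=per, mean=mean, sd=sd, sem=sem, n_replicas=r)


@dataclass
class RankReport:
    """Top interaction pairs and region-block sums of an energy matrix."""

    top_pairs: dict  # component -> list of (row_label, col_label, energy)
    block_sums: dict  # component -> DataFrame (row regions x col regions)
    row_region_of: Mapping[str, str] = field(default_factory=dict)
    col_region_of: Mapping[str, str] = field(default_factory=dict)

    def asymmetry(self, region_x: str, region_y: str, component: str = "total") -> float:
        """Difference of total interaction formed by two row regions
        (e.g. protomer A vs protomer B) with all column residues."""
        bs = self.block_sums[component]
        sx = float(bs.loc[region_x].sum()) if region_x in bs.index else 0.0
        sy = float(bs.loc[region_y].sum()) if region_y in bs.index else 0.0
        return sx - sy


def rank_and_partition(
    matrix: EnergyMatrix,
    k: int,
    region_map: Mapping[str, str] | None = None,
) -> RankReport:
    """Rank the k most favorable (most negative) pairs per component and
    sum the matrix over region blocks given by ``region_map``
    (label per ``chain:resseq:resname`` identity; unlabeled -> 'other')."""
    region_map = dict(region_map or {})

    def label_of(name: str) -> str:
        if name in region_map:
            return region_map[name]
        warnings.warn(f"residue {name} has no region label; assigned 'other'", stacklevel=2)
        return "other"

    row_lab = {r: label_of(r) for r in matrix.rows}
    col_lab = {c: label_of(c) for c in matrix.cols}

    top_pairs: dict = {}
    block_sums: dict = {}
    for comp in ("coulomb", "vdw", "total"):
        vals = matrix.component(comp)
        order = np.argsort(vals, axis=None)[:k]
        pairs = []
        for flat in order:
            a, b = np.unravel_index(flat, vals.shape)
            pairs.append((matrix.rows[a], matrix.cols[b], float(vals[a, b])))
        top_pairs[comp] = pairs
        df = pd.DataFrame(vals, index=matrix.rows, columns=matrix.cols)
        df = df.groupby(lambda r: row_lab[r]).sum().T.groupby(lambda c: col_lab[c]).sum().T
        block_sums[comp] = df
    return RankReport(top_pairs=top_pairs, block_sums=block_sums, row_region_of=row_lab, col_region_of=col_lab)


def export_heatmap_table(
    matrix: EnergyMatrix,
    path: str | Path,
    clip: float = 1.0,
    component: str = "total",
) -> np.ndarray:
    """Write the full-precision component matrix as TSV and return a copy
    clamped to [-clip, +clip] for heatmap rendering."""
    if clip <= 0:
        raise ValueError("clip must be > 0")
    df = matrix.to_frame(component)
    df.to_csv(path, sep="\t", float_format="%.6f")
    return np.clip(matrix.component(component), -clip, clip)
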