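"""MM-GBSA binding energetics.

Generalized-Born polar solvation in the OBC flavor (pairwise HCT
descreening integrals rescaled through the tanh(psi) correction), a
Shrake-Rupley SASA-based nonpolar term, and the single-trajectory binding
free energy protocol:

    dG_bind = < dE_vdw + dE_coul + dG_GB + dG_np >

where receptor and ligand frames are sub-selections of the complex frames,
so internal bonded terms cancel exactly and the gas-phase differences
reduce to inter-group nonbonded sums.  No entropy term; salt concentration
zero (no Debye screening).

Units: kcal/mol, Angstrom, elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from chapdyn.core_io import Trajectory
from chapdyn.pair_energetics import COULOMB_CONSTANT, direct_intergroup_energy
from chapdyn.params import ParameterizedSystem

__all__ = [
    "GBParams",
    "BindingReport",
    "effective_born_radii",
    "gb_energy",
    "gb_energy_pairwise",
    "sphere_points",
    "sasa",
    "mmgbsa_binding",
    "per_residue_gbsa",
]


@dataclass
class GBParams:
    """Parameters of the GB/SA model.

    OBC coefficients (alpha, beta, gamma_obc) and the 0.09 A dielectric
    offset follow the OBC-II parameterization; the nonpolar term is
    ``gamma_np * SASA + np_offset`` per species with the conventional
    surface tension 0.0072 kcal/mol/A^2.
    """

    eps_in: float = 1.0
    eps_out: float = 78.5
    alpha: float = 1.0
    beta: float = 0.8
    gamma_obc: float = 4.85
    dielectric_offset: float = 0.09  # Angstrom
    gamma_np: float = 0.0072  # kcal/mol/A^2
    np_offset: float = 0.0  # kcal/mol
    probe_radius: float = 1.4  # Angstrom
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("require eps_out > eps_in >= 1")
        if self.gamma_np < 0:
            raise ValueError("gamma_np must be >= 0")


def _hct_integral(r: np.ndarray, s: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Pairwise HCT descreening term H(r, s; rho) for each (i, j).

    ``r``: distances (n, n); ``s``: screened neighbour radii S_j*rho_t_j as a
    row (n,); ``rho``: descreened self radii rho_t_i as a column (n, 1).
    Diagonal entries must be masked by the caller.
    """
    s_row = s[None, :]
    rho_col = rho[:, None]
    u = r + s_row
    # engulfed neighbour: no contribution
    contributes = rho_col < u
    l = np.maximum(np.abs(r - s_row), rho_col)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_l = 1.0 / l
        inv_u = 1.0 / u
        term = 0.5 * (
            inv_l - inv_u
            + 0.25 * (r - s_row**2 / np.where(r > 0, r, 1.0)) * (inv_u**2 - inv_l**2)
            + 0.5 * np.log(l / u) / np.where(r > 0, r, 1.0)
        )
        # atom i's descreened sphere poking inside neighbour j
        inside = rho_col < (s_row - r)
        term = term + np.where(inside, 2.0 * 0.5 * (1.0 / rho_col - inv_l) * np.ones_like(r), 0.0)
    return np.where(contributes, term, 0.0)


def effective_born_radii(
    system_or_arrays,
    coords: np.ndarray,
    params: GBParams | None = None,
) -> np.ndarray:
    """Per-atom effective Born radii (A) for one frame, OBC scheme.

    Accepts either a :class:`ParameterizedSystem` or a tuple
    ``(born_radius, gb_screen)`` of per-atom arrays.  For an isolated atom
    the result equals the intrinsic radius minus the dielectric offset;
    burial only increases it.
    """
    params = params or GBParams()
    if isinstance(system_or_arrays, ParameterizedSystem):
        rho_i = system_or_arrays.born_radius
        screen = system_or_arrays.gb_screen
    else:
        rho_i, screen = system_or_arrays
    rho_i = np.asarray(rho_i, dtype=float)
    if np.any(rho_i <= params.dielectric_offset):
        raise ValueError("all intrinsic Born radii must exceed the dielectric offset")
    rho_t = rho_i - params.dielectric_offset
    s = np.asarray(screen, dtype=float) * rho_t
    coords = np.asarray(coords, dtype=float)
    from scipy.spatial.distance import squareform, pdist

    r = squareform(pdist(coords))
    h = _hct_integral(r, s, rho_t)
    np.fill_diagonal(h, 0.0)
    integral = h.sum(axis=1)
    psi = integral * rho_t
    inner = params.alpha * psi - params.beta * psi**2 + params.gamma_obc * psi**3
    inv_radius = 1.0 / rho_t - np.tanh(inner) / rho_i
    radii = 1.0 / inv_radius
    bad = ~np.isfinite(radii) | (radii <= 0)
    if np.any(bad):
        raise ValueError(f"non-finite effective Born radius for atom index {int(np.nonzero(bad)[0][0])}")
    return radii


def gb_energy_pairwise(
    charges: np.ndarray,
    coords: np.ndarray,
    radii: np.ndarray,
    params: GBParams | None = None,
) -> np.ndarray:
    """Full (n, n) matrix of GB energy terms; the total polar solvation
    energy is the sum over all ordered pairs including the i = j self
    terms (for which f_GB reduces to R_i)."""
    params = params or GBParams()
    q = np.asarray(charges, dtype=float)
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    rr = np.outer(radii, radii)
    f_gb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    pref = -0.5 * COULOMB_CONSTANT * (1.0 / params.eps_in - 1.0 / params.eps_out)
    return pref * np.outer(q, q) / f_gb


def gb_energy(
    charges: np.ndarray,
    coords: np.ndarray,
    radii: np.ndarray,
    params: GBParams | None = None,
) -> float:
    """Generalized-Born polar solvation energy (kcal/mol) of one frame.

    Always <= 0 for any nonzero charge set when eps_out > eps_in; for a
    single ion it reduces to the Born expression
    ``-(k_e/2)(1/eps_in - 1/eps_out) q^2 / R``.
    """
    return float(gb_energy_pairwise(charges, coords, radii, params).sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2), Shrake-Rupley.

    Each atom's sphere of radius ``r_i + probe`` is sampled at ``n_points``
    quasi-uniform points; a point is accessible when it lies outside every
    other atom's probe-expanded sphere.  Per-atom area is the accessible
    fraction of ``4 pi (r_i + probe)^2``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("SASA radii must be > 0")
    n = len(coords)
    pts = sphere_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = expanded.max()
    neighbor_lists = tree.query_ball_point(coords, expanded + max_reach)
    areas = np.empty(n)
    for i in range(n):
        nb = np.array([j for j in neighbor_lists[i] if j != i], dtype=int)
        if nb.size:
            surface = coords[i] + expanded[i] * pts
            # point buried when inside any neighbour's probe-expanded sphere
            d2 = (
                np.sum(surface**2, axis=1)[:, None]
                - 2.0 * surface @ coords[nb].T
                + np.sum(coords[nb] ** 2, axis=1)[None, :]
            )
            buried = np.any(d2 < (expanded[nb][None, :] ** 2), axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


@dataclass
class BindingReport:
    """MM-GBSA component energies per frame, per replica, and aggregated.

    ``per_frame`` columns: frame, replica, dE_vdw, dE_coul, dG_gb, dG_np,
    dG_total (kcal/mol); ``per_replica`` holds each replica's mean and SD;
    ``summary`` holds the cross-replica mean, the SD of the per-replica
    means, and the SEM (None when fewer than two replicas).
    """

    per_frame: pd.DataFrame
    per_replica: pd.DataFrame
    summary: dict


_COMPONENTS = ["dE_vdw", "dE_coul", "dG_gb", "dG_np", "dG_total"]


def _species_gb_np(system, idx, coords, params, radii_table):
    """(polar, nonpolar) solvation energy of the species made of atoms idx."""
    q = system.charge[idx]
    sub = coords[idx]
    rho, screen = system.born_radius[idx], system.gb_screen[idx]
    radii = effective_born_radii((rho, screen), sub, params)
    polar = gb_energy(q, sub, radii, params)
    areas = sasa(sub, radii_table[idx], params.probe_radius, params.n_sphere_points)
    nonpolar = params.gamma_np * float(areas.sum()) + params.np_offset
    return polar, nonpolar


def mmgbsa_binding(
    system: ParameterizedSystem,
    trajectory: Trajectory,
    sel_receptor: np.ndarray,
    sel_ligand: np.ndarray,
    params: GBParams | None = None,
    sel_complex: np.ndarray | None = None,
    frame_indices: Sequence[int] | None = None,
    sasa_radii: np.ndarray | None = None,
) -> BindingReport:
    """Single-trajectory MM-GBSA binding free energy of ligand to receptor.

    Receptor and ligand must be disjoint and (if given) their union must
    equal ``sel_complex``.  Gas-phase dE terms are inter-group nonbonded
    sums; dG_GB and dG_np are complex minus isolated-subsystem solvation
    terms with radii recomputed per species.
    """
    params = params or GBParams()
    idx_r = np.asarray(sel_receptor, dtype=int)
    idx_l = np.asarray(sel_ligand, dtype=int)
    if np.intersect1d(idx_r, idx_l).size:
        raise ValueError("receptor and ligand selections overlap")
    idx_c = np.sort(np.concatenate([idx_r, idx_l]))
    if sel_complex is not None and not np.array_equal(np.sort(np.asarray(sel_complex)), idx_c):
        raise ValueError("sel_complex must equal the union of receptor and ligand selections")
    radii_table = sasa_radii if sasa_radii is not None else system.rmin_half()

    frames = list(frame_indices) if frame_indices is not None else list(range(trajectory.n_frames))
    records = []
    for f in frames:
        coords = trajectory.coords[f]
        e_coul, e_vdw = direct_intergroup_energy(system, coords, idx_r, idx_l, params.eps_in)
        gb_c, np_c = _species_gb_np(system, idx_c, coords, params, radii_table)
        gb_r, np_r = _species_gb_np(system, idx_r, coords, params, radii_table)
        gb_l, np_l = _species_gb_np(system, idx_l, coords, params, radii_table)
        d_gb = gb_c - gb_r - gb_l
        d_np = np_c - np_r - np_l
        records.append(
            {
                "frame": f,
                "replica": int(trajectory.replica_ids[f]),
                "dE_vdw": e_vdw,
                "dE_coul": e_coul,
                "dG_gb": d_gb,
                "dG_np": d_np,
                "dG_total": e_vdw + e_coul + d_gb + d_np,
            }
        )
    per_frame = pd.DataFrame.from_records(records)
    grouped = per_frame.groupby("replica")[_COMPONENTS]
    per_replica = grouped.agg(["mean", "std"])
    rep_means = grouped.mean()
    r = len(rep_means)
    summary = {"n_replicas": r, "n_frames": len(frames)}
    for c in _COMPONENTS:
        summary[f"{c}_mean"] = float(rep_means[c].mean())
        if r >= 2:
            sd = float(rep_means[c].std(ddof=1))
            summary[f"{c}_sd"] = sd
            summary[f"{c}_sem"] = sd / np.sqrt(r)
        else:
            summary[f"{c}_sd"] = None
            summary[f"{c}_sem"] = None
    return BindingReport(per_frame=per_frame, per_replica=per_replica, summary=summary)


def per_residue_gbsa(
    system: ParameterizedSystem,
    trajectory: Trajectory,
    sel_receptor: np.ndarray,
    sel_ligand: np.ndarray,
    params: GBParams | None = None,
    frame_indices: Sequence[int] | None = None,
    sasa_radii: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue decomposition of the MM-GBSA binding energy.

    Pairwise gas-phase and GB cross terms are split half to each partner
    residue; GB self terms and per-atom dSASA go to their own residue, so
    residue contributions sum exactly to the per-frame total.
    Returns a DataFrame indexed by residue label with mean component
    contributions over the analyzed frames.
    """
    params = params or GBParams()
    idx_r = np.asarray(sel_receptor, dtype=int)
    idx_l = np.asarray(sel_ligand, dtype=int)
    if np.intersect1d(idx_r, idx_l).size:
        raise ValueError("receptor and ligand selections overlap")
    idx_c = np.sort(np.concatenate([idx_r, idx_l]))
    structure = system.structure
    radii_table = sasa_radii if sasa_radii is not None else system.rmin_half()

    from chapdyn.pair_energetics import _frame_energies, _pair_grids, residue_label

    uids = structure.residue_uids(idx_c)
    uid_pos = {u: k for k, u in enumerate(uids)}
    labels = [residue_label(structure, structure.residue_index[u][0]) for u in uids]
    res_of_c = np.array([uid_pos[structure.atoms[i].res_uid] for i in idx_c])
    pos_in_c = {int(a): k for k, a in enumerate(idx_c)}
    res_of_r = np.array([res_of_c[pos_in_c[int(i)]] for i in idx_r])
    res_of_l = np.array([res_of_c[pos_in_c[int(i)]] for i in idx_l])
    pos_r = np.array([pos_in_c[int(i)] for i in idx_r])
    pos_l = np.array([pos_in_c[int(i)] for i in idx_l])

    qq, sig, eps, sc, sv = _pair_grids(system, idx_r, idx_l)
    frames = list(frame_indices) if frame_indices is not None else list(range(trajectory.n_frames))
    acc = {c: np.zeros(len(uids)) for c in _COMPONENTS}
    for f in frames:
        coords = trajectory.coords[f]
        ec, ev = _frame_energies(coords, idx_r, idx_l, qq, sig, eps, sc, sv, params.eps_in)
        for mat, comp in ((ec, "dE_coul"), (ev, "dE_vdw")):
            half_rows = 0.5 * mat.sum(axis=1)
            half_cols = 0.5 * mat.sum(axis=0)
            np.add.at(acc[comp], res_of_r, half_rows)
            np.add.at(acc[comp], res_of_l, half_cols)
        # GB: complex pairwise matrix minus isolated-subsystem blocks
        sub_c = coords[idx_c]
        radii_c = effective_born_radii((system.born_radius[idx_c], system.gb_screen[idx_c]), sub_c, params)
        t_c = gb_energy_pairwise(system.charge[idx_c], sub_c, radii_c, params)
        for idx_s, pos_s in ((idx_r, pos_r), (idx_l, pos_l)):
            sub = coords[idx_s]
            radii_s = effective_born_radii((system.born_radius[idx_s], system.gb_screen[idx_s]), sub, params)
            t_s = gb_energy_pairwise(system.charge[idx_s], sub, radii_s, params)
            t_c[np.ix_(pos_s, pos_s)] -= t_s
        np.add.at(acc["dG_gb"], res_of_c, t_c.sum(axis=1))
        # nonpolar: per-atom dSASA
        d_area = np.empty(len(idx_c))
        area_c = sasa(sub_c, radii_table[idx_c], params.probe_radius, params.n_sphere_points)
        d_area[:] = area_c
        for idx_s, pos_s in ((idx_r, pos_r), (idx_l, pos_l)):
            area_s = sasa(coords[idx_s], radii_table[idx_s], params.probe_radius, params.n_sphere_points)
            d_area[pos_s] -= area_s
        np.add.at(acc["dG_np"], res_of_c, params.gamma_np * d_area)
    n = len(frames)
    df = pd.DataFrame({c: acc[c] / n for c in _COMPONENTS[:-1]}, index=labels)
    df["dG_total"] = df[_COMPONENTS[:-1]].sum(axis=1)
    return df
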