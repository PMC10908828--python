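"""Trajectory superposition, RMSF-based B-factors, and essential-dynamics PCA.

RMSF is computed about the trajectory mean after rigid-body fitting;
B-factors follow the harmonic relation ``B = (8 pi^2 / 3) RMSF^2``.
Cross-state comparison uses a *joint* normalization: all profiles are
divided by the pooled maximum raw B and scaled to 100, preserving
within-profile ratios exactly so that relative mobility between systems
remains directly comparable.

PCA is performed on mean-centred C-alpha coordinates with population
(1/F) covariance normalization so that eigenvalues partition the total
coordinate variance exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from chapdyn.core_io import MolecularStructure, Trajectory, write_trajectory
from chapdyn.geometry import apply_transform, kabsch

__all__ = [
    "B_FACTOR_PREFACTOR",
    "FluctuationProfile",
    "ModeSet",
    "fit_frames",
    "rmsf",
    "normalize_bfactors",
    "pca",
    "export_mode_trajectory",
]

B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class FluctuationProfile:
    """Per-atom RMSF (A) and B-factors (A^2), with optional normalized B."""

    atom_indices: np.ndarray
    labels: list[str]
    rmsf: np.ndarray
    b_raw: np.ndarray
    b_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.rmsf < 0) or np.any(self.b_raw < 0):
            raise ValueError("RMSF and B must be non-negative")


@dataclass
class ModeSet:
    """Essential-dynamics modes of C-alpha coordinates.

    ``eigenvalues`` (A^2, descending) partition the total coordinate
    variance; ``eigenvectors`` rows are orthonormal 3N directions;
    ``projections`` are centred frames projected on each mode.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_modes, 3n)
    variance_fractions: np.ndarray
    projections: np.ndarray  # (F, n_modes)
    mean: np.ndarray  # (3n,)
    atom_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def fit_frames(
    trajectory: Trajectory,
    fit_selection: np.ndarray | None = None,
    mode: str = "iterative-mean",
    max_iter: int = 10,
    tol: float = 1e-6,
) -> Trajectory:
    """Least-squares (Kabsch) superposition of every frame.

    ``mode='to-first-frame'`` fits once onto frame 1; the default
    ``'iterative-mean'`` alternates fitting and mean recomputation until
    the mean structure shifts by < tol A (at most ``max_iter`` rounds).
    The transform is computed on ``fit_selection`` and applied to all atoms.
    """
    if mode not in ("to-first-frame", "iterative-mean"):
        raise ValueError(f"unknown fit mode {mode!r}")
    sel = np.arange(trajectory.n_atoms) if fit_selection is None else np.asarray(fit_selection, dtype=int)
    if sel.size < 3:
        raise ValueError("fitting requires at least 3 atoms")
    coords = trajectory.coords.copy()
    if trajectory.n_frames == 1:
        return Trajectory(coords=coords, template=trajectory.template,
                          replica_ids=trajectory.replica_ids.copy(),
                          frame_time_ps=trajectory.frame_time_ps)

    def fit_all(reference: np.ndarray) -> None:
        for f in range(coords.shape[0]):
            rot, trans = kabsch(coords[f, sel], reference)
            coords[f] = apply_transform(coords[f], rot, trans)

    fit_all(coords[0, sel])
    if mode == "iterative-mean":
        prev_mean = coords[:, sel].mean(axis=0)
        for _ in range(max_iter):
            fit_all(prev_mean)
            new_mean = coords[:, sel].mean(axis=0)
            shift = float(np.sqrt(np.mean(np.sum((new_mean - prev_mean) ** 2, axis=-1))))
            prev_mean = new_mean
            if shift < tol:
                break
    return Trajectory(coords=coords, template=trajectory.template,
                      replica_ids=trajectory.replica_ids.copy(),
                      frame_time_ps=trajectory.frame_time_ps)


def rmsf(trajectory: Trajectory, selection: np.ndarray | None = None) -> FluctuationProfile:
    """RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames, and raw B-factors.

    The trajectory should already be fitted (see :func:`fit_frames`).
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    sel = np.arange(trajectory.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    sub = trajectory.coords[:, sel, :]
    mean = sub.mean(axis=0)
    msf = np.mean(np.sum((sub - mean) ** 2, axis=-1), axis=0)
    r = np.sqrt(msf)
    labels = [
        f"{a.chain_id}:{a.res_key}:{a.res_name}:{a.name}"
        for a in (trajectory.template.atoms[i] for i in sel)
    ]
    return FluctuationProfile(atom_indices=sel, labels=labels, rmsf=r, b_raw=B_FACTOR_PREFACTOR * msf)


def normalize_bfactors(profiles: list[FluctuationProfile]) -> list[FluctuationProfile]:
    """Joint normalization across systems: every profile divided by the
    pooled maximum raw B and scaled to 100.  Within-profile ratios (and
    hence residue orderings) are preserved exactly.  An all-zero pool
    normalizes to all zeros."""
    if not profiles:
        raise ValueError("no profiles to normalize")
    pooled_max = max(float(p.b_raw.max()) for p in profiles)
    out = []
    for p in profiles:
        b_norm = np.zeros_like(p.b_raw) if pooled_max == 0 else 100.0 * p.b_raw / pooled_max
        out.append(
            FluctuationProfile(
                atom_indices=p.atom_indices, labels=p.labels,
                rmsf=p.rmsf, b_raw=p.b_raw, b_norm=b_norm,
            )
        )
    return out


def pca(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    n_modes: int | None = None,
) -> ModeSet:
    """Principal component analysis of (already fitted) C-alpha coordinates.

    Uses SVD of the centred frame matrix with 1/F normalization, so
    eigenvalues sum exactly to the total coordinate variance.  Requesting
    more modes than the covariance rank truncates with a warning.
    """
    if trajectory.n_frames < 2:
        raise ValueError("PCA requires at least 2 frames")
    sel = np.arange(trajectory.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    x = trajectory.coords[:, sel, :].reshape(trajectory.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    lam = s**2 / trajectory.n_frames
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    k = min(n_modes, len(lam)) if n_modes is not None else len(lam)
    if n_modes is not None and n_modes > rank:
        warnings.warn(
            f"requested {n_modes} modes but covariance rank is {rank}; truncating",
            stacklevel=2,
        )
    total = float(lam.sum())
    fractions = lam / total if total > 0 else np.zeros_like(lam)
    projections = xc @ vt.T
    return ModeSet(
        eigenvalues=lam[:k],
        eigenvectors=vt[:k],
        variance_fractions=fractions[:k],
        projections=projections[:, :k],
        mean=mean,
        atom_indices=sel,
    )


def export_mode_trajectory(
    modes: ModeSet,
    template: MolecularStructure,
    k: int,
    n_steps: int = 20,
    amplitude: float = 2.0,
    path=None,
) -> Trajectory:
    """Animate mode ``k`` (0-based): frames interpolate the mean structure
    from -amplitude*sqrt(lambda_k) to +amplitude*sqrt(lambda_k) along the
    eigenvector.  ``n_steps=2`` yields exactly the two extreme frames.
    When ``path`` is given the animation is written as multi-model PDB.
    """
    if k >= modes.n_modes:
        raise ValueError(f"mode {k} not available ({modes.n_modes} modes)")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    sel = modes.atom_indices if modes.atom_indices is not None else np.arange(len(modes.mean) // 3)
    sub_template = template.subset(list(sel))
    scale = amplitude * np.sqrt(modes.eigenvalues[k])
    amps = np.linspace(-scale, scale, n_steps) if n_steps > 1 else np.array([0.0])
    frames = modes.mean[None, :] + amps[:, None] * modes.eigenvectors[k][None, :]
    coords = frames.reshape(n_steps, -1, 3)
    traj = Trajectory(coords=coords, template=sub_template)
    if path is not None:
        write_trajectory(traj, path)
    return traj
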