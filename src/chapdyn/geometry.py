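"""Rigid-body least-squares superposition (Kabsch algorithm)."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "apply_transform", "rmsd"]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising
    ``|| (mobile @ R.T + t) - reference ||``.

    Reflections are excluded: the returned rotation is orthonormal with
    det +1.  Requires >= 3 non-collinear point pairs.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    if p.shape[0] < 3:
        raise ValueError("superposition requires at least 3 point pairs")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(pc, tol=1e-8) < 2:
        raise ValueError("superposition requires non-collinear points")
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) and np.linalg.det(rot) > 0
    trans = q.mean(axis=0) - rot @ p.mean(axis=0)
    return rot, trans


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two paired coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))
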