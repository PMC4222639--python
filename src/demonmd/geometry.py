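"""Shared geometric primitives: Kabsch superposition, RMSD, dihedrals."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rotation", "superpose", "kabsch_rmsd", "rmsd_raw", "dihedral"]


def kabsch_rotation(mobile: np.ndarray, ref: np.ndarray,
                    weights: np.ndarray | None = None):
    """Optimal rotation/translation mapping ``mobile`` onto ``ref``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` is least-squares closest
    to ``ref`` (proper rotation; reflections are excluded).
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {ref.shape}")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * ref).sum(axis=0)
    P = mobile - mc
    Q = ref - rc
    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def superpose(mobile: np.ndarray, ref: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    R, t = kabsch_rotation(mobile, ref, weights)
    return np.asarray(mobile) @ R.T + t


def rmsd_raw(a: np.ndarray, b: np.ndarray,
             weights: np.ndarray | None = None) -> float:
    """RMSD without superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d2 = ((a - b) ** 2).sum(axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def kabsch_rmsd(a: np.ndarray, b: np.ndarray,
                weights: np.ndarray | None = None) -> float:
    """Minimum RMSD between point sets after optimal superposition."""
    return rmsd_raw(superpose(a, b, weights), b, weights)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180].

    Zero for a planar cis arrangement, 180 for planar trans (IUPAC sign
    convention: positive for a clockwise rotation looking down p1->p2).
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)
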