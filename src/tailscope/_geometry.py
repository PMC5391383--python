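"""Internal rigid-body and internal-coordinate geometry helpers.

Everything here works on plain float arrays; the leading axes broadcast, so
the same routines place one atom in one frame or one atom in every frame of
a trajectory at once.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nerf_place", "dihedral", "bond_angle", "kabsch", "kabsch_rmsd_xyz"]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: np.ndarray | float,
) -> np.ndarray:
    """Place atom D given the three preceding atoms A-B-C (NeRF construction).

    ``bond`` is |C-D| in Å, ``angle`` the B-C-D angle and ``torsion`` the
    A-B-C-D dihedral, both in radians.  ``a``, ``b``, ``c`` may carry leading
    batch axes; ``torsion`` broadcasts against them.
    """
    torsion = np.asarray(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(angle) * np.ones_like(torsion),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ],
        axis=-1,
    )
    return (
        c
        + d_local[..., 0:1] * bc
        + d_local[..., 1:2] * m
        + d_local[..., 2:3] * n
    )


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral p0-p1-p2-p3 in radians (IUPAC sign convention)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = _unit(np.asarray(p2) - np.asarray(p1))
    b2 = np.asarray(p3) - np.asarray(p2)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.arctan2(y, x)


def bond_angle(p0, p1, p2) -> np.ndarray:
    u = _unit(np.asarray(p0) - np.asarray(p1))
    v = _unit(np.asarray(p2) - np.asarray(p1))
    return np.arccos(np.clip(np.sum(u * v, axis=-1), -1.0, 1.0))


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with proper rotation ``R`` (no reflection) and
    translation ``t`` such that ``mobile @ R.T + t`` best fits ``target`` in
    the least-squares sense.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch expects two equally shaped (n, 3) arrays")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = tc - rot @ mc
    moved = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, t, rmsd


def kabsch_rmsd_xyz(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two matched point sets over rigid motions."""
    return kabsch(a, b)[2]
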