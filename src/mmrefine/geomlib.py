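"""Small vector-geometry helpers shared across modules."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                 d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n2 = np.linalg.norm(b2)
    if n2 < 1e-9:
        raise ValueError("degenerate dihedral: coincident central atoms")
    n1 = np.cross(b1, b2)
    n3 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n3) < 1e-9:
        raise ValueError("degenerate dihedral: collinear atoms")
    x = np.dot(n1, n3)
    y = np.dot(np.cross(n1, n3), b2 / n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def wrap_deg(delta: float | np.ndarray):
    """Wrap an angle difference to (-180, 180]."""
    return -((-np.asarray(delta) + 180.0) % 360.0 - 180.0)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given a-b-c with |c-d|, angle(b,c,d) and torsion(a,b,c,d).

    Angles in degrees (natural-extension reference frame construction).
    """
    th = np.radians(angle)
    ph = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(th),
                               np.sin(th) * np.cos(ph),
                               np.sin(th) * np.sin(ph)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues formula)."""
    a = unit(np.asarray(axis, float))
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    k = np.array([[0.0, -a[2], a[1]],
                  [a[2], 0.0, -a[0]],
                  [-a[1], a[0], 0.0]])
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector a onto unit vector b."""
    a = unit(np.asarray(a, float))
    b = unit(np.asarray(b, float))
    v = np.cross(a, b)
    sv = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if sv < 1e-12:
        if c > 0.0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return axis_rotation(perp, np.pi)
    return axis_rotation(v, np.arctan2(sv, c))


def kabsch_rotation(p: np.ndarray, q: np.ndarray,
                    allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimizing || R p_i - q_i || (rows are vectors)."""
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if allow_reflection:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares superposition; returns (rmsd, transformed mobile)."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    r = kabsch_rotation(mobile - cm, target - ct)
    moved = (mobile - cm) @ r.T + ct
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rmsd, moved
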