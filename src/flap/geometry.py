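"""Low-level geometric primitives: internal-coordinate atom placement,
dihedrals, and Kabsch superposition."""

from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom D given three reference atoms A-B-C, the C-D bond
    length (A), the B-C-D angle and the A-B-C-D dihedral (degrees).

    Standard natural-extension-of-reference-frame construction.
    """
    ang = np.deg2rad(angle)
    dih = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        # colinear references: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention
    (trans/anti = 180)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = p0 - p1
    v = p2 - p1
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation superposing ``mobile`` onto ``target``.

    Returns (R, t, centered mobile mean) such that the superposed
    coordinates are ``(mobile - mob_mean) @ R.T + tgt_mean``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    mob_mean = mobile.mean(axis=0)
    tgt_mean = target.mean(axis=0)
    P = mobile - mob_mean
    Q = target - tgt_mean
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, tgt_mean, mob_mean


def superpose(mobile: np.ndarray, target: np.ndarray,
              apply_to: np.ndarray | None = None) -> np.ndarray:
    """Superpose ``mobile`` onto ``target`` (Kabsch) and return the
    transformed ``apply_to`` coordinates (defaults to ``mobile``)."""
    R, tgt_mean, mob_mean = kabsch_rotation(mobile, target)
    pts = mobile if apply_to is None else np.asarray(apply_to, float)
    return (pts - mob_mean) @ R.T + tgt_mean


def rmsd(a: np.ndarray, b: np.ndarray, superposed: bool = False) -> float:
    """RMSD between matched point sets; Kabsch-superposes first unless
    ``superposed`` is True."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if not superposed:
        a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``points`` about the line through ``origin``
    along ``axis``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    pts = np.asarray(points, float) - origin
    return pts @ R.T + origin
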