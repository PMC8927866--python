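"""Low-level 3D geometry: torsion angles, internal-coordinate atom placement,
and batched best-fit (Kabsch) superposition.

These are the numeric primitives shared by structure parsing, side-chain template
construction, fragment search, and the synthetic backbone builder.
"""

from __future__ import annotations

import numpy as np


def torsion(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the atan2 formulation, which is numerically stable for near-planar and
    near-linear configurations.
    """
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -np.degrees(np.arctan2(y, x))  # IUPAC sign convention
    # normalize -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms a-b-c (NeRF).

    D is at distance `bond` from c, with angle b-c-D of `angle_deg` and dihedral
    a-b-c-D of `torsion_deg`.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    # local displacement in the frame where bc is +x
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        # a-b-c collinear: pick an arbitrary perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        n_norm = np.linalg.norm(n)
    n /= n_norm
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between point sets ``a`` and ``b`` (n x 3) over rigid
    superposition (rotation + translation, proper rotations only)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("expected n x 3 coordinates with n >= 3")
    return float(kabsch_rmsd_many(a, b[None, :, :])[0])


def kabsch_rmsd_many(query: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Best-fit RMSD between one query (n x 3) and a stack of targets (m x n x 3).

    Uses the singular values of the covariance matrix: with both point sets
    centered, min RMSD^2 = (|q|^2 + |t|^2 - 2 * (s1 + s2 +/- s3)) / n, the sign of
    s3 chosen to keep the rotation proper.
    """
    q = np.asarray(query, float)
    t = np.asarray(targets, float)
    if t.ndim != 3 or t.shape[1:] != q.shape:
        raise ValueError(f"target stack shape {t.shape} incompatible with query {q.shape}")
    n = q.shape[0]
    qc = q - q.mean(axis=0)
    tc = t - t.mean(axis=1, keepdims=True)
    # covariance per target: H = qc^T . tc  (3 x 3 each)
    h = np.einsum("ni,mnj->mij", qc, tc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    trace = s[:, 0] + s[:, 1] + d * s[:, 2]
    sq = (qc**2).sum() + (tc**2).sum(axis=(1, 2)) - 2.0 * trace
    return np.sqrt(np.maximum(sq, 0.0) / n)


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best-fit rotation R and translation t mapping ``mobile`` onto ``target``.

    Returns (R, t, transformed_mobile) with transformed = mobile @ R.T + t.
    """
    m = np.asarray(mobile, float)
    g = np.asarray(target, float)
    mc = m.mean(axis=0)
    gc = g.mean(axis=0)
    h = (m - mc).T @ (g - gc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = gc - rot @ mc
    return rot, t, m @ rot.T + t
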