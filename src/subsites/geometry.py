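"""Low-level vector geometry: rotations, dihedrals, internal-coordinate
placement (NeRF) and Kabsch least-squares superposition.

All angles are degrees, all lengths Angstrom. Functions operate on plain
numpy arrays; the structural hierarchy lives in :mod:`subsites.structure`.
"""

from __future__ import annotations

import numpy as np

from .errors import SuperpositionError


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix for a proper rotation about ``axis``."""
    k = unit(np.asarray(axis, dtype=float))
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1.0 - np.cos(a)) * (K @ K)


def rotate_about_line(
    coords: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis``."""
    R = rotation_about_axis(axis, angle_deg)
    return (np.asarray(coords) - origin) @ R.T + origin


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def angle(p0, p1, p2) -> float:
    """Bond angle at ``p1`` in degrees."""
    u = unit(np.asarray(p0, float) - np.asarray(p1, float))
    v = unit(np.asarray(p2, float) - np.asarray(p1, float))
    return float(np.rad2deg(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom ``d`` bonded to ``c`` from internal coordinates.

    ``bond_angle`` is the b-c-d angle and ``torsion`` the a-b-c-d dihedral
    (natural extension reference frame construction).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.deg2rad(bond_angle)
    chi = np.deg2rad(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    return (
        c
        - bond_length * np.cos(theta) * bc
        + bond_length * np.sin(theta) * (np.cos(chi) * m + np.sin(chi) * n)
    )


def kabsch(ref: np.ndarray, mov: np.ndarray):
    """Optimal rigid transform mapping ``mov`` onto ``ref``.

    Returns ``(R, t, rmsd)`` with ``mov @ R.T + t`` the superposed copy and
    ``det(R) = +1`` (reflections excluded).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise SuperpositionError("coordinate sets must both be N x 3")
    n = ref.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 atom pairs to superpose")
    ref_mean = ref.mean(axis=0)
    mov_mean = mov.mean(axis=0)
    ref_c = ref - ref_mean
    mov_c = mov - mov_mean
    # degenerate (collinear or coincident) point sets have rank < 2
    for c in (ref_c, mov_c):
        s = np.linalg.svd(c, compute_uv=False)
        if s[1] < 1e-8 * max(1.0, s[0]):
            raise SuperpositionError("degenerate (collinear) coordinate set")
    H = mov_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_mean - R @ mov_mean
    moved = mov @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd
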