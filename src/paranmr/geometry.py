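"""Low-level vector geometry shared across the package.

Internal-coordinate (NeRF-style) atom placement, torsion angles, and axis
rotations.  All coordinates are in Å, all angles in radians unless a function
name says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "dihedral",
    "dihedrals",
    "bond_angle",
    "nerf_place",
    "nerf_place_jacobian",
    "rotation_about_axis",
]


def _cross(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise cross product; much faster than np.cross on small inputs."""
    return np.stack(
        [
            u[..., 1] * v[..., 2] - u[..., 2] * v[..., 1],
            u[..., 2] * v[..., 0] - u[..., 0] * v[..., 2],
            u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0],
        ],
        axis=-1,
    )


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in radians."""
    u = normalize(a - b)
    v = normalize(c - b)
    return float(np.arccos(np.clip(u @ v, -1.0, 1.0)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a–b–c–d in radians, IUPAC sign convention."""
    return float(dihedrals(a[None], b[None], c[None], d[None])[0])


def dihedrals(a, b, c, d) -> np.ndarray:
    """Vectorized signed torsions for stacked points of shape (n, 3)."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    m1 = _cross(n1, b2 / np.sqrt((b2 * b2).sum(axis=-1, keepdims=True)))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def _frame(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Orthonormal frame (bc_hat, m_hat, n_hat) at c from three points."""
    bc = c - b
    v = b - a
    bc_hat = normalize(bc)
    n = _cross(v, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear frame atoms: dihedral reference undefined")
    n_hat = n / nn
    m_hat = _cross(n_hat, bc_hat)
    return bc_hat, m_hat, n_hat


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    distance: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place point D from frame atoms (a, b, c).

    ``distance`` = |c–D|, ``angle`` = b–c–D, ``torsion`` = a–b–c–D, both in
    radians.  This is the standard natural-extension reference-frame
    construction used in sequential chain building.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    bc_hat, m_hat, n_hat = _frame(a, b, c)
    # the -sin component makes the measured a-b-c-D torsion (IUPAC sign)
    # equal the requested one
    d2 = np.array(
        [
            -distance * np.cos(angle),
            distance * np.sin(angle) * np.cos(torsion),
            -distance * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d2[0] * bc_hat + d2[1] * m_hat + d2[2] * n_hat


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def _norm_jac(u: np.ndarray) -> np.ndarray:
    """Jacobian of u/|u| with respect to u."""
    n = np.linalg.norm(u)
    uh = u / n
    return (np.eye(3) - np.outer(uh, uh)) / n


def nerf_place_jacobian(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    distance: float,
    angle: float,
    torsion: float,
):
    """Placement plus the analytic Jacobian ∂D/∂(a, b, c), shape (3, 9).

    The Jacobian propagates through the two normalizations and cross products
    of the frame construction; it is what virtual-site force projection uses.
    """
    bc = c - b
    v = b - a
    bc_hat = normalize(bc)
    n = np.cross(v, bc)
    if np.linalg.norm(n) < 1e-10:
        raise ValueError("collinear frame atoms: dihedral reference undefined")
    n_hat = normalize(n)
    m_hat = np.cross(n_hat, bc_hat)

    alpha = -distance * np.cos(angle)
    beta = distance * np.sin(angle) * np.cos(torsion)
    gamma = -distance * np.sin(angle) * np.sin(torsion)

    site = c + alpha * bc_hat + beta * m_hat + gamma * n_hat

    P_bc = _norm_jac(bc)
    P_n = _norm_jac(n)
    # d(bc)/dx and d(v)/dx for x in (a, b, c) as multiples of identity
    d_bc = {"a": 0.0, "b": -1.0, "c": 1.0}
    d_v = {"a": -1.0, "b": 1.0, "c": 0.0}
    S_bc = _skew(bc)
    S_v = _skew(v)
    S_bchat = _skew(bc_hat)
    S_nhat = _skew(n_hat)

    jac = np.zeros((3, 9))
    for k, x in enumerate(("a", "b", "c")):
        # dn/dx = d(v × bc)/dx = -[bc]× dv/dx + [v]× dbc/dx
        dn = -S_bc * d_v[x] + S_v * d_bc[x]
        dn_hat = P_n @ dn
        dbc_hat = P_bc * d_bc[x]
        dm_hat = -S_bchat @ dn_hat + S_nhat @ dbc_hat
        dD = alpha * dbc_hat + beta * dm_hat + gamma * dn_hat
        if x == "c":
            dD = dD + np.eye(3)
        jac[:, 3 * k : 3 * k + 3] = dD
    return site, jac


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix for angle theta about a (not necessarily unit) axis."""
    u = normalize(axis)
    K = _skew(u)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)
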