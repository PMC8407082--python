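"""Residual dipolar couplings: back-calculation, tensor fitting, restraints.

A weakly aligned molecule's N–H RDC is the Saupe contraction

    D_calc = uᵀ A u

with u the unit N→H bond vector and A the traceless symmetric alignment
tensor.  Here A carries Hz units — the dipolar prefactor is absorbed into
the tensor — so fitting A to observed couplings is a plain linear least
squares in the five independent components (A_xx, A_yy, A_xy, A_xz, A_yz;
A_zz = −A_xx − A_yy).  The SVD-based least-squares fit is the classical
baseline; during sampling the five components are instead carried as live
auxiliary degrees of freedom updated alongside the coordinates, coupled to
the structure only through the flat-bottom restraint energy

    E = Σ_i ½ k · max(0, |D_calc,i − D_obs,i| − tol)²

with tol = 1.5 Hz and k = 0.5 kJ mol⁻¹ Hz⁻² by default.  Minimizing E over
the tensor alone (at tol = 0) reproduces the SVD fit, so the two routes
cross-check each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import RDCRecord, Structure

__all__ = [
    "AlignmentTensor",
    "RDCRestraintConfig",
    "bond_vectors",
    "design_matrix",
    "back_calculate_rdc",
    "back_calculate_all",
    "fit_tensor_svd",
    "rdc_restraint_energy",
    "q_factor",
]


@dataclass(frozen=True)
class AlignmentTensor:
    """Traceless symmetric alignment tensor in Hz (5 independent components)."""

    a_xx: float
    a_yy: float
    a_xy: float
    a_xz: float
    a_yz: float

    @property
    def a_zz(self) -> float:
        return -self.a_xx - self.a_yy

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.a_xx, self.a_xy, self.a_xz],
                [self.a_xy, self.a_yy, self.a_yz],
                [self.a_xz, self.a_yz, self.a_zz],
            ]
        )

    def as_vector(self) -> np.ndarray:
        return np.array([self.a_xx, self.a_yy, self.a_xy, self.a_xz, self.a_yz])

    @classmethod
    def from_vector(cls, v) -> "AlignmentTensor":
        v = np.asarray(v, dtype=float)
        return cls(*v)

    @classmethod
    def from_matrix(cls, m) -> "AlignmentTensor":
        m = np.asarray(m, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("alignment tensor must be symmetric")
        if abs(np.trace(m)) > 1e-8 * max(1.0, np.abs(m).max()):
            raise ValueError("alignment tensor must be traceless")
        return cls(m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2])

    def rotated(self, rotation: np.ndarray) -> "AlignmentTensor":
        r = np.asarray(rotation, dtype=float)
        return AlignmentTensor.from_matrix(r @ self.matrix @ r.T)


@dataclass(frozen=True)
class RDCRestraintConfig:
    """Flat-bottom half-width (Hz) and curvature (kJ mol⁻¹ Hz⁻²)."""

    tolerance: float = 1.5
    k_rdc: float = 0.5

    def __post_init__(self):
        if self.tolerance < 0 or self.k_rdc < 0:
            raise ValueError("tolerance and k_rdc must be >= 0")


def bond_vectors(structure: Structure, records: list[RDCRecord]) -> np.ndarray:
    """Unit N→H vectors, one per record, shape (n, 3)."""
    out = np.empty((len(records), 3))
    for i, rec in enumerate(records):
        n = structure.xyz(rec.chain_id, rec.residue_index, "N")
        h = structure.xyz(rec.chain_id, rec.residue_index, "H")
        v = h - n
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(
                f"zero-length N-H bond at {rec.chain_id}:{rec.residue_index}"
            )
        out[i] = v / norm
    return out


def design_matrix(u: np.ndarray) -> np.ndarray:
    """Rows mapping the 5-component tensor vector to D = uᵀAu.

    D = A_xx(ux²−uz²) + A_yy(uy²−uz²) + 2A_xy·ux·uy + 2A_xz·ux·uz + 2A_yz·uy·uz
    """
    u = np.atleast_2d(u)
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    return np.column_stack(
        [ux**2 - uz**2, uy**2 - uz**2, 2 * ux * uy, 2 * ux * uz, 2 * uy * uz]
    )


def back_calculate_rdc(
    structure: Structure, tensor: AlignmentTensor, record: RDCRecord
) -> float:
    """D_calc = uᵀ A u in Hz for one amide."""
    u = bond_vectors(structure, [record])[0]
    return float(u @ tensor.matrix @ u)


def back_calculate_all(
    structure: Structure, tensor: AlignmentTensor, records: list[RDCRecord]
) -> np.ndarray:
    u = bond_vectors(structure, records)
    return design_matrix(u) @ tensor.as_vector()


def fit_tensor_svd(
    structure: Structure, records: list[RDCRecord]
) -> tuple[AlignmentTensor, np.ndarray]:
    """Least-squares alignment tensor from ≥ 5 couplings (via SVD).

    Returns (tensor, residuals D_obs − D_calc).  Raises if the system is
    underdetermined or the bond-vector geometry leaves the 5-component
    design rank-deficient.
    """
    if len(records) < 5:
        raise ValueError(
            f"need at least 5 RDCs to determine the alignment tensor, got {len(records)}"
        )
    u = bond_vectors(structure, records)
    A = design_matrix(u)
    d_obs = np.array([r.D_obs for r in records], dtype=float)
    solution, _, rank, _ = np.linalg.lstsq(A, d_obs, rcond=None)
    if rank < 5:
        raise ValueError(
            f"rank-deficient design (rank {rank} < 5): bond vectors do not span "
            "enough orientations"
        )
    tensor = AlignmentTensor.from_vector(solution)
    residuals = d_obs - A @ solution
    return tensor, residuals


def rdc_restraint_energy(
    structure: Structure,
    tensor_dof: AlignmentTensor | np.ndarray,
    records: list[RDCRecord],
    config: RDCRestraintConfig = RDCRestraintConfig(),
):
    """Flat-bottom RDC energy with gradients for atoms and tensor DOF.

    Returns ``(E, atom_grads, tensor_grad)`` where ``atom_grads`` maps
    (chain, residue, atom_name) to ∂E/∂xyz for the N and H atoms of each
    violated record, and ``tensor_grad`` is ∂E/∂(five components).  The
    tensor components are auxiliary sampler degrees of freedom; forces on
    them are just −tensor_grad.
    """
    if isinstance(tensor_dof, AlignmentTensor):
        tensor = tensor_dof
    else:
        tensor = AlignmentTensor.from_vector(tensor_dof)
    a_vec = tensor.as_vector()
    a_mat = tensor.matrix

    energy = 0.0
    tensor_grad = np.zeros(5)
    atom_grads: dict[tuple[str, int, str], np.ndarray] = {}
    for rec in records:
        n_xyz = structure.xyz(rec.chain_id, rec.residue_index, "N")
        h_xyz = structure.xyz(rec.chain_id, rec.residue_index, "H")
        r = h_xyz - n_xyz
        norm = np.linalg.norm(r)
        if norm == 0:
            raise ValueError(
                f"zero-length N-H bond at {rec.chain_id}:{rec.residue_index}"
            )
        u = r / norm
        row = design_matrix(u)[0]
        d_calc = float(row @ a_vec)
        dev = d_calc - rec.D_obs
        excess = abs(dev) - config.tolerance
        if excess <= 0:
            continue
        energy += 0.5 * config.k_rdc * excess**2
        dE_dD = config.k_rdc * excess * math.copysign(1.0, dev)
        tensor_grad += dE_dD * row
        # dD/du = 2 A u, chain through the normalization of r = h - n
        dD_du = 2.0 * a_mat @ u
        P = (np.eye(3) - np.outer(u, u)) / norm
        g = dE_dD * (P @ dD_du)
        kh = (rec.chain_id, rec.residue_index, "H")
        kn = (rec.chain_id, rec.residue_index, "N")
        atom_grads[kh] = atom_grads.get(kh, 0.0) + g
        atom_grads[kn] = atom_grads.get(kn, 0.0) - g
    return energy, atom_grads, tensor_grad


def q_factor(d_obs, d_calc) -> float:
    """Q = rms(D_obs − D_calc) / rms(D_obs), the standard RDC quality metric."""
    d_obs = np.asarray(d_obs, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if d_obs.shape != d_calc.shape or d_obs.size == 0:
        raise ValueError("need equally sized, non-empty coupling lists")
    rms_obs = math.sqrt(float(np.mean(d_obs**2)))
    if rms_obs == 0:
        raise ValueError("all-zero observed couplings: Q undefined")
    return math.sqrt(float(np.mean((d_obs - d_calc) ** 2))) / rms_obs
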