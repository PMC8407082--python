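"""Desk-scale replica-exchange Monte Carlo over the restraint posterior.

The sampler targets the Bayesian posterior p(x|D) ∝ p(x)·p(D|x) at toy
scale: a minimal chain prior (harmonic bonds and angles, peptide-plane
torsions, soft Cα excluded volume) stands in for a molecular force field,
and the restraint energies — PRE flat-bottom collections, secondary-
structure fragment collections, and the RDC block with live alignment-tensor
degrees of freedom — stand in for the likelihood.  Each residue is reduced
to four beads (N, H, CA, C); spin labels are virtual sites recomputed from
the backbone frame every evaluation and carry no pairwise interactions.

Replicas run Metropolis Monte Carlo at temperatures on a geometric ladder
with restraint strengths scaled by the ladder's α schedule; nearest-neighbor
exchanges use the standard two-state acceptance ratio.  Moves are torsion
pivots (exact φ/ψ rotations, so the chain prior stays near its minimum),
crankshaft rotations between two Cα pivots, small single-bead displacements,
rigid-body moves of secondary chains, and Gaussian moves of the five tensor
components.  Everything is reproducible from one master seed; per-replica
streams are spawned deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import dihedrals, nerf_place, rotation_about_axis
from .io import RDCRecord, Structure
from .rdc import AlignmentTensor, RDCRestraintConfig, design_matrix
from .restraints import ReplicaLadder, RestraintCollection, SSFragmentGroup
from .spinlabels import VirtualSiteSpec, place_virtual_site
from .synthetic import EXTENDED_TORSIONS, IDEAL_GEOMETRY, build_backbone

__all__ = [
    "KB_KJ_MOL_K",
    "PriorParams",
    "MoveParams",
    "ToySystem",
    "Trajectory",
    "start_conformation",
    "run_remc",
]

KB_KJ_MOL_K = 0.008314462618  # Boltzmann constant, kJ mol^-1 K^-1


@dataclass(frozen=True)
class PriorParams:
    """Minimal chain-prior parameters (kJ/mol, Å, rad)."""

    bond_k: float = 300.0
    angle_k: float = 80.0
    torsion_k: float = 40.0  # peptide-plane (omega, amide-H) restoring terms
    # soft-sphere diameter below the ~4.7 Å closest Cα approach of packed
    # helices: prevents chain crossings without blocking rearrangements
    ev_radius: float = 3.5
    ev_k: float = 20.0


@dataclass(frozen=True)
class MoveParams:
    """Move mixture weights and amplitudes."""

    w_pivot: float = 6.0
    w_crankshaft: float = 2.0
    w_local: float = 1.0
    w_rigid: float = 1.0  # only applies when there are secondary chains
    w_tensor: float = 1.0  # only applies when RDC tensor DOF are present
    pivot_sd_deg: float = 25.0
    #: fraction of pivot proposals that take a large torsion jump instead
    #: of a small step (symmetric Gaussian mixture, so detailed balance
    #: holds); jumps carry chains across torsion basins quickly
    pivot_jump_prob: float = 0.2
    pivot_jump_sd_deg: float = 110.0
    crank_sd_deg: float = 30.0
    local_sd: float = 0.15
    rigid_rot_sd_deg: float = 10.0
    rigid_trans_sd: float = 0.8
    tensor_sd: float = 0.4
    #: amplitude multiplier at the bottom replica, rising linearly to 1 at
    #: the top — cold replicas refine with fine moves, hot ones explore
    amp_scale_bottom: float = 0.3


class ToySystem:
    """A reduced system: topology, priors, restraints, ladder.

    ``pre_collections`` hold :class:`FlatBottomRestraint` members addressed
    by label-site token and (chain, residue) amide; ``ss_collections`` hold
    :class:`SSFragmentGroup` members; the RDC block applies to all records
    with active fraction 1.  Restraint energies scale with the replica's α.
    """

    def __init__(
        self,
        structure: Structure,
        label_specs: list[VirtualSiteSpec] = (),
        pre_collections: list[RestraintCollection] = (),
        ss_collections: list[RestraintCollection] = (),
        rdc_records: list[RDCRecord] = (),
        rdc_config: RDCRestraintConfig = RDCRestraintConfig(),
        initial_tensor: AlignmentTensor | None = None,
        ladder: ReplicaLadder = ReplicaLadder(),
        prior: PriorParams = PriorParams(),
        moves: MoveParams = MoveParams(),
    ):
        self.structure = structure
        self.label_specs = list(label_specs)
        self.pre_collections = list(pre_collections)
        self.ss_collections = list(ss_collections)
        self.rdc_records = list(rdc_records)
        self.rdc_config = rdc_config
        self.ladder = ladder
        self.prior = prior
        self.moves = moves
        self.has_tensor = bool(rdc_records)
        self.tensor0 = (
            (initial_tensor or AlignmentTensor(0.0, 0.0, 0.0, 0.0, 0.0)).as_vector()
            if self.has_tensor
            else None
        )
        self._compile()

    # -- compilation --------------------------------------------------------
    def _compile(self) -> None:
        s = self.structure
        g = IDEAL_GEOMETRY
        rad = math.radians
        self.chain_ids = s.chain_ids
        self.chain_residues = {c: s.residues(c) for c in self.chain_ids}
        idx = s.index_of

        bonds, b0 = [], []
        angles, a0 = [], []
        torsions, t0 = [], []
        for c in self.chain_ids:
            rs = self.chain_residues[c]
            for n, r in enumerate(rs):
                iN, iH = idx(c, r, "N"), idx(c, r, "H")
                iCA, iC = idx(c, r, "CA"), idx(c, r, "C")
                bonds += [(iN, iH), (iN, iCA), (iCA, iC)]
                b0 += [g["b_n_h"], g["b_n_ca"], g["b_ca_c"]]
                angles += [(iH, iN, iCA), (iN, iCA, iC)]
                a0 += [rad(g["a_ca_n_h"]), rad(g["a_n_ca_c"])]
                if n + 1 < len(rs):
                    r2 = rs[n + 1]
                    jN, jH, jCA = idx(c, r2, "N"), idx(c, r2, "H"), idx(c, r2, "CA")
                    bonds.append((iC, jN))
                    b0.append(g["b_c_n"])
                    angles += [(iCA, iC, jN), (iC, jN, jCA)]
                    a0 += [rad(g["a_ca_c_n"]), rad(g["a_c_n_ca"])]
                    # peptide-plane restoring torsions: omega and amide-H
                    torsions += [(iCA, iC, jN, jCA), (iC, jCA, jN, jH)]
                    t0 += [math.pi, math.pi]
        self._bonds = np.array(bonds)
        self._b0 = np.array(b0)
        self._angles = np.array(angles)
        self._a0 = np.array(a0)
        self._torsions = np.array(torsions).reshape(-1, 4)
        self._t0 = np.array(t0)
        self._ca_idx = np.array(
            [idx(c, r, "CA") for c in self.chain_ids for r in self.chain_residues[c]]
        )
        ca_chain = np.array(
            [ci for ci, c in enumerate(self.chain_ids) for _ in self.chain_residues[c]]
        )
        ca_pos = np.concatenate(
            [np.arange(len(self.chain_residues[c])) for c in self.chain_ids]
        )
        same = ca_chain[:, None] == ca_chain[None, :]
        near = np.abs(ca_pos[:, None] - ca_pos[None, :]) < 2
        self._ev_mask = ~(same & near)
        self._ev_mask &= np.triu(np.ones_like(self._ev_mask, dtype=bool), 1)

        # PRE restraints flattened
        site_names = [sp.site_name for sp in self.label_specs]
        pr_site, pr_h, pr_lo, pr_up, pr_k, pr_sw, pr_coll = [], [], [], [], [], [], []
        for ci, coll in enumerate(self.pre_collections):
            for r in coll.restraints:
                pr_site.append(site_names.index(r.site_a))
                pr_h.append(idx(r.site_b[0], r.site_b[1], "H"))
                pr_lo.append(r.lower)
                pr_up.append(r.upper)
                pr_k.append(r.k)
                pr_sw.append(math.inf if r.linear_switch is None else r.linear_switch)
                pr_coll.append(ci)
        self._pre = (
            np.array(pr_site, dtype=int),
            np.array(pr_h, dtype=int),
            np.array(pr_lo),
            np.array(pr_up),
            np.array(pr_k),
            np.array(pr_sw),
            np.array(pr_coll, dtype=int),
        )
        # restraints were flattened in collection order → contiguous slices
        self._pre_slices = []
        off = 0
        for coll in self.pre_collections:
            self._pre_slices.append((off, off + len(coll.restraints), coll))
            off += len(coll.restraints)

        # SS fragment groups flattened
        ss_tor, ss_tor_t, ss_tor_tol, ss_tor_k, ss_tor_g = [], [], [], [], []
        ss_d_ij, ss_d_lo, ss_d_up, ss_d_k, ss_d_g = [], [], [], [], []
        self._ss_group_coll = []  # (collection index, group count offset)
        gid = 0
        for ci, coll in enumerate(self.ss_collections):
            n_groups = len(coll.restraints)
            self._ss_group_coll.append((ci, gid, n_groups))
            for group in coll.restraints:
                assert isinstance(group, SSFragmentGroup)
                c = group.chain_id
                rs = self.chain_residues[c]
                for t in group.torsions:
                    r = t.residue_index
                    if t.name == "phi":
                        if r == rs[0]:
                            continue  # first residue has no phi
                        quad = (
                            idx(c, r - 1, "C"),
                            idx(c, r, "N"),
                            idx(c, r, "CA"),
                            idx(c, r, "C"),
                        )
                    else:
                        if r == rs[-1]:
                            continue  # last residue has no psi
                        quad = (
                            idx(c, r, "N"),
                            idx(c, r, "CA"),
                            idx(c, r, "C"),
                            idx(c, r + 1, "N"),
                        )
                    ss_tor.append(quad)
                    ss_tor_t.append(rad(t.target_deg))
                    ss_tor_tol.append(rad(t.tolerance_deg))
                    ss_tor_k.append(t.k)
                    ss_tor_g.append(gid)
                for (ri, rj, lo, up, k) in group.ca_distances:
                    ss_d_ij.append((idx(c, ri, "CA"), idx(c, rj, "CA")))
                    ss_d_lo.append(lo)
                    ss_d_up.append(up)
                    ss_d_k.append(k)
                    ss_d_g.append(gid)
                gid += 1
        self._n_ss_groups = gid
        self._ss_tor = (
            np.array(ss_tor, dtype=int).reshape(-1, 4),
            np.array(ss_tor_t),
            np.array(ss_tor_tol),
            np.array(ss_tor_k),
            np.array(ss_tor_g, dtype=int),
        )
        self._ss_dist = (
            np.array(ss_d_ij, dtype=int).reshape(-1, 2),
            np.array(ss_d_lo),
            np.array(ss_d_up),
            np.array(ss_d_k),
            np.array(ss_d_g, dtype=int),
        )

        # fused torsion table for the fast path: prior peptide-plane
        # torsions first, then SS fragment torsions — one dihedral batch
        self._fused_tor = np.vstack(
            [self._torsions.reshape(-1, 4), self._ss_tor[0].reshape(-1, 4)]
        ).astype(int)
        self._n_prior_tor = len(self._torsions)

        # RDC records
        self._rdc_n = np.array(
            [idx(r.chain_id, r.residue_index, "N") for r in self.rdc_records], dtype=int
        )
        self._rdc_h = np.array(
            [idx(r.chain_id, r.residue_index, "H") for r in self.rdc_records], dtype=int
        )
        self._rdc_obs = np.array([r.D_obs for r in self.rdc_records])

        # pivot-move residue weights: residues not locked by any secondary-
        # structure fragment get extra proposal weight (hinge regions move
        # whole segments); a fixed proposal distribution keeps detailed
        # balance intact
        locked: set[tuple[str, int]] = set()
        for coll in self.ss_collections:
            for group in coll.restraints:
                for r in group.residues:
                    locked.add((group.chain_id, r))
        self._pivot_weights = {}
        for c in self.chain_ids:
            w = np.array(
                [1.0 if (c, r) in locked else 6.0 for r in self.chain_residues[c]]
            )
            self._pivot_weights[c] = w / w.sum()

        # virtual-site frame atoms (a=C, b=N, c=CA) and internal coordinates
        self._site_frames = np.array(
            [
                (
                    idx(sp.chain_id, sp.residue_index, "C"),
                    idx(sp.chain_id, sp.residue_index, "N"),
                    idx(sp.chain_id, sp.residue_index, "CA"),
                )
                for sp in self.label_specs
            ],
            dtype=int,
        ).reshape(-1, 3)
        d = np.array([sp.distance for sp in self.label_specs])
        th = np.radians([sp.angle_deg for sp in self.label_specs])
        ph = np.radians([sp.dihedral_deg for sp in self.label_specs])
        self._site_abc = (
            -d * np.cos(th),
            d * np.sin(th) * np.cos(ph),
            -d * np.sin(th) * np.sin(ph),
        )

    # -- energies -----------------------------------------------------------
    def prior_energy(self, coords: np.ndarray) -> float:
        p = self.prior
        e = 0.0
        d = np.linalg.norm(coords[self._bonds[:, 0]] - coords[self._bonds[:, 1]], axis=1)
        e += 0.5 * p.bond_k * float(((d - self._b0) ** 2).sum())
        if p.angle_k > 0 and len(self._angles):
            u = coords[self._angles[:, 0]] - coords[self._angles[:, 1]]
            v = coords[self._angles[:, 2]] - coords[self._angles[:, 1]]
            cosang = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            e += 0.5 * p.angle_k * float(((ang - self._a0) ** 2).sum())
        if p.torsion_k > 0 and len(self._torsions):
            chi = dihedrals(
                coords[self._torsions[:, 0]],
                coords[self._torsions[:, 1]],
                coords[self._torsions[:, 2]],
                coords[self._torsions[:, 3]],
            )
            dev = np.mod(chi - self._t0 + math.pi, 2 * math.pi) - math.pi
            e += 0.5 * p.torsion_k * float((dev**2).sum())
        if p.ev_k > 0 and len(self._ca_idx) > 2:
            ca = coords[self._ca_idx]
            dmat = cdist(ca, ca)
            viol = np.where(self._ev_mask, np.maximum(0.0, p.ev_radius - dmat), 0.0)
            e += 0.5 * p.ev_k * float((viol**2).sum())
        return e

    @staticmethod
    def _flat_bottom(d, lo, up, k, switch):
        delta = np.maximum(0.0, d - up) + np.maximum(0.0, lo - d)
        quad = np.minimum(delta, switch)
        lin = np.maximum(delta - switch, 0.0)  # 0 wherever switch is inf
        sw_safe = np.where(np.isfinite(switch), switch, 0.0)
        return 0.5 * k * quad**2 + k * sw_safe * lin

    def _site_positions(self, coords: np.ndarray) -> np.ndarray:
        # vectorized internal-coordinate placement, same math as nerf_place
        fr = self._site_frames
        a, b, c = coords[fr[:, 0]], coords[fr[:, 1]], coords[fr[:, 2]]
        bc = c - b
        bc_hat = bc / np.sqrt((bc * bc).sum(axis=1, keepdims=True))
        v = b - a
        n = np.stack(
            [
                v[:, 1] * bc[:, 2] - v[:, 2] * bc[:, 1],
                v[:, 2] * bc[:, 0] - v[:, 0] * bc[:, 2],
                v[:, 0] * bc[:, 1] - v[:, 1] * bc[:, 0],
            ],
            axis=1,
        )
        n_hat = n / np.sqrt((n * n).sum(axis=1, keepdims=True))
        m_hat = np.stack(
            [
                n_hat[:, 1] * bc_hat[:, 2] - n_hat[:, 2] * bc_hat[:, 1],
                n_hat[:, 2] * bc_hat[:, 0] - n_hat[:, 0] * bc_hat[:, 2],
                n_hat[:, 0] * bc_hat[:, 1] - n_hat[:, 1] * bc_hat[:, 0],
            ],
            axis=1,
        )
        al, be, ga = self._site_abc
        return c + al[:, None] * bc_hat + be[:, None] * m_hat + ga[:, None] * n_hat

    def restraint_energy(self, coords: np.ndarray, tensor: np.ndarray | None):
        """Total data energy and per-collection breakdown."""
        breakdown: dict[str, float] = {}
        total = 0.0

        site_i, h_i, lo, up, k, sw, coll_i = self._pre
        if len(site_i):
            sites = self._site_positions(coords)
            d = np.linalg.norm(sites[site_i] - coords[h_i], axis=1)
            e = self._flat_bottom(d, lo, up, k, sw)
            for start, end, coll in self._pre_slices:
                members = e[start:end]
                na = coll.n_active
                part = np.partition(members, na - 1)[:na] if na < len(members) else members
                val = float(part.sum())
                breakdown[coll.label] = val
                total += val

        if self._n_ss_groups:
            genergy = np.zeros(self._n_ss_groups)
            quads, t0, tol, tk, tg = self._ss_tor
            if len(quads):
                chi = dihedrals(
                    coords[quads[:, 0]], coords[quads[:, 1]],
                    coords[quads[:, 2]], coords[quads[:, 3]],
                )
                dev = np.abs(np.mod(chi - t0 + math.pi, 2 * math.pi) - math.pi)
                ex = np.maximum(0.0, dev - tol)
                np.add.at(genergy, tg, 0.5 * tk * ex**2)
            pairs, dlo, dup, dk, dg = self._ss_dist
            if len(pairs):
                d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
                e = self._flat_bottom(d, dlo, dup, dk, np.inf)
                np.add.at(genergy, dg, e)
            for ci, g0, ng in self._ss_group_coll:
                coll = self.ss_collections[ci]
                members = genergy[g0 : g0 + ng]
                if ng == 0:
                    breakdown[coll.label] = 0.0
                    continue
                na = coll.n_active
                part = np.partition(members, na - 1)[:na] if na < ng else members
                val = float(part.sum())
                breakdown[coll.label] = val
                total += val

        if self.has_tensor and len(self._rdc_n):
            r = coords[self._rdc_h] - coords[self._rdc_n]
            u = r / np.linalg.norm(r, axis=1, keepdims=True)
            d_calc = design_matrix(u) @ tensor
            ex = np.maximum(
                0.0, np.abs(d_calc - self._rdc_obs) - self.rdc_config.tolerance
            )
            val = float(0.5 * self.rdc_config.k_rdc * (ex**2).sum())
            breakdown["rdc"] = val
            total += val
        return total, breakdown

    def energy(self, coords: np.ndarray, tensor: np.ndarray | None = None):
        """(prior energy, restraint energy) of a configuration.

        Single fused evaluation (shared dihedral batch); equal to
        ``prior_energy`` + ``restraint_energy`` run separately.
        """
        p = self.prior
        # bonds
        bvec = coords[self._bonds[:, 0]] - coords[self._bonds[:, 1]]
        d = np.sqrt(np.einsum("ij,ij->i", bvec, bvec))
        ep = 0.5 * p.bond_k * float(((d - self._b0) ** 2).sum())
        # angles
        if p.angle_k > 0 and len(self._angles):
            u = coords[self._angles[:, 0]] - coords[self._angles[:, 1]]
            v = coords[self._angles[:, 2]] - coords[self._angles[:, 1]]
            cosang = np.einsum("ij,ij->i", u, v) / np.sqrt(
                np.einsum("ij,ij->i", u, u) * np.einsum("ij,ij->i", v, v)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            ep += 0.5 * p.angle_k * float(((ang - self._a0) ** 2).sum())
        # all torsions in one batch
        ft = self._fused_tor
        chi = (
            dihedrals(coords[ft[:, 0]], coords[ft[:, 1]], coords[ft[:, 2]], coords[ft[:, 3]])
            if len(ft)
            else np.empty(0)
        )
        npr = self._n_prior_tor
        if p.torsion_k > 0 and npr:
            dev = np.mod(chi[:npr] - self._t0 + math.pi, 2 * math.pi) - math.pi
            ep += 0.5 * p.torsion_k * float((dev**2).sum())
        # excluded volume
        if p.ev_k > 0 and len(self._ca_idx) > 2:
            ca = coords[self._ca_idx]
            dmat = cdist(ca, ca)
            viol = np.where(self._ev_mask, np.maximum(0.0, p.ev_radius - dmat), 0.0)
            ep += 0.5 * p.ev_k * float((viol**2).sum())

        er = 0.0
        site_i, h_i, lo, up, k, sw, _ = self._pre
        if len(site_i):
            sites = self._site_positions(coords)
            dv = sites[site_i] - coords[h_i]
            dd = np.sqrt(np.einsum("ij,ij->i", dv, dv))
            e = self._flat_bottom(dd, lo, up, k, sw)
            for start, end, coll in self._pre_slices:
                members = e[start:end]
                na = coll.n_active
                part = (
                    np.partition(members, na - 1)[:na] if na < len(members) else members
                )
                er += float(part.sum())
        if self._n_ss_groups:
            _, t0, tol, tk, tg = self._ss_tor
            genergy = np.zeros(self._n_ss_groups)
            if len(t0):
                sschi = chi[npr:]
                dev = np.abs(np.mod(sschi - t0 + math.pi, 2 * math.pi) - math.pi)
                ex = np.maximum(0.0, dev - tol)
                genergy = np.bincount(
                    tg, weights=0.5 * tk * ex**2, minlength=self._n_ss_groups
                )
            pairs, dlo, dup, dk, dg = self._ss_dist
            if len(pairs):
                pv = coords[pairs[:, 0]] - coords[pairs[:, 1]]
                pd = np.sqrt(np.einsum("ij,ij->i", pv, pv))
                genergy = genergy + np.bincount(
                    dg,
                    weights=self._flat_bottom(pd, dlo, dup, dk, np.inf),
                    minlength=self._n_ss_groups,
                )
            for ci, g0, ng in self._ss_group_coll:
                coll = self.ss_collections[ci]
                if ng == 0:
                    continue
                members = genergy[g0 : g0 + ng]
                na = coll.n_active
                part = np.partition(members, na - 1)[:na] if na < ng else members
                er += float(part.sum())
        if self.has_tensor and len(self._rdc_n):
            r = coords[self._rdc_h] - coords[self._rdc_n]
            u = r / np.sqrt(np.einsum("ij,ij->i", r, r))[:, None]
            d_calc = design_matrix(u) @ tensor
            ex = np.maximum(
                0.0, np.abs(d_calc - self._rdc_obs) - self.rdc_config.tolerance
            )
            er += float(0.5 * self.rdc_config.k_rdc * (ex**2).sum())
        return ep, er


# ---------------------------------------------------------------------------
# Starting conformations
# ---------------------------------------------------------------------------


def start_conformation(structure: Structure, mode: str = "extended") -> np.ndarray:
    """Starting coordinates for a system templated on ``structure``.

    ``extended`` rebuilds every chain as an ideal all-trans chain (constant
    consecutive Cα–Cα spacing) with chains offset 40 Å apart;
    ``from_structure`` copies the template coordinates.
    """
    if mode == "from_structure":
        return structure.coords.copy()
    if mode != "extended":
        raise ValueError(f"unknown start mode {mode!r}")
    coords = np.empty_like(structure.coords)
    for ci, chain in enumerate(structure.chain_ids):
        residues = structure.residues(chain)
        ext = build_backbone(
            [EXTENDED_TORSIONS] * len(residues), chain, start_residue=residues[0]
        )
        offset = np.array([0.0, 40.0 * ci, 0.0])
        for r in residues:
            for name in ("N", "H", "CA", "C"):
                coords[structure.index_of(chain, r, name)] = (
                    ext.xyz(chain, r, name) + offset
                )
    return coords


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Frames of the bottom replica plus bookkeeping.

    ``energies`` rows are (prior, restraint, total at the bottom replica's
    α = 1); re-evaluating a stored frame with the system reproduces them.
    """

    frames: list[np.ndarray] = field(default_factory=list)
    tensors: list[np.ndarray | None] = field(default_factory=list)
    energies: list[tuple[float, float, float]] = field(default_factory=list)
    walker_ids: list[int] = field(default_factory=list)
    stride: int = 1
    exchange_attempts: int = 0
    exchange_accepts: int = 0
    move_attempts: int = 0
    move_accepts: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.move_accepts / max(1, self.move_attempts)

    @property
    def exchange_rate(self) -> float:
        return self.exchange_accepts / max(1, self.exchange_attempts)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# The REMC driver
# ---------------------------------------------------------------------------


class _Replica:
    __slots__ = ("coords", "tensor", "e_prior", "e_restr", "walker")

    def __init__(self, coords, tensor, e_prior, e_restr, walker):
        self.coords = coords
        self.tensor = tensor
        self.e_prior = e_prior
        self.e_restr = e_restr
        self.walker = walker


def _propose(
    system: ToySystem, rep: _Replica, rng: np.random.Generator, amp: float = 1.0
):
    """One trial move; returns (new_coords, new_tensor) or None for no-op."""
    mp = system.moves
    weights = [mp.w_pivot, mp.w_crankshaft, mp.w_local]
    kinds = ["pivot", "crank", "local"]
    if len(system.chain_ids) > 1:
        weights.append(mp.w_rigid)
        kinds.append("rigid")
    if system.has_tensor:
        weights.append(mp.w_tensor)
        kinds.append("tensor")
    w = np.array(weights) / sum(weights)
    kind = kinds[rng.choice(len(kinds), p=w)]
    coords = rep.coords
    s = system.structure

    if kind == "tensor":
        tensor = rep.tensor.copy()
        tensor[rng.integers(5)] += rng.normal(0.0, amp * mp.tensor_sd)
        return coords, tensor

    chain = system.chain_ids[rng.integers(len(system.chain_ids))]
    residues = system.chain_residues[chain]
    new = coords.copy()

    if kind == "pivot":
        i = int(residues[rng.choice(len(residues), p=system._pivot_weights[chain])])
        which = "phi" if rng.random() < 0.5 else "psi"
        if rng.random() < mp.pivot_jump_prob:
            theta = rng.normal(0.0, math.radians(mp.pivot_jump_sd_deg))
        else:
            theta = rng.normal(0.0, amp * math.radians(mp.pivot_sd_deg))
        iN = s.index_of(chain, i, "N")
        iCA = s.index_of(chain, i, "CA")
        iC = s.index_of(chain, i, "C")
        if which == "phi":
            a0, a1 = coords[iN], coords[iCA]
        else:
            a0, a1 = coords[iCA], coords[iC]
        pos = residues.index(i)
        downstream = pos >= len(residues) / 2
        moved: list[int] = []
        if which == "phi":
            if downstream:
                moved.append(iC)
                tail = residues[pos + 1 :]
            else:
                moved.append(s.index_of(chain, i, "H"))
                tail = residues[:pos]
        else:
            if downstream:
                tail = residues[pos + 1 :]
            else:
                moved += [iN, s.index_of(chain, i, "H")]
                tail = residues[:pos]
        for r in tail:
            for name in ("N", "H", "CA", "C"):
                moved.append(s.index_of(chain, r, name))
        if not moved:
            return None
        R = rotation_about_axis(a1 - a0, theta)
        new[moved] = (coords[moved] - a0) @ R.T + a0
        return new, rep.tensor

    if kind == "crank":
        if len(residues) < 4:
            return None
        pos = rng.integers(0, len(residues) - 2)
        span = int(rng.integers(2, min(6, len(residues) - pos)))
        i, j = residues[pos], residues[pos + span]
        iCA = s.index_of(chain, i, "CA")
        jCA = s.index_of(chain, j, "CA")
        theta = rng.normal(0.0, amp * math.radians(mp.crank_sd_deg))
        moved = [s.index_of(chain, i, "C")]
        for r in residues[pos + 1 : pos + span]:
            for name in ("N", "H", "CA", "C"):
                moved.append(s.index_of(chain, r, name))
        moved += [s.index_of(chain, j, "N"), s.index_of(chain, j, "H")]
        axis = coords[jCA] - coords[iCA]
        if np.linalg.norm(axis) < 1e-8:
            return None
        R = rotation_about_axis(axis, theta)
        a0 = coords[iCA]
        new[moved] = (coords[moved] - a0) @ R.T + a0
        return new, rep.tensor

    if kind == "rigid":
        # rigid-body move of a whole secondary chain
        chain = system.chain_ids[1 + rng.integers(len(system.chain_ids) - 1)]
        residues = system.chain_residues[chain]
        idxs = [
            s.index_of(chain, r, name)
            for r in residues
            for name in ("N", "H", "CA", "C")
        ]
        centre = coords[idxs].mean(axis=0)
        axis = rng.normal(size=3)
        R = rotation_about_axis(
            axis, rng.normal(0.0, amp * math.radians(mp.rigid_rot_sd_deg))
        )
        t = rng.normal(0.0, amp * mp.rigid_trans_sd, size=3)
        new[idxs] = (coords[idxs] - centre) @ R.T + centre + t
        return new, rep.tensor

    # local single-bead displacement
    atom = rng.integers(len(coords))
    new[atom] = coords[atom] + rng.normal(0.0, amp * mp.local_sd, size=3)
    return new, rep.tensor


def run_remc(
    system: ToySystem,
    steps: int,
    seed: int,
    start: np.ndarray | str = "extended",
    stride: int = 10,
    exchange_every: int = 10,
    moves_per_sweep: int | None = None,
) -> Trajectory:
    """Run replica-exchange Metropolis Monte Carlo for ``steps`` sweeps.

    ``start`` is either a coordinate array or a mode for
    :func:`start_conformation`.  Frames of whatever configuration currently
    occupies the bottom (coldest, fully restrained) replica are recorded
    every ``stride`` sweeps.  Identical (seed, inputs) give identical
    trajectories.
    """
    if steps <= 0:
        raise ValueError("steps must be positive")
    n_rep = system.ladder.n_replicas
    seq = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in seq.spawn(n_rep + 1)]
    ex_rng = rngs[-1]

    coords0 = (
        start if isinstance(start, np.ndarray) else start_conformation(system.structure, start)
    )
    tensor0 = system.tensor0.copy() if system.has_tensor else None
    ep0, er0 = system.energy(coords0, tensor0)
    if not (math.isfinite(ep0) and math.isfinite(er0)):
        raise RuntimeError(
            "divergent energy at initialization; loosen the starting "
            "conformation (overlapping beads?)"
        )
    replicas = [
        _Replica(coords0.copy(), None if tensor0 is None else tensor0.copy(), ep0, er0, w)
        for w in range(n_rep)
    ]
    betas = [1.0 / (KB_KJ_MOL_K * system.ladder.temperature(i)) for i in range(n_rep)]
    alphas = [system.ladder.alpha(i) for i in range(n_rep)]
    amp0 = system.moves.amp_scale_bottom
    amps = [
        amp0 + (1.0 - amp0) * (i / (n_rep - 1) if n_rep > 1 else 1.0)
        for i in range(n_rep)
    ]

    if moves_per_sweep is None:
        moves_per_sweep = max(
            8, sum(len(r) for r in system.chain_residues.values())
        )

    traj = Trajectory(stride=stride)

    def record(sweep: int) -> None:
        rep = replicas[0]
        traj.frames.append(rep.coords.copy())
        traj.tensors.append(None if rep.tensor is None else rep.tensor.copy())
        traj.energies.append(
            (rep.e_prior, rep.e_restr, rep.e_prior + alphas[0] * rep.e_restr)
        )
        traj.walker_ids.append(rep.walker)

    for sweep in range(1, steps + 1):
        for ri, rep in enumerate(replicas):
            rng = rngs[ri]
            beta, alpha = betas[ri], alphas[ri]
            for _ in range(moves_per_sweep):
                prop = _propose(system, rep, rng, amps[ri])
                traj.move_attempts += 1
                if prop is None:
                    continue
                new_coords, new_tensor = prop
                tensor_only = new_coords is rep.coords
                if tensor_only:
                    ep = rep.e_prior
                    er, _ = system.restraint_energy(rep.coords, new_tensor)
                else:
                    ep, er = system.energy(new_coords, new_tensor)
                delta = (ep + alpha * er) - (rep.e_prior + alpha * rep.e_restr)
                if delta <= 0 or rng.random() < math.exp(-beta * delta):
                    if not tensor_only:
                        rep.coords = new_coords
                    rep.tensor = new_tensor
                    rep.e_prior, rep.e_restr = ep, er
                    traj.move_accepts += 1
        if n_rep > 1 and sweep % exchange_every == 0:
            offset = (sweep // exchange_every) % 2
            for i in range(offset, n_rep - 1, 2):
                a, b = replicas[i], replicas[i + 1]
                ua_a = a.e_prior + alphas[i] * a.e_restr
                ua_b = b.e_prior + alphas[i] * b.e_restr
                ub_a = a.e_prior + alphas[i + 1] * a.e_restr
                ub_b = b.e_prior + alphas[i + 1] * b.e_restr
                ln_acc = -(betas[i] * ua_b + betas[i + 1] * ub_a) + (
                    betas[i] * ua_a + betas[i + 1] * ub_b
                )
                traj.exchange_attempts += 1
                if ln_acc >= 0 or ex_rng.random() < math.exp(ln_acc):
                    replicas[i], replicas[i + 1] = b, a
                    traj.exchange_accepts += 1
        if sweep % stride == 0:
            record(sweep)
    return traj
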