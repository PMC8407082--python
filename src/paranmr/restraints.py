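"""Flat-bottom restraints, collections with active fractions, and ladders.

The likelihood side of the inference is a set of interval penalties.  Each
restraint is zero on [lower, upper]; outside, the penalty rises as a
half-harmonic ½k(Δ)² for a configurable width and then continues linearly
with matched slope, so early-stage samplers never see enormous forces (set
``linear_switch=None`` for the pure-quadratic form).

Restraints are grouped into *collections*.  Each evaluation, only the
ceil(f·N) lowest-energy members of a collection are *active* and contribute
energy and forces; the remainder are presumed spurious and ignored.  This is
what lets sparse, noisy data restrain a structure without any single bad
datum dominating: if at least the active fraction of a collection is
satisfied, the collection's energy is exactly zero.  How restraints are
divided into collections therefore matters — one global collection can
ignore an entire informative subset, while grouping by label site and
distance class can only ignore a fraction of each.

Secondary-structure predictions enter as 5-residue fragment groups: a window
qualifies when at least 4 of its 5 residues share a helix or extended call,
and contributes φ/ψ torsion restraints plus Cα(i)–Cα(i+3) distance windows.
Fragment groups form their own collection with active fraction 0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import SSPrediction

__all__ = [
    "PRE_FORCE_CONSTANT_KJ_NM2",
    "PRE_FORCE_CONSTANT",
    "PRE_ACTIVE_FRACTION",
    "SS_ACTIVE_FRACTION",
    "FlatBottomRestraint",
    "TorsionRestraint",
    "SSFragmentGroup",
    "RestraintCollection",
    "ReplicaLadder",
    "SSTemplates",
    "DEFAULT_SS_TEMPLATES",
    "restraint_energy_force",
    "flat_bottom_energy",
    "select_active",
    "collection_energy",
    "build_pre_collections",
    "build_ss_restraints",
    "ladder_scale",
]

#: Default PRE restraint force constant as quoted per nm² and converted once
#: to the package's internal Å unit (250 kJ mol⁻¹ nm⁻² = 2.5 kJ mol⁻¹ Å⁻²).
PRE_FORCE_CONSTANT_KJ_NM2 = 250.0
PRE_FORCE_CONSTANT = PRE_FORCE_CONSTANT_KJ_NM2 / 100.0  # kJ mol^-1 Å^-2

PRE_ACTIVE_FRACTION = 0.9
SS_ACTIVE_FRACTION = 0.95


def flat_bottom_energy(
    d: float,
    lower: float,
    upper: float,
    k: float,
    linear_switch: float | None = 3.0,
) -> tuple[float, float]:
    """Energy (kJ/mol) and dE/dd of the flat-bottom penalty at distance d.

    Zero on [lower, upper]; ½k·Δ² on either side for Δ up to
    ``linear_switch``; beyond that, linear with matched slope (C¹ overall).
    """
    if d >= lower and d <= upper:
        return 0.0, 0.0
    if d > upper:
        delta, sign = d - upper, 1.0
    else:
        delta, sign = lower - d, -1.0
    if linear_switch is None or delta <= linear_switch:
        return 0.5 * k * delta * delta, sign * k * delta
    s = linear_switch
    return 0.5 * k * s * s + k * s * (delta - s), sign * k * s


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Interval penalty between a spin-label site and an amide proton.

    ``site_a`` is a label-site token resolved to a virtual-site position;
    ``site_b`` is a (chain, residue) amide-proton reference.  ``dclass``
    records the PRE distance class the bounds came from, for bookkeeping.
    """

    site_a: str
    site_b: tuple[str, int]
    lower: float
    upper: float
    k: float = PRE_FORCE_CONSTANT
    linear_switch: float | None = 3.0
    dclass: str | None = None

    def __post_init__(self):
        if not (0 <= self.lower < self.upper):
            raise ValueError(
                f"require 0 <= lower < upper, got [{self.lower}, {self.upper}]"
            )
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    def energy_force(self, d: float) -> tuple[float, float]:
        return flat_bottom_energy(d, self.lower, self.upper, self.k, self.linear_switch)

    def energy(self, site_positions: dict, structure) -> float:
        d = float(
            np.linalg.norm(
                site_positions[self.site_a]
                - structure.xyz(self.site_b[0], self.site_b[1], "H")
            )
        )
        return self.energy_force(d)[0]


def restraint_energy_force(restraint: FlatBottomRestraint, d: float):
    """Functional form of the restraint at separation d (Å)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return restraint.energy_force(d)


@dataclass(frozen=True)
class TorsionRestraint:
    """Flat-bottom penalty on a backbone torsion (degrees), periodic."""

    residue_index: int
    name: str  # "phi" | "psi"
    target_deg: float
    tolerance_deg: float
    k: float = 80.0  # kJ mol^-1 rad^-2

    def energy(self, angle_deg: float) -> float:
        dev = (angle_deg - self.target_deg + 180.0) % 360.0 - 180.0
        ex = abs(dev) - self.tolerance_deg
        if ex <= 0:
            return 0.0
        return 0.5 * self.k * math.radians(ex) ** 2


@dataclass(frozen=True)
class SSTemplates:
    """Torsion targets/tolerances and Cα(i)–Cα(i+3) windows per SS class.

    Values are conventional ideal-geometry windows (degrees, Å), exposed as
    configuration because secondary-structure restraint templates are a
    modelling choice, not a measured quantity.
    """

    helix_phi: tuple[float, float] = (-62.5, 17.5)
    helix_psi: tuple[float, float] = (-42.5, 17.5)
    extended_phi: tuple[float, float] = (-135.0, 45.0)
    extended_psi: tuple[float, float] = (135.0, 45.0)
    helix_ca_window: tuple[float, float] = (4.5, 6.5)
    extended_ca_window: tuple[float, float] = (8.5, 11.5)
    # strong enough that a torsion outside its window costs several kT at
    # room temperature — secondary structure should form early and firmly
    torsion_k: float = 80.0  # kJ mol^-1 rad^-2
    distance_k: float = PRE_FORCE_CONSTANT  # kJ mol^-1 Å^-2


DEFAULT_SS_TEMPLATES = SSTemplates()


@dataclass(frozen=True)
class SSFragmentGroup:
    """One qualifying 5-residue window of secondary-structure restraints.

    The group energy is the sum of its member torsion and distance
    restraints; a collection treats each group as a single member when
    selecting the active subset.
    """

    chain_id: str
    start_residue: int
    ss_class: str  # "helix" | "extended"
    torsions: tuple[TorsionRestraint, ...]
    ca_distances: tuple[tuple[int, int, float, float, float], ...]
    # (residue_i, residue_j, lower, upper, k)

    def __post_init__(self):
        if self.ss_class not in ("helix", "extended"):
            raise ValueError(f"unknown ss_class {self.ss_class}")

    @property
    def residues(self) -> range:
        return range(self.start_residue, self.start_residue + 5)


@dataclass
class RestraintCollection:
    """A set of restraints (or fragment groups) with an active fraction."""

    restraints: list
    active_fraction: float
    label: str = ""

    def __post_init__(self):
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active_fraction must be in (0, 1]")

    @property
    def n_active(self) -> int:
        # ceil guarantees at least the stated fraction is enforced; the tiny
        # epsilon absorbs binary-float artifacts like 0.9*30 = 27.000...004
        n = len(self.restraints)
        return min(n, max(1, math.ceil(self.active_fraction * n - 1e-9)))

    def __len__(self) -> int:
        return len(self.restraints)


def select_active(collection: RestraintCollection, energies) -> np.ndarray:
    """Indices of the ceil(f·N) lowest-energy members (ties by index)."""
    energies = np.asarray(energies, dtype=float)
    if len(collection) == 0:
        raise ValueError("cannot select from an empty collection")
    if energies.shape != (len(collection),):
        raise ValueError("one energy per member required")
    if not np.all(np.isfinite(energies)):
        raise ValueError("member energies must be finite")
    order = np.argsort(energies, kind="stable")
    return np.sort(order[: collection.n_active])


def collection_energy(collection: RestraintCollection, energies) -> float:
    """Sum of the active members' energies.

    Exactly zero whenever at least the active fraction of the members are
    individually satisfied (zero-energy).
    """
    energies = np.asarray(energies, dtype=float)
    active = select_active(collection, energies)
    return float(energies[active].sum())


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_pre_collections(
    measurements,
    scheme: str = "by_site_and_class",
    k: float = PRE_FORCE_CONSTANT,
    active_fraction: float = PRE_ACTIVE_FRACTION,
    linear_switch: float | None = 3.0,
) -> list[RestraintCollection]:
    """Turn classified PRE measurements into restraint collections.

    ``scheme="single"`` puts every restraint in one collection; the selector
    may then ignore any 10% of the data — including, say, an entire label
    site's short-distance subset.  ``scheme="by_site_and_class"`` makes one
    collection per (label site, distance class) pair (empty pairs omitted),
    so at most 10% of each site/class combination can be ignored.
    """
    if scheme not in ("single", "by_site_and_class"):
        raise ValueError(f"unknown scheme {scheme!r}")
    restraints = [
        FlatBottomRestraint(
            site_a=m.label_site,
            site_b=(m.chain_id, m.residue_index),
            lower=m.lower,
            upper=m.upper,
            k=k,
            linear_switch=linear_switch,
            dclass=m.dclass,
        )
        for m in measurements
    ]
    if scheme == "single":
        return [
            RestraintCollection(restraints, active_fraction, label="all_pre")
        ]
    groups: dict[tuple[str, str], list] = {}
    for r in restraints:
        groups.setdefault((r.site_a, r.dclass), []).append(r)
    return [
        RestraintCollection(rs, active_fraction, label=f"{site}:{dclass}")
        for (site, dclass), rs in sorted(groups.items())
    ]


def build_ss_restraints(
    prediction: SSPrediction,
    templates: SSTemplates = DEFAULT_SS_TEMPLATES,
    active_fraction: float = SS_ACTIVE_FRACTION,
) -> RestraintCollection:
    """Fragment-restraint collection from a secondary-structure string.

    Every 5-residue window (starting at residues 1..L−4) in which ≥ 4/5
    residues are predicted helical, or ≥ 4/5 extended, becomes one
    :class:`SSFragmentGroup` of φ/ψ torsion restraints plus Cα(i)–Cα(i+3)
    distance windows.  Shorter chains yield an empty collection.
    """
    ss = prediction.ss
    groups: list[SSFragmentGroup] = []
    for start in range(len(ss) - 4):
        window = ss[start : start + 5]
        if window.count("H") >= 4:
            ss_class = "helix"
            phi, psi = templates.helix_phi, templates.helix_psi
            ca_win = templates.helix_ca_window
        elif window.count("E") >= 4:
            ss_class = "extended"
            phi, psi = templates.extended_phi, templates.extended_psi
            ca_win = templates.extended_ca_window
        else:
            continue
        first = start + 1  # 1-based residue index
        class_letter = "H" if ss_class == "helix" else "E"
        torsions = []
        for resi in range(first, first + 5):
            # a 4/5 window may contain one residue predicted otherwise;
            # restraining its torsions against its own prediction would
            # penalize the correct structure, so only conforming residues
            # get torsion restraints (the distance windows still span all)
            if ss[resi - 1] != class_letter:
                continue
            torsions.append(
                TorsionRestraint(resi, "phi", phi[0], phi[1], templates.torsion_k)
            )
            torsions.append(
                TorsionRestraint(resi, "psi", psi[0], psi[1], templates.torsion_k)
            )
        ca_dists = tuple(
            (resi, resi + 3, ca_win[0], ca_win[1], templates.distance_k)
            for resi in range(first, first + 2)
        )
        groups.append(
            SSFragmentGroup(
                chain_id=prediction.chain_id,
                start_residue=first,
                ss_class=ss_class,
                torsions=tuple(torsions),
                ca_distances=ca_dists,
            )
        )
    if not groups:
        import warnings

        warnings.warn(
            f"secondary-structure prediction for chain {prediction.chain_id} "
            "yields no fragment groups",
            stacklevel=2,
        )
        return RestraintCollection([], 1.0, label=f"ss:{prediction.chain_id}")
    return RestraintCollection(
        groups, active_fraction, label=f"ss:{prediction.chain_id}"
    )


# ---------------------------------------------------------------------------
# Replica ladder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplicaLadder:
    """Temperature and restraint-strength schedule across replicas.

    Temperatures follow a geometric progression from ``t_min`` (replica 0)
    to ``t_max``; the restraint scale α decreases linearly in replica index
    from 1 at the bottom to ``alpha_min`` at the top, so high replicas
    explore with weakened data terms and feed conformations downward.
    """

    n_replicas: int = 8
    t_min: float = 300.0
    t_max: float = 500.0
    alpha_min: float = 0.0

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")
        if not 0 < self.t_min <= self.t_max:
            raise ValueError("require 0 < t_min <= t_max")
        if not 0 <= self.alpha_min <= 1:
            raise ValueError("alpha_min must be in [0, 1]")

    def temperature(self, i: int) -> float:
        self._check(i)
        if self.n_replicas == 1:
            return self.t_min
        ratio = (self.t_max / self.t_min) ** (1.0 / (self.n_replicas - 1))
        return self.t_min * ratio**i

    def alpha(self, i: int) -> float:
        self._check(i)
        if self.n_replicas == 1:
            return 1.0
        x = i / (self.n_replicas - 1)
        return 1.0 - (1.0 - self.alpha_min) * x

    def _check(self, i: int) -> None:
        if not 0 <= i < self.n_replicas:
            raise IndexError(f"replica index {i} out of range")


def ladder_scale(ladder: ReplicaLadder, replica_index: int) -> tuple[float, float]:
    """(temperature in K, restraint scale α) for one replica."""
    return ladder.temperature(replica_index), ladder.alpha(replica_index)
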