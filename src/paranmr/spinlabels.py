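"""Nitroxide spin labels as non-interacting virtual sites.

An MTSL label attached at an engineered cysteine is represented by a single
dummy point — the mean nitroxide-oxygen centroid — placed deterministically
from the host residue's backbone frame (N, CA, C) by internal coordinates
(distance from CA, angle to N, dihedral to C).  The site carries no pairwise
interactions, so all ten labels of an experiment series can coexist in one
system without perturbing the unrestrained energy; restraint forces applied
to a site are projected back onto the three frame atoms through the analytic
Jacobian of the placement map, which conserves total force.

The default internal coordinates put the centroid ~7 Å from Cα roughly along
the Cβ direction.  They are approximate stand-ins for a dynamics-matched
parameterization of the MTSL rotamer cloud, and are deliberately exposed as
per-site configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import nerf_place, nerf_place_jacobian
from .io import Structure

__all__ = [
    "VirtualSiteSpec",
    "DEFAULT_SITE_GEOMETRY",
    "STUDY_SITES",
    "default_study_sites",
    "place_virtual_site",
    "place_virtual_sites",
    "project_site_force",
    "read_site_table",
    "write_site_table",
]

#: Approximate MTSL nitroxide-oxygen centroid in the backbone frame:
#: (distance from CA in Å, site–CA–N angle in deg, site–CA–N–C dihedral in deg).
DEFAULT_SITE_GEOMETRY = (7.0, 115.0, -120.0)

#: The ten cysteine-mutant label sites of the calmodulin study series;
#: C149 is a single-residue C-terminal extension and uses the same rule.
STUDY_SITES = {
    "S17C": 17,
    "T34C": 34,
    "N42C": 42,
    "N53C": 53,
    "R86C": 86,
    "T110C": 110,
    "T117C": 117,
    "E127C": 127,
    "Q143C": 143,
    "149C": 149,
}


@dataclass(frozen=True)
class VirtualSiteSpec:
    """Deterministic placement rule for one spin-label site."""

    site_name: str
    chain_id: str
    residue_index: int
    distance: float = DEFAULT_SITE_GEOMETRY[0]
    angle_deg: float = DEFAULT_SITE_GEOMETRY[1]
    dihedral_deg: float = DEFAULT_SITE_GEOMETRY[2]

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def default_study_sites(chain_id: str = "protein") -> list[VirtualSiteSpec]:
    """Specs for the ten study label sites with default geometry."""
    return [
        VirtualSiteSpec(name, chain_id, resi) for name, resi in STUDY_SITES.items()
    ]


_SITE_COLS = ["site_name", "chain", "residue", "d", "theta", "phi"]


def read_site_table(tsv_text: str) -> list[VirtualSiteSpec]:
    """Parse a TSV of per-site placement rules (d in Å, angles in degrees)."""
    import io as _stdio

    import pandas as pd

    from .io import ParseError

    df = pd.read_csv(_stdio.StringIO(tsv_text), sep="\t")
    if list(df.columns) != _SITE_COLS:
        raise ParseError(f"site table header must be {_SITE_COLS}, got {list(df.columns)}")
    return [
        VirtualSiteSpec(
            site_name=str(r.site_name),
            chain_id=str(r.chain),
            residue_index=int(r.residue),
            distance=float(r.d),
            angle_deg=float(r.theta),
            dihedral_deg=float(r.phi),
        )
        for r in df.itertuples(index=False)
    ]


def write_site_table(specs: list[VirtualSiteSpec]) -> str:
    lines = ["\t".join(_SITE_COLS)]
    for s in specs:
        lines.append(
            "\t".join(
                [
                    s.site_name,
                    s.chain_id,
                    str(s.residue_index),
                    repr(float(s.distance)),
                    repr(float(s.angle_deg)),
                    repr(float(s.dihedral_deg)),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _frame_atoms(structure: Structure, spec: VirtualSiteSpec):
    for name in ("N", "CA", "C"):
        if not structure.has_atom(spec.chain_id, spec.residue_index, name):
            raise KeyError(
                f"virtual site {spec.site_name}: frame atom {name} missing for "
                f"{spec.chain_id}:{spec.residue_index}"
            )
    c_atom = structure.xyz(spec.chain_id, spec.residue_index, "C")
    n_atom = structure.xyz(spec.chain_id, spec.residue_index, "N")
    ca = structure.xyz(spec.chain_id, spec.residue_index, "CA")
    return c_atom, n_atom, ca


def place_virtual_site(structure: Structure, spec: VirtualSiteSpec) -> np.ndarray:
    """Cartesian position (Å) of the label site; rigid-motion covariant."""
    c_atom, n_atom, ca = _frame_atoms(structure, spec)
    return nerf_place(
        c_atom,
        n_atom,
        ca,
        spec.distance,
        math.radians(spec.angle_deg),
        math.radians(spec.dihedral_deg),
    )


def place_virtual_sites(
    structure: Structure, specs: list[VirtualSiteSpec]
) -> dict[str, np.ndarray]:
    return {s.site_name: place_virtual_site(structure, s) for s in specs}


def project_site_force(
    structure: Structure, spec: VirtualSiteSpec, force_on_site: np.ndarray
) -> dict[str, np.ndarray]:
    """Distribute a force on the virtual site onto its frame atoms.

    Returns forces keyed by frame-atom name (N, CA, C).  Because the
    placement map is a deterministic function of the frame atoms, the
    chain rule gives F_atom = (∂site/∂atom)ᵀ · F_site; the Jacobian columns
    over a uniform translation sum to the identity, so the projected forces
    sum exactly to the site force.
    """
    c_atom, n_atom, ca = _frame_atoms(structure, spec)
    _, jac = nerf_place_jacobian(
        c_atom,
        n_atom,
        ca,
        spec.distance,
        math.radians(spec.angle_deg),
        math.radians(spec.dihedral_deg),
    )
    f = np.asarray(force_on_site, dtype=float)
    # jac columns are ordered (a=C, b=N, c=CA)
    return {
        "C": jac[:, 0:3].T @ f,
        "N": jac[:, 3:6].T @ f,
        "CA": jac[:, 6:9].T @ f,
    }
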