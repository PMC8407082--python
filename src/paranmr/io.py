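"""Readers and writers for every external representation the pipeline touches.

Formats:

* a fixed-column PDB subset (``ATOM``/``TER``/``END``/``MODEL``/``ENDMDL``)
  for structures and toy trajectories;
* TSV tables with mandated headers for peak intensities, RDCs, and
  secondary-structure strings;
* a restraint TSV plus a sidecar file recording collection membership and
  active fractions.

All distances are Å.  Residue numbering is 1-based and contiguous per chain;
chains are named by tokens (conventionally ``protein`` and ``peptide``).
Missing paramagnetic peaks ("broadened beyond detection") are encoded as an
explicit flag — empty cells on disk, ``None`` in memory — never as zero
intensity, which would be a legal-looking but wrong number in the log-ratio
of the two-point estimator.
"""

from __future__ import annotations

import io as _stdio
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "Atom",
    "Structure",
    "IntensityRecord",
    "RDCRecord",
    "SSPrediction",
    "DEFAULT_CHAIN_NAMES",
    "read_structure",
    "write_structure",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "read_intensity_table",
    "write_intensity_table",
    "read_rdc_table",
    "write_rdc_table",
    "read_ss_prediction",
    "write_ss_prediction",
    "write_restraints",
    "read_restraints",
]


class ParseError(ValueError):
    """Malformed input text (bad fixed columns, wrong headers...)."""


class ValidationError(ValueError):
    """Well-formed input with physically invalid content."""


#: Conventional mapping from one-letter PDB chain identifiers to the chain
#: tokens the rest of the pipeline speaks.
DEFAULT_CHAIN_NAMES = {"A": "protein", "B": "peptide"}


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str


class Structure:
    """Atomic coordinates with (chain, residue, atom-name) addressing.

    Holds whatever backbone subset the pipeline needs (N, H, CA, C per
    residue plus anything else present); coordinates are a single (n, 3)
    array so samplers can replace them wholesale.
    """

    def __init__(self, atoms: list[Atom], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValidationError(
                f"coords shape {coords.shape} does not match {len(atoms)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")
        self.atoms = list(atoms)
        self.coords = coords
        self._index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_index, a.atom_name)
            if key in self._index:
                raise ValidationError(f"duplicate atom key {key}")
            self._index[key] = i

    # -- addressing ---------------------------------------------------------
    def index_of(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        try:
            return self._index[(chain_id, residue_index, atom_name)]
        except KeyError:
            raise KeyError(
                f"atom {atom_name} of {chain_id}:{residue_index} not in structure"
            ) from None

    def has_atom(self, chain_id: str, residue_index: int, atom_name: str) -> bool:
        return (chain_id, residue_index, atom_name) in self._index

    def xyz(self, chain_id: str, residue_index: int, atom_name: str) -> np.ndarray:
        return self.coords[self.index_of(chain_id, residue_index, atom_name)]

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self, chain_id: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.residue_index, None)
        return sorted(seen)

    def sequence(self, chain_id: str) -> list[str]:
        names: dict[int, str] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                names.setdefault(a.residue_index, a.residue_name)
        return [names[r] for r in sorted(names)]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, np.array(coords, dtype=float))

    def copy(self) -> "Structure":
        return self.with_coords(self.coords.copy())

    def renamed(self, mapping: dict[str, str]) -> "Structure":
        atoms = [
            replace(a, chain_id=mapping.get(a.chain_id, a.chain_id))
            for a in self.atoms
        ]
        return Structure(atoms, self.coords.copy())

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Structure)
            and self.atoms == other.atoms
            and np.array_equal(self.coords, other.coords)
        )


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------


def _parse_float_field(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def read_structure(pdb_text: str, chain_names: dict[str, str] | None = None) -> Structure:
    """Parse a fixed-column PDB ``ATOM``/``TER``/``END`` subset.

    ``chain_names`` optionally maps one-letter chain identifiers to chain
    tokens (see :data:`DEFAULT_CHAIN_NAMES`); unmapped identifiers are kept
    verbatim.  Only the first ``MODEL`` of a multi-model file is read.
    """
    chain_names = chain_names or {}
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    in_first_model = True
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            in_first_model = False
        if rec not in ("ATOM", "HETATM") or not in_first_model:
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: ATOM record truncated before coordinates")
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain_char = line[21].strip() or "A"
        try:
            resi = int(line[22:26])
        except ValueError:
            raise ParseError(
                f"line {lineno}: malformed residue number {line[22:26]!r}"
            ) from None
        x = _parse_float_field(line[30:38], "x coordinate", lineno)
        y = _parse_float_field(line[38:46], "y coordinate", lineno)
        z = _parse_float_field(line[46:54], "z coordinate", lineno)
        element = line[76:78].strip() if len(line) >= 78 else name[:1]
        chain = chain_names.get(chain_char, chain_char)
        atoms.append(Atom(chain, resi, resname, name, element or name[:1]))
        coords.append([x, y, z])
    return Structure(atoms, np.array(coords, dtype=float).reshape(len(atoms), 3))


def _chain_letters(structure: Structure) -> dict[str, str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {}
    for i, cid in enumerate(structure.chain_ids):
        out[cid] = cid if len(cid) == 1 else letters[i]
    return out


def _format_atom_line(serial: int, a: Atom, xyz: np.ndarray, letter: str) -> str:
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4.4s} {a.residue_name:<3.3s} {letter}"
        f"{a.residue_index:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
    )


def write_structure(structure: Structure) -> str:
    """Serialize to PDB text; chain tokens map to letters (A, B, ...)."""
    letters = _chain_letters(structure)
    lines = []
    serial = 0
    prev_chain = None
    for a, xyz in zip(structure.atoms, structure.coords):
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        serial += 1
        lines.append(_format_atom_line(serial, a, xyz, letters[a.chain_id]))
        prev_chain = a.chain_id
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_trajectory_pdb(
    pdb_text: str, chain_names: dict[str, str] | None = None
) -> tuple[Structure, list[np.ndarray]]:
    """Read a multi-model PDB into a template structure plus frame coords."""
    models: list[list[str]] = []
    current: list[str] | None = None
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                models.append(current)
            current = None
        elif rec in ("ATOM", "HETATM") and current is not None:
            current.append(line)
    if not models:
        structure = read_structure(pdb_text, chain_names)
        return structure, [structure.coords.copy()]
    structures = [read_structure("\n".join(m), chain_names) for m in models]
    template = structures[0]
    for s in structures[1:]:
        if s.atoms != template.atoms:
            raise ParseError("trajectory models differ in topology")
    return template, [s.coords for s in structures]


def write_trajectory_pdb(structure: Structure, frames: list[np.ndarray]) -> str:
    """Serialize a coordinate series as a multi-model PDB."""
    letters = _chain_letters(structure)
    out = []
    for m, coords in enumerate(frames, start=1):
        out.append(f"MODEL {m:8d}")
        serial = 0
        for a, xyz in zip(structure.atoms, coords):
            serial += 1
            out.append(_format_atom_line(serial, a, xyz, letters[a.chain_id]))
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Intensity tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityRecord:
    """One amide's peak intensities at two relaxation delays.

    Paramagnetic intensities are ``None`` when the peak is broadened beyond
    detection (the short-distance signature).
    """

    label_site: str
    chain_id: str
    residue_index: int
    I_dia_Ta: float
    I_dia_Tb: float
    I_para_Ta: float | None
    I_para_Tb: float | None

    def __post_init__(self):
        if self.residue_index < 1:
            raise ValidationError("residue_index must be >= 1")
        for name in ("I_dia_Ta", "I_dia_Tb"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValidationError(f"{name} must be positive, got {v}")
        paras = (self.I_para_Ta, self.I_para_Tb)
        if (paras[0] is None) != (paras[1] is None):
            raise ValidationError(
                "paramagnetic intensities must both be present or both missing"
            )
        for name in ("I_para_Ta", "I_para_Tb"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValidationError(f"{name} must be positive, got {v}")

    @property
    def broadened(self) -> bool:
        return self.I_para_Ta is None


_INTENSITY_COLS = [
    "label_site",
    "chain",
    "residue",
    "I_dia_Ta",
    "I_dia_Tb",
    "I_para_Ta",
    "I_para_Tb",
]


def _read_tsv(tsv_text: str, expected_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(_stdio.StringIO(tsv_text), sep="\t", dtype=str)
    if list(df.columns) != expected_cols:
        unknown = [c for c in df.columns if c not in expected_cols]
        missing = [c for c in expected_cols if c not in df.columns]
        raise ParseError(
            f"unexpected table header: unknown columns {unknown}, missing {missing}"
        )
    return df


def read_intensity_table(tsv_text: str) -> list[IntensityRecord]:
    df = _read_tsv(tsv_text, _INTENSITY_COLS)
    records = []
    for row in df.itertuples(index=False):
        def opt(v):
            return None if (v is None or (isinstance(v, float) and math.isnan(v)) or str(v) == "" or str(v) == "nan") else float(v)

        records.append(
            IntensityRecord(
                label_site=str(row.label_site),
                chain_id=str(row.chain),
                residue_index=int(row.residue),
                I_dia_Ta=float(row.I_dia_Ta),
                I_dia_Tb=float(row.I_dia_Tb),
                I_para_Ta=opt(row.I_para_Ta),
                I_para_Tb=opt(row.I_para_Tb),
            )
        )
    return records


def _fmt(v) -> str:
    return "" if v is None else repr(float(v))


def write_intensity_table(records: list[IntensityRecord]) -> str:
    lines = ["\t".join(_INTENSITY_COLS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.label_site,
                    r.chain_id,
                    str(r.residue_index),
                    _fmt(r.I_dia_Ta),
                    _fmt(r.I_dia_Tb),
                    _fmt(r.I_para_Ta),
                    _fmt(r.I_para_Tb),
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# RDC tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RDCRecord:
    """A measured amide N–H residual dipolar coupling in Hz."""

    chain_id: str
    residue_index: int
    D_obs: float
    sigma: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.D_obs):
            raise ValidationError("D_obs must be finite")
        if self.sigma is not None and self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


_RDC_COLS = ["chain", "residue", "D_obs_Hz", "sigma_Hz"]


def read_rdc_table(tsv_text: str) -> list[RDCRecord]:
    df = _read_tsv(tsv_text, _RDC_COLS)
    out = []
    for row in df.itertuples(index=False):
        sigma = row.sigma_Hz
        sigma = None if (sigma is None or str(sigma) in ("", "nan")) else float(sigma)
        out.append(
            RDCRecord(
                chain_id=str(row.chain),
                residue_index=int(row.residue),
                D_obs=float(row.D_obs_Hz),
                sigma=sigma,
            )
        )
    return out


def write_rdc_table(records: list[RDCRecord]) -> str:
    lines = ["\t".join(_RDC_COLS)]
    for r in records:
        lines.append(
            "\t".join(
                [r.chain_id, str(r.residue_index), repr(float(r.D_obs)), _fmt(r.sigma)]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Secondary-structure predictions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSPrediction:
    """Per-residue secondary-structure classes over the alphabet H/E/L."""

    chain_id: str
    ss: str

    def __post_init__(self):
        bad = set(self.ss) - set("HEL")
        if bad:
            raise ValidationError(f"secondary-structure alphabet is H/E/L, got {bad}")

    def __len__(self) -> int:
        return len(self.ss)


_SS_COLS = ["chain", "ss_string"]


def read_ss_prediction(
    tsv_text: str, chain_lengths: dict[str, int] | None = None
) -> list[SSPrediction]:
    df = _read_tsv(tsv_text, _SS_COLS)
    preds = [SSPrediction(str(r.chain), str(r.ss_string)) for r in df.itertuples(index=False)]
    if chain_lengths is not None:
        for p in preds:
            expected = chain_lengths.get(p.chain_id)
            if expected is not None and len(p) != expected:
                raise ValidationError(
                    f"secondary-structure string for chain {p.chain_id} has length "
                    f"{len(p)}, chain has {expected} residues"
                )
    return preds


def write_ss_prediction(preds: list[SSPrediction]) -> str:
    lines = ["\t".join(_SS_COLS)]
    for p in preds:
        lines.append(f"{p.chain_id}\t{p.ss}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Restraint files (TSV + collection sidecar)
# ---------------------------------------------------------------------------


def write_restraints(collections, path: str) -> None:
    """Write distance-restraint collections as a TSV plus a sidecar.

    The TSV carries one row per restraint with columns (label_site, class,
    chain, residue, lower_A, upper_A, k); the sidecar ``<path>.collections``
    records the uniform linear-switch width, and one line per collection with
    its label, active fraction, and member row indices.
    """
    from .restraints import FlatBottomRestraint  # noqa: F401  (type of members)

    rows = ["\t".join(["label_site", "class", "chain", "residue", "lower_A", "upper_A", "k"])]
    side = []
    switches = set()
    row_index = 0
    for coll in collections:
        members = []
        for r in coll.restraints:
            rows.append(
                "\t".join(
                    [
                        r.site_a,
                        r.dclass or "",
                        r.site_b[0],
                        str(r.site_b[1]),
                        repr(float(r.lower)),
                        "inf" if math.isinf(r.upper) else repr(float(r.upper)),
                        repr(float(r.k)),
                    ]
                )
            )
            switches.add(r.linear_switch)
            members.append(str(row_index))
            row_index += 1
        side.append(f"{coll.label}\t{repr(float(coll.active_fraction))}\t{','.join(members)}")
    if len(switches) > 1:
        raise ValidationError(
            "restraint TSV assumes a uniform linear-switch width; got "
            f"{sorted(switches)}"
        )
    switch = switches.pop() if switches else None
    header = f"# linear_switch_A={'' if switch is None else repr(float(switch))}\n"
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    with open(str(path) + ".collections", "w") as fh:
        fh.write(header)
        fh.write("\n".join(side) + ("\n" if side else ""))


def read_restraints(path: str):
    """Read back what :func:`write_restraints` wrote, field-for-field."""
    from .restraints import FlatBottomRestraint, RestraintCollection

    with open(path) as fh:
        tsv = fh.read()
    df = _read_tsv(tsv, ["label_site", "class", "chain", "residue", "lower_A", "upper_A", "k"])
    with open(str(path) + ".collections") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# linear_switch_A="):
        raise ParseError("restraint sidecar missing linear_switch header")
    switch_text = lines[0].split("=", 1)[1]
    switch = None if switch_text == "" else float(switch_text)

    restraints = []
    for row in df.itertuples(index=False):
        dclass = None if (row._1 is None or str(row._1) in ("", "nan")) else str(row._1)
        kwargs = {} if switch is None else {"linear_switch": switch}
        restraints.append(
            FlatBottomRestraint(
                site_a=str(row.label_site),
                site_b=(str(row.chain), int(row.residue)),
                lower=float(row.lower_A),
                upper=float(row.upper_A),
                k=float(row.k),
                dclass=dclass,
                **kwargs,
            )
        )
    collections = []
    for line in lines[1:]:
        if not line.strip():
            continue
        label, fraction, members = line.split("\t")
        idx = [int(i) for i in members.split(",")] if members else []
        collections.append(
            RestraintCollection(
                restraints=[restraints[i] for i in idx],
                active_fraction=float(fraction),
                label=label,
            )
        )
    return collections
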