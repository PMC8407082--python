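"""Paramagnetic relaxation enhancement: rates, distances, and classes.

The transverse PRE rate Γ₂ of an amide proton near a nitroxide spin label is
dominated by the direct electron–proton dipole-dipole interaction (Curie-spin
relaxation is negligible for nitroxides) and follows the Solomon–Bloembergen
form

    Γ₂(r) = (K / r⁶) · [4 τc + 3 τc / (1 + ωH² τc²)]

with K = (1/15) (μ₀/4π)² γH² g² μB² S(S+1), ωH the proton Larmor angular
frequency, and τc = (τr⁻¹ + τs⁻¹)⁻¹ the effective correlation time of the
electron–nucleus vector.  For nitroxides the electron relaxation time τs is
long (> 10⁻⁷ s) so τc is dominated by molecular tumbling τr.

Γ₂ itself is estimated from HSQC peak intensities at two relaxation delays
separated by ΔT:

    Γ₂ = (1/ΔT) · ln[ I_dia(T_b) I_para(T_a) / (I_dia(T_a) I_para(T_b)) ]

Distances invert Γ₂(r) exactly (a sixth root).  Because peaks very close to
the label broaden beyond detection and peaks far away barely change, derived
distances are classified into short / medium / long bands that map to broad
flat-bottom restraint bounds with a ±5 Å buffer for spin-label flexibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import constants as _const

from .io import IntensityRecord

__all__ = [
    "PREConditions",
    "PREMeasurement",
    "BROADENED",
    "UNPERTURBED",
    "SHORT_MAX_A",
    "LONG_MIN_A",
    "BUFFER_A",
    "effective_tau_c",
    "dipolar_constant",
    "gamma2_from_distance",
    "distance_from_gamma2",
    "gamma2_two_point",
    "classify_distance",
    "measurements_from_intensities",
    "write_measurement_table",
]

#: Flag values for unquantifiable peaks.
BROADENED = "broadened"
UNPERTURBED = "unperturbed"

#: Distance-class boundaries and the flexibility buffer, in Å.
SHORT_MAX_A = 12.0
LONG_MIN_A = 20.0
BUFFER_A = 5.0

_GAMMA_1H = _const.physical_constants["proton gyromag. ratio"][0]  # rad s^-1 T^-1
_G_ELECTRON = abs(_const.physical_constants["electron g factor"][0])


def effective_tau_c(tau_r: float, tau_s: float | None = None) -> float:
    """Effective correlation time τc = (τr⁻¹ + τs⁻¹)⁻¹.

    ``tau_s=None`` (or infinity) means the electron relaxation time is long
    enough to ignore, so τc reduces to τr.
    """
    if not tau_r > 0:
        raise ValueError(f"tau_r must be positive, got {tau_r}")
    if tau_s is None or math.isinf(tau_s):
        return tau_r
    if not tau_s > 0:
        raise ValueError(f"tau_s must be positive, got {tau_s}")
    return 1.0 / (1.0 / tau_r + 1.0 / tau_s)


@dataclass(frozen=True)
class PREConditions:
    """Experimental conditions and physical constants of the Γ₂↔r map.

    Defaults are the study conditions of the calmodulin–peptide system: a
    600 MHz spectrometer, τr ≈ 9.5 ns tumbling with effectively infinite
    nitroxide electron relaxation, a 20 ms two-point delay, and an S = 1/2
    nitroxide with free-electron g.
    """

    spectrometer_MHz: float = 600.0
    tau_r: float = 9.5e-9
    tau_s: float | None = None  # None == effectively infinite
    delta_T: float = 0.020
    S_spin: float = 0.5
    g: float = _G_ELECTRON
    gamma_I: float = _GAMMA_1H
    mu_0: float = _const.mu_0
    mu_B: float = _const.physical_constants["Bohr magneton"][0]

    def __post_init__(self):
        for name in ("spectrometer_MHz", "tau_r", "delta_T"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def omega_H(self) -> float:
        """Proton Larmor angular frequency, rad s⁻¹."""
        return 2.0 * math.pi * self.spectrometer_MHz * 1e6

    @property
    def tau_c(self) -> float:
        return effective_tau_c(self.tau_r, self.tau_s)


def dipolar_constant(conditions: PREConditions) -> float:
    """K = (1/15)(μ₀/4π)² γH² g² μB² S(S+1), in m⁶ s⁻²."""
    c = conditions
    return (
        (1.0 / 15.0)
        * (c.mu_0 / (4.0 * math.pi)) ** 2
        * c.gamma_I**2
        * c.g**2
        * c.mu_B**2
        * c.S_spin
        * (c.S_spin + 1.0)
    )


def _spectral_bracket(conditions: PREConditions) -> float:
    tc = conditions.tau_c
    wh = conditions.omega_H
    return 4.0 * tc + 3.0 * tc / (1.0 + wh**2 * tc**2)


def gamma2_from_distance(r_angstrom: float, conditions: PREConditions) -> float:
    """Γ₂ in s⁻¹ for an electron–proton distance r in Å."""
    if not r_angstrom > 0:
        raise ValueError(f"distance must be positive, got {r_angstrom}")
    r_m = r_angstrom * 1e-10
    return dipolar_constant(conditions) / r_m**6 * _spectral_bracket(conditions)


def distance_from_gamma2(gamma2: float, conditions: PREConditions) -> float | str:
    """Distance in Å from Γ₂ in s⁻¹ (exact sixth-root inversion).

    Non-positive Γ₂ — noise making the paramagnetic peak look no weaker than
    the diamagnetic one — is long-distance information, not an error: the
    :data:`UNPERTURBED` flag is returned.
    """
    if not gamma2 > 0:
        return UNPERTURBED
    k_br = dipolar_constant(conditions) * _spectral_bracket(conditions)
    r_m = (k_br / gamma2) ** (1.0 / 6.0)
    return r_m * 1e10


def gamma2_two_point(record: IntensityRecord, delta_T: float) -> float | str:
    """Two-delay Γ₂ estimator; propagates the broadened flag."""
    if not delta_T > 0:
        raise ValueError("delta_T must be positive")
    if record.broadened:
        return BROADENED
    ratio = (record.I_dia_Tb * record.I_para_Ta) / (record.I_dia_Ta * record.I_para_Tb)
    return math.log(ratio) / delta_T


def classify_distance(r_or_flag: float | str) -> tuple[str, float, float]:
    """Map a PRE distance (or flag) to (class, lower bound, upper bound) in Å.

    short  : r ≤ 12  → (0, 17);   broadened peaks are short by construction
    medium : 12 < r < 20 → (r − 5, r + 5)
    long   : r ≥ 20 → (15, ∞);    unperturbed peaks are long by construction

    The short upper bound is the short/medium boundary plus the ±5 Å buffer;
    the long lower bound is the medium/long boundary minus it.
    """
    if r_or_flag == BROADENED:
        return ("short", 0.0, SHORT_MAX_A + BUFFER_A)
    if r_or_flag == UNPERTURBED:
        return ("long", LONG_MIN_A - BUFFER_A, math.inf)
    r = float(r_or_flag)
    if not r > 0:
        raise ValueError(f"distance must be positive, got {r}")
    if r <= SHORT_MAX_A:
        return ("short", 0.0, SHORT_MAX_A + BUFFER_A)
    if r < LONG_MIN_A:
        return ("medium", r - BUFFER_A, r + BUFFER_A)
    return ("long", LONG_MIN_A - BUFFER_A, math.inf)


@dataclass(frozen=True)
class PREMeasurement:
    """A classified PRE-derived distance for one label-site/amide pair."""

    label_site: str
    chain_id: str
    residue_index: int
    gamma2: float | str  # s^-1, or BROADENED/UNPERTURBED
    distance: float | str  # Å, or BROADENED/UNPERTURBED
    dclass: str = field(init=False)
    lower: float = field(init=False)
    upper: float = field(init=False)

    def __post_init__(self):
        dclass, lower, upper = classify_distance(self.distance)
        object.__setattr__(self, "dclass", dclass)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)


def write_measurement_table(measurements: list["PREMeasurement"]) -> str:
    """Serialize classified measurements as TSV."""
    lines = [
        "\t".join(
            ["label_site", "chain", "residue", "gamma2_s-1", "r_A", "class", "lower_A", "upper_A"]
        )
    ]
    for m in measurements:
        g2 = m.gamma2 if isinstance(m.gamma2, str) else repr(float(m.gamma2))
        r = m.distance if isinstance(m.distance, str) else repr(float(m.distance))
        up = "inf" if math.isinf(m.upper) else repr(float(m.upper))
        lines.append(
            "\t".join(
                [m.label_site, m.chain_id, str(m.residue_index), g2, r, m.dclass,
                 repr(float(m.lower)), up]
            )
        )
    return "\n".join(lines) + "\n"


def measurements_from_intensities(
    records: list[IntensityRecord],
    conditions: PREConditions | None = None,
    unperturbed_intensity_ratio: float = 0.95,
) -> list[PREMeasurement]:
    """Full intensity → Γ₂ → distance → class pipeline.

    ``unperturbed_intensity_ratio`` is the relative intensity change below
    which a peak counts as "barely changed": peaks whose implied para/dia
    decay over ΔT stays above this ratio carry only the information that the
    label is far away and are flagged :data:`UNPERTURBED`.
    """
    conditions = conditions or PREConditions()
    if not 0 < unperturbed_intensity_ratio <= 1:
        raise ValueError("unperturbed_intensity_ratio must be in (0, 1]")
    gamma2_floor = math.log(1.0 / unperturbed_intensity_ratio) / conditions.delta_T
    out = []
    for rec in records:
        g2 = gamma2_two_point(rec, conditions.delta_T)
        if g2 == BROADENED:
            distance: float | str = BROADENED
        elif g2 <= gamma2_floor:
            g2 = UNPERTURBED if g2 <= 0 else g2
            distance = UNPERTURBED
        else:
            distance = distance_from_gamma2(g2, conditions)
        out.append(
            PREMeasurement(
                label_site=rec.label_site,
                chain_id=rec.chain_id,
                residue_index=rec.residue_index,
                gamma2=g2,
                distance=distance,
            )
        )
    return out
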