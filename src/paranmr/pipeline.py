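"""Convenience wiring: scenario → simulated data → restraints → toy system.

These helpers chain the forward simulator, the PRE conversion pipeline, the
restraint builders and the sampler setup exactly the way the CLI, examples
and tests do, so the full inference loop is a couple of calls.
"""

from __future__ import annotations

from .io import SSPrediction
from .pre import PREMeasurement, measurements_from_intensities
from .rdc import AlignmentTensor, RDCRestraintConfig
from .restraints import (
    PRE_ACTIVE_FRACTION,
    PRE_FORCE_CONSTANT,
    ReplicaLadder,
    build_pre_collections,
    build_ss_restraints,
)
from .sampler import MoveParams, PriorParams, ToySystem
from .synthetic import SyntheticScenario, simulate_all_pre, simulate_rdc, simulate_ss

__all__ = ["measurements_from_scenario", "system_from_scenario"]


def measurements_from_scenario(scenario: SyntheticScenario) -> list[PREMeasurement]:
    """Simulate every site's intensity table and convert it to distances."""
    records = simulate_all_pre(scenario)
    return measurements_from_intensities(records, scenario.conditions)


def system_from_scenario(
    scenario: SyntheticScenario,
    scheme: str = "by_site_and_class",
    include_rdc: bool = True,
    include_ss: bool = True,
    ladder: ReplicaLadder = ReplicaLadder(),
    prior: PriorParams = PriorParams(),
    moves: MoveParams = MoveParams(),
    active_fraction: float = PRE_ACTIVE_FRACTION,
    force_constant: float = PRE_FORCE_CONSTANT,
) -> ToySystem:
    """Build the restrained toy system for a synthetic scenario.

    ``scheme`` selects the collection grouping: one global collection
    (``"single"``) versus one per (label site, distance class) pair
    (``"by_site_and_class"``).
    """
    measurements = measurements_from_scenario(scenario)
    pre_collections = build_pre_collections(
        measurements, scheme=scheme, k=force_constant, active_fraction=active_fraction
    )
    ss_collections = []
    if include_ss:
        for chain, ss in scenario.ss.items():
            coll = build_ss_restraints(SSPrediction(chain, ss))
            if len(coll):
                ss_collections.append(coll)
    rdc_records = simulate_rdc(scenario) if include_rdc else []
    return ToySystem(
        structure=scenario.structure,
        label_specs=list(scenario.label_sites),
        pre_collections=pre_collections,
        ss_collections=ss_collections,
        rdc_records=rdc_records,
        rdc_config=RDCRestraintConfig(),
        initial_tensor=AlignmentTensor(0.0, 0.0, 0.0, 0.0, 0.0),
        ladder=ladder,
        prior=prior,
        moves=moves,
    )
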