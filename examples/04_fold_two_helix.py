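"""Restrained replica-exchange folding of the two-helix toy.

Builds the full restrained system (PRE collections, secondary-structure
fragments, RDC block with live tensor degrees of freedom) from simulated
data, starts from an extended chain, runs the replica-exchange Monte Carlo
sampler, and prints the backbone-RMSD trajectory of the bottom replica
against the synthetic ground truth.
"""

from paranmr.analysis import backbone_selection, rmsd_distribution
from paranmr.pipeline import system_from_scenario
from paranmr.sampler import run_remc
from paranmr.synthetic import two_helix_scenario

scenario = two_helix_scenario(seed=0)
system = system_from_scenario(scenario, scheme="by_site_and_class")
print(
    f"{sum(len(c) for c in system.pre_collections)} PRE restraints in "
    f"{len(system.pre_collections)} collections, "
    f"{system._n_ss_groups} SS fragment groups, {len(system.rdc_records)} RDCs"
)

traj = run_remc(system, steps=400, seed=0, start="extended", stride=25)
sel = backbone_selection(scenario.structure)
series = rmsd_distribution(traj.frames, scenario.structure.coords, sel)

print(f"move acceptance {traj.acceptance_rate:.2f}, "
      f"exchange acceptance {traj.exchange_rate:.2f}")
print("sweep   RMSD(A)   E_restraint(kJ/mol)")
for i, (rmsd, (ep, er, et)) in enumerate(zip(series.values, traj.energies)):
    print(f"{(i + 1) * traj.stride:5d}   {rmsd:6.2f}   {er:10.1f}")
print(
    f"\nbest frame {series.values.min():.2f} A from ground truth — the chain "
    "collapses from ~20 A (extended) as the restraints and chain prior "
    "take hold; longer runs reach the 2-3 A posterior core."
)
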