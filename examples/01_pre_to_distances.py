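"""PRE pipeline: two-delay peak intensities → Γ₂ → distances → classes.

Forward-simulates one spin-label site's HSQC intensity table on a synthetic
two-helix protein, then runs the conversion pipeline and prints per-residue
Γ₂ rates, derived distances and their short/medium/long classification.
"""

from paranmr.pre import measurements_from_intensities
from paranmr.synthetic import simulate_pre_experiment, two_helix_scenario

scenario = two_helix_scenario(seed=0)
site = scenario.label_sites[0]
records = simulate_pre_experiment(scenario, site.site_name)
measurements = measurements_from_intensities(records, scenario.conditions)

print(f"site {site.site_name} (residue {site.residue_index}):")
print("res   gamma2(s^-1)  r(A)    class   bounds(A)")
for m in measurements:
    g2 = f"{m.gamma2:10.1f}" if not isinstance(m.gamma2, str) else f"{m.gamma2:>10s}"
    r = f"{m.distance:6.1f}" if not isinstance(m.distance, str) else f"{m.distance:>6s}"
    upper = "inf" if m.upper == float("inf") else f"{m.upper:.0f}"
    print(f"{m.residue_index:3d}  {g2}  {r}  {m.dclass:>6s}  [{m.lower:.0f}, {upper}]")

n_short = sum(1 for m in measurements if m.dclass == "short")
print(
    f"\n{len(measurements)} amides: {n_short} short (broadened or <= 12 A), "
    "informative for folding;"
)
print("medium rows carry +/-5 A windows around the derived distance;")
print("long rows only say the amide is far (> 15 A) from the label.")
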