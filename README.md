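# paranmr

Integrative protein-structure inference from **sparse paramagnetic NMR
data**: paramagnetic relaxation enhancements (PRE), residual dipolar
couplings (RDC), and chemical-shift-derived secondary-structure calls.

Large or perdeuterated proteins observed only at their backbone amides
yield almost no NOE contacts, so classical NMR structure determination
fails. PRE experiments with nitroxide spin labels recover long-range
(≲ 25 Å) electron–proton distances, and RDCs recover bond orientations —
but both are sparse, noisy, ensemble-averaged, and contaminated by
spin-label flexibility. This package implements the restraint machinery
that makes such data usable for Bayesian structural inference, and a
desk-scale sampler plus synthetic-data generator so every stage can be
exercised end to end without any experimental input. The intended audience
is structural-biology method developers and students of integrative
modelling.

## What is implemented

* **PRE model** — Solomon–Bloembergen conversion
  Γ₂(r) = (K/r⁶)[4τc + 3τc/(1+ωH²τc²)] with
  K = (1/15)(μ₀/4π)²γH²g²μB²S(S+1); the two-delay intensity estimator
  Γ₂ = (1/ΔT)·ln[I_dia(T_b)I_para(T_a)/(I_dia(T_a)I_para(T_b))]; exact
  sixth-root distance inversion; classification into short (r ≤ 12 Å →
  bounds 0–17 Å), medium (12–20 Å → r ± 5 Å) and long (r ≥ 20 Å → 15–∞ Å)
  restraint bands. Broadened-away and unperturbed peaks are first-class
  flags, not numbers.
* **Restraint engine** — flat-bottom interval penalties (harmonic then
  linear, C¹ everywhere), collections with *active-fraction* selection
  (the ceil(f·N) lowest-energy members count, the rest are presumed
  spurious; f = 0.9 for PRE, 0.95 for secondary structure), per-site ×
  distance-class grouping, 5-residue secondary-structure fragment
  restraints under the 4/5 rule, and a replica ladder with
  temperature/restraint-strength schedules.
* **RDC model** — Saupe contraction D = uᵀAu with the traceless alignment
  tensor in Hz, SVD least-squares fitting, Q-factor, and the 1.5 Hz
  flat-bottom restraint with the five tensor components as live sampler
  degrees of freedom (gradients flow to both atoms and tensor).
* **Spin labels** — each nitroxide is a non-interacting virtual site placed
  deterministically from the host backbone frame; forces project back
  through the analytic Jacobian.
* **Toy sampler** — replica-exchange Metropolis Monte Carlo on a reduced
  backbone (N, H, CA, C beads), with a minimal chain prior standing in for
  the force field and the restraints standing in for the likelihood of the
  posterior p(x|D) ∝ p(x)p(D|x).
* **Synthetic data** — helical toy structures with frozen ground truths and
  a forward simulator of the full experimental design: ten label sites,
  four of ten datasets with detectable peptide, r⁻⁶ ensemble-averaged PRE
  over a jittered label cloud, detection-floor broadening, RDCs from a
  known tensor plus noise.
* **Analysis** — Kabsch superposition, RMSD distributions with equilibration
  discard and tail exclusion, Gaussian-KDE summaries, restraints-per-residue
  statistics.

## Worked example

`examples/03_rdc_tensor_fit.py` simulates noisy couplings on the two-lobe
toy complex and fits the alignment tensor back:

```
58 couplings, 1.0 Hz additive noise
component   truth    fitted
  Axx      4.000    3.942
  Ayy     -9.000   -8.580
  Axy      3.000    2.827
  Axz     -2.000   -2.082
  Ayz      1.500    1.394
Q-factor of the fit: 0.265 (rms residual over rms observed)
flat-bottom restraint energy at the fit: 0.409 kJ/mol (7 couplings outside the 1.5 Hz window)
```

The five fitted components sit within the noise of the ground-truth tensor;
the Q-factor ≈ noise/rms(D) confirms the fit is noise-limited; and the
flat-bottom energy shows why a 1.5 Hz tolerance keeps almost all couplings
penalty-free. `examples/04_fold_two_helix.py` runs the full loop — simulated
PRE + RDC + secondary structure → restraint collections → replica-exchange
folding from an extended chain — and prints the backbone RMSD of the bottom
replica falling from 6.7 Å (post-collapse) to a best frame of 2.70 Å within
400 sweeps, while the restraint energy drops from ~8800 to ~40 kJ/mol; the
remaining examples cover PRE conversion, active-fraction selection and
ensemble analysis (per-lobe RMSD below whole-complex RMSD, restraint
densities per residue).

A thin CLI mirrors the pipeline: `paranmr simulate`, `paranmr convert-pre`,
`paranmr fit-rdc`, `paranmr fold-toy`, `paranmr analyze` (see `--help`).

See `docs/methods.md` for the models, defaults, and limitations.

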