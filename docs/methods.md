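# Methods

This note documents the models, conventions, default parameters and known
limitations of `paranmr`. It is the package's own account of its science;
every number quoted here is either a configurable default or something the
test suite and `scripts/acceptance.py` recompute.

## Problem setting

Sparsely protonated (perdeuterated, amide-labelled) proteins yield too few
NOE contacts for conventional NMR structure determination. Paramagnetic
relaxation enhancement (PRE) from nitroxide spin labels provides long-range
(up to ~25 Å) electron–proton distances instead, and residual dipolar
couplings (RDCs) provide bond-vector orientations. Both observables are
ensemble averages over flexible labels and noisy peak fits, so they are best
treated as *interval* information inside a Bayesian posterior
p(x|D) ∝ p(x)·p(D|x), where a physical prior p(x) supplies what the sparse
data cannot. This package implements the data side of that inference —
observable → restraint conversion, restraint collections with
active-fraction selection, alignment-tensor machinery, spin-label virtual
sites — plus a desk-scale replica-exchange Monte Carlo sampler and a
forward simulator so the whole loop is testable end to end on synthetic
ground truth.

## PRE model

The transverse enhancement for a nitroxide label (Curie-spin relaxation
negligible) is

    Γ₂(r) = (K / r⁶) · [4 τc + 3 τc / (1 + ωH² τc²)],
    K = (1/15) (μ₀/4π)² γH² g² μB² S(S+1),

with τc = (τr⁻¹ + τs⁻¹)⁻¹. Defaults are the study conditions of the
calmodulin–peptide complex: 600 MHz proton frequency, τr = 9.5 ns, τs
effectively infinite (nitroxide), S = 1/2, free-electron g. Γ₂ is estimated
from two HSQC relaxation delays separated by ΔT = 20 ms:

    Γ₂ = (1/ΔT) · ln[ I_dia(T_b) I_para(T_a) / (I_dia(T_a) I_para(T_b)) ].

Distance inversion is the exact sixth root; the forward/inverse pair is
tested to 1e−9 relative.

Distances are classified into bands that become flat-bottom bounds
(all in Å, with a ±5 buffer for label flexibility):

| class  | distance range | bounds        |
|--------|----------------|---------------|
| short  | r ≤ 12         | (0, 17)       |
| medium | 12 < r < 20    | (r−5, r+5)    |
| long   | r ≥ 20         | (15, ∞)       |

Peaks broadened beyond detection carry only "close" information and are
classified short without a numeric Γ₂; peaks whose intensity barely changes
(implied para/dia decay ratio above a configurable threshold, default 0.95
over ΔT) or whose apparent Γ₂ is negative carry only "far" information and
are classified long. The broadened flag is explicit — never encoded as zero
intensity, which would silently poison the log-ratio.

## Restraints and collections

A flat-bottom restraint is zero on [lower, upper]; outside, ½k·Δ² for Δ up
to a switch width (default 3 Å) and then linear with matched slope, so an
extended starting chain never sees enormous forces. The pure-quadratic form
is available by setting the switch to None. The default PRE force constant
is 250 kJ mol⁻¹ nm⁻², converted once at load to 2.5 kJ mol⁻¹ Å⁻² (the
package is Å-internal everywhere).

Collections hold restraints with an active fraction f: each evaluation the
ceil(f·N) lowest-energy members contribute, the rest are ignored as
presumed spurious. `ceil` (not floor) guarantees at least the stated
fraction is enforced for small N; ties break by ascending index so runs are
reproducible. PRE collections default to f = 0.9, grouped either as one
global collection or per (label site, distance class) — the grouping
determines *what* the selector may ignore, and the per-site/class grouping
prevents an entire informative short-distance subset from being discarded,
which the toy trials reproduce qualitatively.

Secondary-structure predictions (H/E/L per residue) become 5-residue
fragment groups wherever ≥ 4/5 of a window shares a helix or extended
call. Each group carries φ/ψ torsion restraints (helix −62.5°/−42.5°,
extended −135°/+135°, tolerance 17.5°/45°, force constant 80 kJ mol⁻¹
rad⁻² — several kT per stray torsion, so secondary structure forms early
and firmly) and Cα(i)–Cα(i+3) windows (helix 4.5–6.5 Å, extended
8.5–11.5 Å). These template values are conventional ideal-geometry choices
exposed as configuration — the underlying experimental pipeline defers them
to external tooling, so they are a modelling decision here, not a measured
quantity. Within a 4/5 window, torsion restraints are applied only to the
residues whose *own* prediction matches the window class: restraining the
one admissible non-conforming residue against its own prediction would
penalize the correct structure and bias sampling toward distorting loops,
so only the distance windows span the full fragment. The fragment
collection uses f = 0.95, letting 5% of fragments disagree with their
prediction.

RDC restraints form their own implicit collection with f = 1: the data are
already tolerance-buffered by the 1.5 Hz flat bottom, and no active
fraction is stated for them.

## RDC model

D_calc = uᵀAu with u the unit N→H vector and A a traceless symmetric
tensor carrying Hz units — the dipolar prefactor is absorbed into A, which
makes the tensor fit strictly linear in its five components and avoids
unit-sensitive physical constants. The SVD least-squares fit is the
classical baseline and doubles as an oracle: with tolerance 0, minimizing
the flat-bottom energy over the tensor components alone must land on the
SVD solution (tested to 1e−6). During sampling the five components are
live auxiliary degrees of freedom updated by the same Metropolis kernel as
the coordinates; this follows the "tensor as dynamical variable" treatment
and is contractually equivalent to (not bit-identical with) encodings that
park the components on dummy particles. Defaults: tolerance 1.5 Hz, k =
0.5 kJ mol⁻¹ Hz⁻². Experimental sigmas are carried for reporting but do
not reweight the restraint.

## Spin-label virtual sites

Each label is one non-interacting dummy point placed deterministically from
the host residue's backbone frame (N, CA, C) by internal coordinates.
Defaults (7.0 Å from Cα, 115° to N, −120° dihedral to C) put the point
roughly along the Cβ direction at the nitroxide-oxygen mean distance; they
are **approximate placeholders** for a dynamics-matched MTSL
parameterization, exposed per site in configuration. Because the placement
map is differentiable, restraint forces on a site project exactly onto the
frame atoms via the analytic Jacobian transpose (total force conserved;
checked against central differences at 1e−6). Sites carry no pairwise
interactions, so all ten study sites coexist in one system without touching
the unrestrained energy. Label positional heterogeneity is *not* modelled
by the site itself — it is absorbed by the ±5 Å restraint buffer, and in
the forward simulator by an explicit Gaussian cloud.

## Toy sampler

The sampler is Metropolis Monte Carlo, not molecular dynamics: the target
of this package is the restraint/posterior machinery, not an integrator,
and a force field is out of scope. Each residue is four beads (N, H, CA,
C). The chain prior is harmonic bonds and angles at ideal backbone
geometry, peptide-plane restoring torsions (ω and the amide-H improper),
and a soft Cα excluded-volume term (diameter 3.5 Å, safely below the
~4.7 Å closest Cα approach of packed helices — wide enough to forbid chain
crossings, narrow enough not to block rearrangements; a larger diameter
measurably traps misfolded intermediates) — just enough physics to keep
chains chain-like; it encodes no attraction, so all structure comes from
the restraints. Moves: φ/ψ pivot rotations (exact torsion moves that
preserve bond geometry; the proposal is a Gaussian mixture whose 20% "jump"
component crosses torsion basins in one step, and proposal weight is higher
for residues outside secondary-structure fragments — both fixed
distributions, so detailed balance holds), crankshaft rotations between two
Cα pivots, small single-bead displacements, rigid-body moves of secondary
chains, and Gaussian moves of the tensor components. Move amplitudes scale
down toward the bottom replica so cold replicas refine while hot ones
explore.

Replica exchange uses a geometric temperature ladder (default 8 replicas,
300–500 K) with the restraint energy scaled by α(replica), decreasing
linearly from 1 at the bottom to a configurable minimum at the top;
nearest-neighbour swaps alternate parity and use the standard two-state
acceptance ratio, which needs no re-evaluation because prior and restraint
energies are cached separately. One master seed spawns independent
per-replica streams, so trajectories are bit-reproducible. Recorded frames
are whatever configuration currently occupies the bottom (coldest, fully
restrained) replica; stored energies re-evaluate exactly.

The ladder schedules are package defaults, not values taken from any
experimental protocol (production replica-exchange schedules live in
supplementary material we deliberately do not model).

## Synthetic data

The generator emulates the study's design on small helical toys built from
ideal internal coordinates (φ/ψ −60°/−45° helices):

* a two-helix fold (10+4+10 residues) used for sampler recovery tests;
* a two-lobe toy — two helix–turn–helix lobes joined by a 4-residue linker
  with an 8-residue helical peptide docked between the lobes (50 + 8
  residues) — mirroring a calmodulin-like two-domain complex, with ten
  label sites spread along the protein of which a fixed four see the
  peptide (the study design has 4 of 10 datasets with labelled peptide).

PRE forward model: label positions are drawn as an isotropic Gaussian cloud
(sd 2 Å, 50 draws per site — one cloud shared by all amides) around the
virtual site; Γ₂ uses the r⁻⁶ ensemble average over the cloud; intensities
decay exponentially at two delays (T_a = 10 ms, T_b = 30 ms, diamagnetic
R₂ = 15 s⁻¹, base intensity 1000) with multiplicative log-normal noise
(sd 0.02); peaks with I_para/I_dia below 0.05 at T_b are emitted as
broadened. RDCs are uᵀAu from a fixed rhombic ~10 Hz ground-truth tensor
plus additive Gaussian noise (sd 0.5 Hz). The intensity and RDC noise
levels are plausible placeholders — the source experiments do not quantify
theirs. What the generator does **not** emulate: peak overlap, spin
diffusion, diamagnetic contamination, label rotamer anisotropy, or any
force-field physics; passing tests therefore validate the inference
machinery, not performance on real spectra.

## Problem sizes and numerical choices

Desk-scale throughout: toy recovery runs use the 24-residue two-helix
scenario with four label sites, 8 replicas on a 300–420 K ladder with the
restraint scale bottoming at 0.25, exchanges every 3 sweeps, and ~1100 MC
sweeps per seed — sizes chosen so the full suite runs on a single CPU in
minutes. Under these conditions the sampler reaches best-frame backbone
RMSDs of ~1.6–2.0 Å from an extended start across seeds. Quantities with exact
contracts are tested at tight tolerances (Γ₂↔r round trip 1e−9 relative,
C¹ continuity of the penalty at 1e−10, force/gradient checks at 1e−5–1e−6
absolute against central differences); stochastic claims (recovery RMSD,
grouping comparisons) use seeded majorities over 5 seeds. Degenerate
inputs are contracts, not surprises: empty collections, all-zero observed
RDCs, collinear superposition sets, zero-variance KDE samples and
non-positive Γ₂ all have defined behaviour (error or flag) with tests.

## Known limitations

* Single-structure likelihood only: each sampled structure must satisfy the
  (buffered) data individually; genuinely heterogeneous ensembles are out
  of scope, as is hyperparameter inference over buffers/fractions.
* One alignment medium; no dynamics extraction from RDCs.
* The MC prior is not a force field; sidechains do not exist, so nothing
  can be said about packing.
* Virtual-site geometry defaults are approximate; users with a calibrated
  label model should override the per-site internal coordinates.
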