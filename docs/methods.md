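# Methods

## The NAC model

A near-attack conformation (NAC) is a ground-state Michaelis-complex
geometry in which the bond-forming atoms are in van der Waals contact and
the attack angle is near its transition-state value. `nacscreen`
represents a NAC model as a named *conjunction* of criteria over atom
selectors (chain, author residue number, atom name, optional
enzyme/ligand entity tag):

* **Distance criteria** pass on strict `d < threshold`. The threshold is
  either explicit (e.g. 4.0 Å for a carboxylate-oxygen-to-epoxide-carbon
  attack) or the sum of the two atoms' van der Waals radii. Radii are the
  Bondi (1964) set (C 1.70, N 1.55, O 1.52, S 1.80 Å, …), shipped as a
  constant table; unknown elements are a hard error, never a silent
  default. The radius set is a convention choice — other tables differ by
  a few hundredths of an Ångström — and can be bypassed with explicit
  thresholds.
* **Angle criteria** pass on `|measured − target| ≤ tolerance`. "Similar
  to the transition state" is not quantified in the NAC literature, so the
  target is user-supplied and the default tolerance is 20°.

Strict `<` for distances versus `≤` for angle tolerances is a documented
convention; equality at a float boundary is astronomically unlikely, so
the choice has no practical effect but fixes the semantics of edge tests.

Only conjunction is supported: published NAC definitions never combine
criteria disjunctively. Mechanisms with alternative attack atoms (either
epoxide carbon, say) are handled by declaring two models and OR-ing the
masks at the pipeline level — an explicit composition rather than a model
feature.

A frame is *active* iff every criterion passes. The population of an
ensemble is `P = N_active / (N_active + N_inactive)`, the binomial MLE of
the per-frame active probability. Replicates aggregate as the unweighted
mean of per-trajectory P (each trajectory counts once regardless of frame
count); frame-pooling is available as an option but is not the default,
because replicate trajectories are independent estimates of the same
quantity and should not be weighted by length. Variant-versus-reference
calls are strict (`P_variant > P_ref` ⇒ "higher", ties ⇒ "lower"), with
no dead band. Docked-pose sets are classified identically to trajectory
frames; pose gating simply discards inactive poses.

Uncertainty on P uses a percentile bootstrap over frames (default 1000
resamples, 95% level, seeded). I.i.d. resampling ignores the
autocorrelation of MD frames; a moving-block bootstrap with configurable
block length is provided for correlated input. Constant masks yield the
degenerate interval [P, P], flagged in the log.

## Structures and selectors

PDB parsing and writing are delegated to biotite. Author residue
numbering is kept verbatim (mutation tokens like `D192` are
author-numbered); altloc conflicts resolve to the highest occupancy with
ties to first occurrence; insertion codes are part of residue identity;
elements come from columns 77–78 or are inferred from the atom name;
hydrogens and waters are retained (criteria may reference hydrogens,
callers filter waters). Multi-model PDB carries trajectories and pose
sets; XYZ input is accepted with a PDB topology. Units are Å and degrees
throughout. Selector resolution is total: exactly one atom or a typed
error naming the nearest residue (not found) or all matches (ambiguous).

## Mutation spaces and mutant building

Mutations are `X#Y` tokens; a variant is a set of mutations at distinct
positions (the empty set is wild type, id `WT`). Single-point saturation
over N positions yields 19·N variants in a fixed order (position
ascending, mutant letter alphabetical); x-point combination spaces have
exactly C(N, x)·19^x members. Substrate shells ("all residues within 12 Å
of the bound ligand") include a residue iff any of its heavy atoms lies
within the radius of any ligand heavy atom — the reference-point choice
is not standardised, so a Cα-based alternative is available. Catalytic
and substrate-anchoring residues are excluded only via an explicit
user-supplied exclusion list, never inferred.

Mutant structures are built by side-chain grafting: the backbone and all
other residues are untouched; the new residue's ideal heavy-atom side
chain (CCD template, via biotite) is aligned on the existing N/CA/C by
Kabsch superposition; a discrete rotamer grid — χ1 and χ2 over
gauche−/gauche+/trans, at most 9 rotamers, deeper χ kept at template
values — is scanned and the placement with the fewest steric clashes
wins, ties to the first rotamer in library order. A clash is a non-bonded
heavy-atom pair closer than 0.6 × (vdW_i + vdW_j), exempting same-residue
and adjacent-backbone pairs; 0.6 tolerates normal packing contact while
flagging genuine overlap. This deterministic scan is a surrogate for
force-field side-chain relaxation: it is reproducible and cheap, but it
cannot relieve backbone strain, and residual clashes above a configurable
cap (default 0) mark the variant *unbuildable* rather than passing
silently. Glycine targets strip the side chain; proline positions are
mutable but logged, and proline's ring is kept at template geometry.
Backbone-attached hydrogens are retained; side-chain hydrogens are not
rebuilt.

## Surrogate samplers

Real screens sit downstream of docking and MD. Two desk-scale stand-ins
make the pipeline testable without external engines; neither claims the
physics of a solvated force field, and populations computed with them are
properties of the surrogate, not predictions for real systems.

**Exact-fraction synthesis.** `synth_trajectory` constructs an ensemble in
which exactly `round(f·n)` frames are active: criterion atoms are placed
at `threshold·(1 − margin)` (active) or beyond it (inactive), angles at
their targets, with the margin set to exceed the worst-case displacement
from coordinate jitter (each atom moves at most `jitter` Å, so a pair
distance moves at most `2·jitter`; angle perturbations are bounded by
`asin(2·jitter/arm)` per arm). Jitter too large to guarantee the class
boundary is a configuration error, and the jitter-free base frames are
re-verified against the model in case criteria share atoms and fight each
other. Frame order is a seeded permutation. This generator is ground
truth for classifier and population tests; what it does *not* emulate is
the smooth, autocorrelated geometry distribution of real dynamics.

**Metropolis pocket sampler.** A rigid ligand moves in a model pocket
with energy (kT units) `E = ½k(d − d0)² + Σ wall_k·(r_wall − r)²` over
anchor–ligand pairs closer than the wall radius, where `d` is the
attack-pair distance. Proposals are isotropic Gaussian translations
(default 0.3 Å per axis) plus, for multi-atom ligands, rotations about
the centroid (default 5°); Metropolis acceptance at temperature factor T.
The ligand starts at the well centre, so burn-in is negligible. Defaults:
`d0 = 3.5 Å`, `k = 4 /Å²`, wall radius 2.0 Å, `wall_k = 10`, T = 1 —
a well width (σ ≈ 0.5 Å) comparable to the fluctuation of a bound
substrate's attack distance, giving populations in the informative
mid-range for a 4 Å threshold. Acceptance rate is logged, and zero
acceptances over a window raises a non-ergodicity warning.

Its oracle: for a freely translating ligand, the equilibrium radial
marginal of the attack distance is `p(d) ∝ d²·exp(−E(d)/T)` — the `d²`
volume factor is the 3-D translational Jacobian, and omitting it (i.e.
treating the marginal as a plain 1-D Gaussian) biases P(d < 4 Å) by ~0.1
on the default pocket, far beyond sampling noise. `nac_probability`
therefore integrates the full radial weight (with the wall term) by
quadrature. This is exact for a single-atom ligand with one anchor and a
documented reduced-coordinate approximation otherwise; tests compare the
sampler to it within 3 standard errors, with the SE estimated by block
averaging to absorb Monte Carlo autocorrelation. Variant pockets are
modelled by shifting `d0` and `k` (`mutate_pocket`), which makes expected
populations monotone in the perturbation and gives screens a known
ground-truth ordering.

## Pipeline and determinism

`screen` runs mutate → sample/ingest → classify → rank per variant,
fail-soft: a per-variant failure is recorded and the run continues, and
every requested variant ends in exactly one terminal status (classified,
unbuildable, no-NAC-pose, failed). Variants whose docked poses all fail
the NAC gate are excluded from the ranking by default — dynamics is only
meaningful from a catalytically consistent starting pose — with a
zero-score policy available instead. Per-replicate seeds derive from
`SeedSequence([seed, variant_index, replicate])`, so identical config +
seed reproduces every output byte for byte; wall-times live only in the
manifest. Per-variant work is independent and could be parallelised
without changing results; the implementation is serial.

## Problem sizes

The shipped tests and the reproduction script run at desk scale chosen to
make every statistical check decisive: 1000-frame ensembles for
classifier/oracle sweeps (20 random models), 50 000 Metropolis steps at
stride 10 (≈1.4 % relative SE on P), 500 regenerations × 200 bootstrap
resamples for coverage, and 3-variant surrogate screens at 4000 steps per
replicate. All sizes are parameters, not limits.

## Known limitations

* NAC populations proxy the chemistry's *geometric* readiness only;
  hydrolytic half-reactions, expression, solubility and stability are out
  of scope, and high-P variants can still fail experimentally for those
  reasons.
* The rotamer grid is backbone-independent and coarse (3 values per χ,
  two χ max); it is a steric feasibility screen, not an energy model.
* The bootstrap default ignores frame autocorrelation (see block option).
* The pocket surrogate has one reaction coordinate; real ensembles
  couple many. Conclusions from surrogate screens are about the pipeline,
  not about enzymes.
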