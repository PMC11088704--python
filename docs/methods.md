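# Methods

This note documents the models and procedures implemented in `premodel`,
the defaults that matter, what the synthetic generator does and does not
emulate, and the design decisions taken where the methodology is genuinely
open.

## Shift analysis

**CSP.** The composite amide perturbation is Δδ = √(Δδ_H² + (Δδ_N/6)²);
the 1/6 factor maps ¹⁵N changes onto the ¹H scale. Residues amide-assigned
in only one state are flagged (`missing_in_complex` marks candidates for
intermediate-exchange broadening) rather than given a value. Prolines and
residues without amide data never enter the CSP.

**Secondary shifts and SSP.** Secondary shifts are δ_obs − δ_rc with a
pre-proline neighbour correction. The packaged random-coil table
(`premodel/data/random_coil.tsv`) holds classical peptide random-coil values
(GGXGG-type scales, pH ≈ 5, 25 °C) for Cα/Cβ/H^N plus consensus full-helix
and full-strand average secondary shifts; users may substitute their own
table in the same format. The SSP score of residue *i* sums sign-aligned,
weighted secondary shifts over an odd window (default 5) and divides by the
matching weighted reference magnitude — full-helix magnitudes when the
numerator trends positive, full-strand otherwise — so that fully formed
helix scores +1 and fully formed strand −1. Defaults: weights Cα = Cβ = 1.0,
H^N = 0.3 (amide protons are perturbed by ring currents and hydrogen
bonding); outliers |Δδ_sec| > 5 ppm (carbons) / 1.5 ppm (H) are excluded;
|score| is capped at 1.15 to absorb reference-table overshoot. Exact SSP
values depend mildly on the reference table and weighting, which is why the
table is pinned as package data.

## PRE quantification and restraints

Γ₂ is defined as R₂(paramagnetic) − R₂(diamagnetic) — positive for
paramagnetic broadening — with uncertainties combined in quadrature. A
two-point intensity-ratio alternative, Γ₂ = −ln(I_para/I_dia)/Δt with
optional median normalisation over unaffected reference residues, is
provided for data sets without fitted rates.

The Solomon–Bloembergen conversion uses
Γ₂ = K r⁻⁶ (4τ_c + 3τ_c/(1+ω_H²τ_c²)) with
K = (μ₀/4π)² γ_H² g² μ_B² S(S+1)/15. The effective correlation time τ_c is
rarely measured; it is a required parameter (default 8 ns, typical for a
~20 kDa complex). Restraint *distances* depend on it only as τ_c^{1/6}, so a
twofold error in τ_c moves a 20 Å restraint by ~2.5 Å.

**Tag model.** The paramagnetic centre sits on a long flexible tether and is
never observed directly. Each labelling site is represented by `n_pseudo`
(default 3) pseudo-positions fanned 25° around the Cα→Cβ axis at
`centroid_offset` (default 8 Å) from Cβ. Every distance involving a site —
back-calculation *and* restraint evaluation — is the r⁻⁶ average
r_eff = (⟨r_k⁻⁶⟩)^{−1/6} over the fan, which is also how the experiment
weights tag conformers. Using one consistent forward model makes the
noiseless closure exact: restraints generated from simulated data are
satisfied identically by the generating pose.

**Restraint policy.** Residues with Γ₂ ≥ threshold (default
max(20 s⁻¹, 2× median of the quantified Γ₂)) yield flat-bottom restraints
with target sb_distance(Γ₂) and bounds from propagating ±σ(Γ₂), floored at
±0.5 Å (a 1 Å flat region). Two one-sided classes capture the rest of the
information in a PRE data set and are enabled in the synthetic study:

* *weak residues* (Γ₂ below threshold) must be **far** from the tag; the
  lower bound defaults to sb_distance(1.25 × threshold), i.e. the distance
  the sub-threshold rate implies with a 25% noise margin on Γ₂ (a fixed
  absolute bound can be configured instead);
* *residues broadened beyond detection* in the paramagnetic sample must be
  **near** the tag; the upper bound defaults to
  sb_distance(detection ceiling / 1.25).

Restraints attach to the amide proton (the nitrogen as fallback, with
bounds widened by 1 Å). A mutagenesis-derived contact is expressed as a
Cβ-to-midpoint-of-two-Cβ restraint with ±0.5 Å bounds.

## Energy model and sampling

The composite potential is a weighted sum of (i) flat-bottom restraint
terms (k = 2.0 kcal mol⁻¹ Å⁻²), (ii) soft-sphere excluded volume over
non-bonded pairs (element radii × 0.85, k_rep = 1 kcal mol⁻¹ Å⁻²;
intra-residue, adjacent-residue and rigid-body-internal pairs excluded),
(iii) an optional one-sided radius-of-gyration collapse term, and (iv) an
optional inter-chain backbone H-bond reward (off by default — in testing it
stabilised spurious docking modes more than it helped). Peptide residues
carry backbone N, H, Cα, C, O plus a Cβ pseudo-side-chain.

Sampling is Metropolis Monte-Carlo with simulated annealing:

* geometric temperature ladder, 10 stages from 5.0 to 0.05 reduced units,
  with step counts weighted toward the cold stages;
* two annealing cycles per trajectory, each beginning from a fresh random
  rigid-body placement; the first cycle ramps the excluded-volume weight
  from 1% to 100% (restraints can thread the chain before sterics harden);
* each cycle starts with a rigid-body-only pre-docking stage (3 000 steps,
  T = 2, soft sterics) that places the whole peptide in the
  data-consistent region; all pre-docking steps count against the overall
  step budget;
* moves: backbone pivot torsions (the smaller side of the chain rotates,
  so every bond is a local move), rigid-body rotations and translations
  (0.6/0.2/0.2); move sizes shrink as √(T/T_max);
* pivot proposals are rejected if they take φ outside [−160°, −45°] or ψ
  outside [−75°, 170°] — a broad allowed-basin prior standing in for the
  backbone torsion potential the coarse model lacks;
* snapshots are collected only at cold (T ≤ 0.5), fully-steric stages, so
  the selection pool contains converged conformers.

Four independent 50 000-step trajectories are the default production
setting; the toy systems make this a minutes-scale computation on one core.
Identical seeds reproduce bit-identical trajectories.

**Selection.** Per conformer, Γ₂ is back-calculated for every site and
pooled; the Pearson correlation R against the experimental values scores
the conformer (per-conformer correlation, so an ensemble is reported as
mean ± sd of R; an ensemble-averaged r⁻⁶ mode is available). Before
ranking, the pool is filtered to restraint-consistent conformers (smallest
violation count that leaves at least the requested number, violations
counted beyond a 0.5 Å tolerance): a conformer must satisfy the distances
before its correlation is meaningful, and ranking unfiltered pools by R
alone can prefer strained geometries that fit the noise. Ties in R break by
fewer violations, then lower energy, then model id, making the selection
independent of input order.

A note on uniqueness: distances to the pseudo-positions of *n* label sites
determine a position only up to reflection across the plane through the
three site centroids (for n = 3). The toy study therefore places its three
sites so that the mirror image of the docked segment falls inside the
receptor body and is removed by sterics; one-sided restraints from weak and
broadened residues further disambiguate. Real studies face the same
degeneracy, which is one reason several, well-spread labelling sites are
used.

## Ternary protocol

A representative binary conformer is superposed onto a receptor–DNA
template (or, in toy mode, an ideal B-form phosphate-backbone trace —
rise 3.4 Å, twist 36°, P-atom radius 9.4 Å — is placed on the far side of
the receptor). Mobile N-terminal residues missing from the binary model are
grown with sequential clash-free chain extension. Each of 120 independent
runs randomizes the mobile-segment torsions, then anneals with only those
torsions active; the receptor, DNA and the determined peptide segment are
bit-identical across all outputs. The collapse term
rg_k·(Rg − rg_target)² (one-sided, target defaulting to the DNA's own Rg
plus 2 Å) acts on the basic-cluster + DNA selection. The 20 lowest-energy
conformers are kept.

## Synthetic generator

The toy complex emulates the statistical structure the analysis assumes: a
5 × 8-residue parallel β-sheet receptor (5.2 Å strand spacing) with three
cysteine label sites; a 35-residue peptide whose residues 51–66 dock as an
extra edge strand (the C-terminal eight pair with the docking strand; the
taut extended remainder runs off the sheet corner), flanked by
self-avoiding coil; label sites chosen so that several bound-segment amides
fall inside the quantifiable Γ₂ window of each site and the mirror pose is
sterically blocked. Simulated Γ₂ values are multiplicative-noise corrupted
(cv = 0.10 by default; PRE errors grow with the rate), residues 52–57 are
removed entirely (exchange-broadened block), and residues whose noiseless
Γ₂ exceeds a 150 s⁻¹ detection ceiling stay in the table flagged as missing
in the paramagnetic state. Shift tables are random-coil values plus
per-nucleus measurement noise; the bound state adds log-normal amide
perturbations (median composite CSP 0.08 ppm) and fractional-strand
secondary shifts (default population 0.6) inside the bound segment.

What the generator does **not** emulate: chemical exchange between free and
bound states (real apparent Γ₂ values are population- and kinetics-weighted),
tag rotamer dynamics beyond the static fan, scalar/cross-correlated
relaxation contributions, spectral overlap, and sequence-dependent coil
behaviour. Passing recovery tests therefore demonstrate the soundness of the
inference chain under the stated noise model, not performance on any real
spectrum.

## Numerical choices

* Kabsch superposition via SVD-backed rotation alignment; collinear or
  <3-atom selections raise.
* Pairwise ensemble RMSD superposes each pair on the same selection the
  RMSD is computed over.
* Ramachandran classes come from an explicit rectangular φ/ψ grid shipped
  as package data; different checkers draw these contours differently, so
  fractions are comparable only within one grid. Residues with missing
  backbone atoms are skipped, not fatal.
* Flat-bottom energies are exactly zero inside the bounds; the first
  derivative vanishes at both edges.
* Chain growth and pose construction use rejection sampling with documented
  retry limits (100 for extensions/randomization, 300 for toy poses); a
  deterministic RNG stream is derived from the user seed for every source
  of randomness.
* Γ₂ inversion requires Γ₂ > 0; non-positive values are routed to the
  one-sided restraint classes, never inverted.

## Known limitations

* The sampler is a coarse-grained stand-in for force-field dynamics: its
  ensembles satisfy data and excluded volume but have no realistic
  energetics, so ensemble statistics (pairwise RMSD, Ramachandran
  fractions) characterise the restraint-consistent conformational spread,
  not a thermodynamic ensemble.
* Ground-truth interface-contact recovery on the synthetic study runs at
  the edge of what the engine delivers (a fifth of the truth contacts sit
  within 0.5 Å of the 8 Å contact cutoff or involve residues carrying only
  one-sided restraints); seed-to-seed variation of a few percent around the
  target level is expected.
* The detection-ceiling and noise models are deliberately simple; with real
  data the Γ₂ uncertainty column should come from the rate-fitting
  procedure.
* mmCIF output, hydrogen placement and crystallographic symmetry are out of
  scope; PDB is the only coordinate format.
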