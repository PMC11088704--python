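# premodel

Ensemble modelling of complexes between an intrinsically disordered peptide
and a folded domain, driven by solution-NMR observables: chemical shift
perturbations (CSP), secondary-structure propensities (SSP), and — centrally —
paramagnetic relaxation enhancements (PRE).

Such complexes are often too dynamic for NOE-based structure determination:
large parts of the peptide broaden beyond detection on binding, and the few
observable contacts do not define a structure. `premodel` implements the
standard rescue strategy end to end:

1. **Map the binding segment** from shift data. Composite amide CSPs
   Δδ = √(Δδ_H² + (Δδ_N/6)²) locate perturbed residues; windowed SSP scores
   built from Cα/Cβ/H^N secondary shifts (+1 = fully formed helix, −1 = fully
   formed strand) reveal binding-induced secondary structure; residues that
   vanish in the complexed spectrum flag intermediate-exchange broadening.
2. **Convert PREs into long-range distance restraints.** A paramagnetic tag
   (e.g. an Mn²⁺-chelating maleimide on an engineered cysteine) enhances the
   transverse relaxation of nearby amides by

   Γ₂ = K · r⁻⁶ · (4τ_c + 3τ_c / (1 + ω_H²τ_c²)),

   the Solomon–Bloembergen relation, with K assembled from fundamental
   constants and S(S+1) (S = 5/2 for Mn²⁺). The inversion r = (K·J(τ_c)/Γ₂)^{1/6}
   is analytic. Quantifiable Γ₂ values become flat-bottom distance restraints
   (zero inside [lower, upper], harmonic outside, k = 2.0 kcal mol⁻¹ Å⁻²,
   1 Å flat region); residues with negligible PRE optionally yield
   lower-bound-only restraints, and residues broadened beyond detection
   upper-bound-only restraints. Tag flexibility is modelled as a fan of
   pseudo-positions around the Cα→Cβ axis with r⁻⁶ averaging.
3. **Sample restrained conformations** of the flexible peptide on the rigid
   receptor with a Metropolis Monte-Carlo / simulated-annealing engine
   (backbone pivot torsions plus rigid-body moves, soft-sphere excluded
   volume, excluded-volume ramping, rigid-body pre-docking).
4. **Select the representative ensemble**: per conformer, back-calculated Γ₂
   values are pooled over all label sites and correlated (Pearson R) with
   the experimental profile; the best-correlating restraint-consistent
   conformers represent the complex.
5. **Extend to a ternary complex with DNA**: with the receptor, DNA and the
   determined peptide segment held rigid, the disordered N-terminal tail is
   re-sampled under a one-sided radius-of-gyration "collapse" restraint that
   draws a basic cluster toward the DNA; of 120 randomize-and-anneal runs
   the 20 lowest-energy conformers are kept.

A synthetic-data module generates toy complexes with known ground truth
(a small β-sheet receptor, a 35-residue peptide docking as an extra edge
strand, simulated Γ₂ and shift tables with realistic noise and missing data),
so the entire pipeline is testable without any downloads.

## Worked example

Generate a complete synthetic input tree, then run every stage:

```bash
python -c "import premodel; premodel.write_fixtures('fixtures')"
premodel run --config fixtures/config.txt --outdir out --seed 1
```

Artifacts land in `out/`: `csp.tsv`, `ssp_free.tsv`/`ssp_bound.tsv`,
per-site `pre_*.tsv`, `restraints.tsv` (plus an Xplor-style export),
`trajectory.pdb`, `selected.pdb`, `ternary_selected.pdb` and a
`report.txt` with ensemble statistics.

The same study, run as a library (this is what `scripts/acceptance.py`
executes; numbers below are its output for `--seed 1`):

```python
from premodel.cli import binary_recovery_study, ternary_collapse_study
study = binary_recovery_study(seed=1)       # ~2 min on one core
print(study["mean_R"], study["contact_recovery"])
```

```
selected_ensemble_mean_R        0.956   # Pearson R, back-calculated vs experimental Γ₂
contact_recovery_fraction       0.735   # ground-truth Cβ–Cβ < 8 Å contacts recovered
negative_control_recovery       0.0     # restraint weight 0 → interface lost
restraint_closure_energy_kcal   0.0     # noiseless restraints are satisfied exactly by the truth
ssp_bound_segment_mean          -0.53   # β propensity recovered in the bound segment
ternary_rg_with_collapse_A      21.2    # collapse term pulls the tail to the DNA
ternary_rg_without_collapse_A   38.3
```

Read: the 20 selected conformers back-calculate the experimental PRE profile
with R ≈ 0.96, recover ~74% of the true interface contacts (none without
restraints), and the ternary collapse restraint compacts the lysine
cluster + DNA selection from ~38 Å to ~21 Å radius of gyration.

## Selections

Atom selections use `chain:resid_range:atom_names`, e.g. `B:51-66:CA`,
`A::N,CA,C` (all receptor backbone), `B:38-42 D E` (union of terms).

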