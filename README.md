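# softdock

Rigid-body protein–protein docking by FFT-accelerated correlation with
atomic-solvation-parameter (ASP) scoring, plus **soft binding-site
restraints**: a way to use *predicted* — and therefore not always
reliable — binding-site information during sampling without being
destroyed by it when the prediction is wrong.

## The problem

FFT docking methods score every rigid placement of a ligand protein on a
receptor by a grid correlation. Binding-site predictions (from sequence
conservation, interface predictors, antibody CDR definitions, …) can
sharpen the search dramatically, but hard constraints — masking the
search region or filtering poses — fail completely when the predicted
site is wrong, and predictors are right only roughly a third of the
time. `softdock` implements the *soft* alternative: multiply the ASP
values of the predicted **key residues** by a weight factor α > 1,

```
asp'_i = α · asp_i   if atom i belongs to a key residue,
asp'_i = asp_i       otherwise.
```

ASP values are negative by convention, so the surface-contact reward for
burying a key residue grows with α while every other pose keeps its
original score. The search is *biased toward* the predicted site, never
*restricted to* it: with correct information near-native poses climb the
ranking; with wrong information a genuinely well-scoring near-native
pose still survives. The default α = 1.5 comes from a grid search over
1.0–3.0 in steps of 0.1.

## The score

Receptor and ligand are projected on a cubic lattice (1 Å default) as
two channels: a **core** channel marking every cell inside an atom's
van der Waals sphere, and a **surface** channel carrying summed ASP
values on the one-cell solvent-side skin. The score of a relative
integer shift **s** at a given rotation is the correlation

```
S(s) = Σ_x  surf_R(x) · surf_L(x−s)  −  ρ · Σ_x  core_R(x) · core_L(x−s)
```

with overlap penalty ρ = 20. Rotations are sampled on a z-y-z Euler
grid (10° default, pole-deduplicated); for each rotation the full
translation field is computed at once via FFT cross-correlation, the
best 3 shifts per rotation are pooled, and the global top 2000 poses
are kept. Evaluation follows CAPRI practice: ligand RMSD (LRMSD) after
receptor superposition, a *hit* being LRMSD ≤ 10 Å within the top 2000.

## Worked example

Everything is testable offline on generated toy complexes — a solid
pseudo-protein with an asymmetric socket and the complementary knob,
with known native pose and labeled interface:

```sh
softdock make-fixtures --seed 2 --out fix/
softdock dock -r fix/receptor.pdb -l fix/ligand.pdb --step 90 --keep 50 --out poses.tsv
softdock evaluate -r fix/receptor.pdb -l fix/ligand.pdb \
    --native-ligand fix/ligand.pdb --poses poses.tsv --id toy-2
```

which prints

```
complex	HitCount	FirstRMSD	FirstRank	BestRMSD	BestRank
toy-2	19	0.00	1	0.00	1
```

the exact native pose (LRMSD 0 Å) is recovered at rank 1, and 19 of
the 50 kept poses are acceptable hits (LRMSD ≤ 10 Å). To dock with
binding-site restraints instead:

```sh
softdock srm-dock -r fix/receptor.pdb -l fix/ligand.pdb \
    --key-receptor fix/sites_correct.txt --alpha 1.5 --step 90 --out poses_srm.tsv
softdock alpha-scan --alphas 1.0:3.0:0.5 --seeds 0,1 --step 90
```

The same functionality is available as a library
(`softdock.dock`, `softdock.srm_dock`, `softdock.alpha_scan`,
`softdock.hit_stats`, …).

## Scope

`softdock` is a sampling-stage method. Binding-site prediction itself,
pose refinement, re-scoring and flexible docking are out of scope; key
residues enter as plain text lists (`CHAIN RESNUM [ICODE]`), so any
predictor or CDR definition can feed it.
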