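# Methods

## Model

`softdock` treats docking as rigid-body search over rotations and
lattice translations, scored by a two-term grid correlation. The
physical idea is solvation: burying solvent-accessible surface on
complex formation is favorable, and the per-atom contribution is an
atomic solvation parameter (ASP) — an energy-per-area coefficient that
depends only on atom type and is negative by convention. Docking then
maximizes ASP-weighted buried surface subject to a hard-core overlap
penalty.

### Grid projection

Each molecule is projected onto a cubic lattice (spacing 1 Å by
default, origin snapped to multiples of the spacing so independently
projected molecules share one global lattice):

* **core channel** — 1 on every cell whose center lies within the van
  der Waals radius of any atom, 0 elsewhere;
* **surface channel** — on unoccupied cells 26-adjacent to the
  occupancy (a one-cell solvent-side skin), the sum of ASP values of
  all atoms whose sphere dilated by one cell diagonal covers the cell;
  0 elsewhere.

The score of relative integer shift `s` is

    S(s) = Σ surf_R(x)·surf_L(x−s) − ρ·Σ core_R(x)·core_L(x−s),   ρ = 20.

Because ASP values are negative, surface–surface coincidence along a
contact seam contributes positively, while any interpenetration pays ρ
per coincident occupied-cell pair. Placing the skin on the solvent
side (rather than on the outermost occupied layer) is what makes a
*touching* pose score well: the skins of two molecules in vdW contact
coincide without their occupancies overlapping. With the skin inside
the occupancy, surface contact would require interpenetration that the
formula either penalizes (if skin cells carry core) or ignores
entirely (if they do not, making partial burial free) — we verified
empirically that the latter variant rewards pressing the ligand 2–5 Å
into the receptor and never recovers touching native poses.

### Search

Rotations sample a z-y-z Euler grid: φ ∈ [0°, 360°), θ ∈ [0°, 180°]
(both poles always included), ψ ∈ [0°, 360°), default step 10°. At the
poles the Euler chart is degenerate; exact duplicates are removed by
quaternion distance < 1e-6, keeping first occurrences in φ-major
order (step 90° → 24 distinct rotations, step 360° → identity + flip).

At each rotation the ligand is rotated about its centroid, projected,
and the full translation field is obtained by FFT cross-correlation of
the two channels (real transforms via `scipy.fft`, zero-padded per axis
to ≥ n_R + n_L − 1 so cyclic wraparound never mixes disjoint
configurations; insufficient padding raises). A brute-force
direct-summation scan with identical return conventions serves as the
independent oracle and as an FFT-free search path; the two agree to
better than 1e-6 relative everywhere.

Per rotation the best 3 shifts are retained; all candidates are pooled
and sorted by score with deterministic tie-breaking (rotation index,
then lexicographic shift). Sort keys are quantized at 1e-6 — below the
FFT accuracy contract — so the FFT and direct paths produce identical
pose lists. The global top 2000 are returned ranked 1..n.

### Soft restraints (SRM)

Key residues — binding-site predictions supplied as residue lists —
are applied by multiplying the ASP value of *every atom* of each key
residue by a weight factor α:

    asp'_i = α·asp_i  (key residue atom),  asp'_i = asp_i  (otherwise).

α ≥ 1 is enforced; the down-weighting branch (0 < α < 1, for residues
predicted to be *outside* the interface) is deliberately rejected with
a clear message. α = 1 degenerates to the unrestrained search pose for
pose (asserted bit-exactly in tests). For a fixed pose whose interface
buries key residues the score is non-decreasing in α (bilinearity of
the surface term), which is the mechanism of the bias. Receptor and
ligand key sets are weighted independently, each with its own α, since
protocols differ (CDR-only on one side vs. predictor output on both).

The default α = 1.5. `alpha_scan` reproduces the optimization
protocol: a grid over α (default 1.0–3.0, step 0.1) re-docking a case
set and scoring per-α success count and total hit count; the best α
maximizes successes, ties broken by total hits, then by smallest α.
Larger α gives wrong information more weight — on the toy ensembles
the wrong-site hit count at α = 3 drops below α = 1.5, which is the
trade-off that makes a moderate α optimal.

## Evaluation

* **LRMSD**: superpose predicted receptor onto native receptor by
  Kabsch (CA atoms; proper rotations only, via
  `scipy.spatial.transform.Rotation.align_vectors`), apply that
  transform to the predicted ligand, take the RMSD over corresponding
  ligand heavy atoms (CA selectable). Invariant under any global rigid
  motion of the predicted complex.
* **CAPRI classes**: ≤ 2.5 Å high, ≤ 5 Å medium, ≤ 10 Å acceptable
  (inclusive boundaries), else incorrect.
* **Hits**: a pose with LRMSD ≤ 10 Å within the retained top 2000;
  per-complex bookkeeping records hit count, first (lowest-rank) hit
  and best (lowest-LRMSD) hit, with absent fields when there are no
  hits.
* **Surface residues**: relative accessibility strictly above 10%,
  from an own Shrake–Rupley implementation (deterministic golden-spiral
  sphere points, 960 by default; probe 1.4 Å) against per-residue-type
  reference maxima (theoretical Gly-X-Gly values, shipped as data).
* **Interface residues**: surface residues with minimum
  inter-molecular atom distance strictly below 5 Å in the bound
  complex.
* **Prediction accuracy**: |predicted ∩ true interface| / |predicted|,
  absent for empty predictions.
* **UB-RMSD**: CA RMSD between unbound and bound monomers after Kabsch
  superposition, residues matched by (chain, number, insertion code).
* **Relative interface area**: (SASA_R + SASA_L − SASA_complex)/2
  divided by SASA_complex — buried area is halved because it is shared
  by both surfaces, which matches the magnitude of published
  per-complex values (~0.02–0.18).
* **Benchmark summary**: successes (≥ 1 hit), total hits, and mean
  hits per successful complex (1 decimal).

Boundary semantics are deliberately literal: hits inclusive (≤),
interface strict (<), surface strict (>).

## Synthetic toy complexes

The fixtures module generates desk-scale complexes with a known native
pose so every docking and evaluation property is testable offline:

* **Receptor** (default 420 pseudo-residues): a solid quasi-spherical
  blob of carbon pseudo-atoms (one per residue, vdW 1.7 Å) on a 1.9 Å
  lattice — dense enough that the interior is genuinely core on a 1 Å
  grid — with a socket carved to complement the ligand at a 3.5 Å
  center-to-center contact gap. A snug crater wall (two lattice layers
  around the knob's z-band) is built explicitly so the socket encloses
  the knob laterally regardless of the blob radius.
* **Ligand** (default 22 pseudo-residues): a terraced L-prism —
  strongly unequal arms (~13 vs ~6 Å), a two-level stepped bottom, and
  seeded jagged column heights. Grid carving dilates every feature by
  roughly the contact distance (~3.5 Å), which blurs away small-scale
  shape detail, so the knob's asymmetry is engineered at a larger
  scale and, crucially, so that every non-native lattice orientation
  *clashes* (the misplaced arm rams the terraced socket floor or the
  thick wall) rather than merely losing contact. This makes the native
  pose the unique global optimum of the score at a 90° search step —
  verified by docking across 140 consecutive seeds during development.
* Both sides get ±0.1 Å seeded jitter; ASP values come from the
  default table. Construction invariants — zero core–core overlap
  cells at 1 Å, and at least 10 receptor interface plus 10 surface
  non-interface residues under the package's own surface/interface
  rules, so the standard 10-residue key-set protocols always have
  material to sample — are checked at build time; if a jitter draw
  violates one, the jitter is re-derived deterministically (bounded
  rejection sampling), and persistent violations raise rather than
  return a bad fixture.
* **Key sets**: `correct` samples n (default 10) residues uniformly
  from the true interface; `wrong` samples from surface residues that
  are not interface residues — the wrong-information protocol of
  randomized surface decoys.
* `perturb_unbound` adds bounded uniform jitter to emulate unbound
  monomers for UB-RMSD tests.

What passing on these fixtures shows — and what it does not: the
engine's contracts (oracle-exact FFT, restraint identities and
monotonicity, tolerance asymmetry, evaluation geometry) hold exactly;
but pseudo-atom complexes have uniform chemistry, perfect rigidity and
an engineered funnel, so success rates here say nothing quantitative
about real benchmark complexes.

## Defaults and numerical choices

| parameter | default | meaning |
|---|---|---|
| grid spacing | 1.0 Å | translation lattice step |
| ρ | 20 | core–core overlap penalty per cell pair |
| rotation step | 10° | z-y-z Euler grid (tests/fixtures use 90°) |
| per-rotation keep | 3 | best shifts retained per rotation |
| final keep | 2000 | globally ranked pose list length |
| α | 1.5 | key-residue ASP weight |
| hit cutoff | 10 Å | LRMSD for an acceptable hit |
| interface cutoff | 5 Å | strict inter-atom distance |
| surface threshold | 10% | strict relative accessibility |
| probe / sphere points | 1.4 Å / 960 | Shrake–Rupley SASA |

The bundled ASP magnitudes (C −0.5, N −0.2, O −0.2, S −0.6, other
−0.2) are placeholders keyed on element class, not a published
solvation parameter set — the engine's contracts are invariant to the
specific negative values, and the table is a YAML config precisely so
users can substitute a published set. vdW radii are standard element
radii (C 1.70, N 1.55, O 1.52, S 1.80 Å). PDB reading keeps heavy
atoms of the first model, altloc '' or 'A', and drops HETATM records;
no hydrogen placement or protonation is attempted.

The acceptance script scales the docking experiments to a desk: 90°
rotation step, toy complexes of 420 + 22 pseudo-residues, 20-seed
ensembles, chosen so the complete run finishes in a few minutes while
still exercising every code path of the full-size search.

## Known limitations

* Rigid bodies only; no side-chain or backbone flexibility, no
  refinement or re-scoring.
* The score has no electrostatics or shape-complementarity channel;
  discrimination rests entirely on ASP-weighted buried surface and the
  overlap penalty.
* One α per key set; per-residue confidence weighting is not
  implemented.
* The grid skin is one cell thick: contact scoring is sensitive to the
  spacing at sub-angstrom scales, which is inherent to lattice
  correlation methods.
* `benchmark_summary` arithmetic is exact, but the bundled reference
  tables are transcriptions of published per-complex integers; one
  row's unrestrained hit count is inconsistent with its published
  column total, so the overall unrestrained mean is computed from the
  published group totals instead of the row sum.
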