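# deva — multi-objective evolutionary protein design

`deva` is a fixed-backbone protein design engine for problems where a single
score is not enough — typified by metalloprotein design, where a sequence
must simultaneously be compatible with its scaffold *and* create a
high-affinity metal coordination site. Instead of collapsing these goals
into one weighted score, `deva` runs NSGA-II, the standard elitist
multi-objective genetic algorithm: candidate sequences are individuals,
residue-level mutation and crossover diversify the population, fast
non-dominated sorting and crowding distance drive selection, and after N
generations the rank-0 Pareto front is extracted. A single best-trade-off
design is then chosen at the **knee point** of the normalized front — the
member farthest (perpendicularly) from the line/hyperplane through the
per-objective extremes.

The package ships two fully specified geometric objectives that stand in
for learned models of p(metal | sequence, structure) and
p(sequence | metal, structure):

- **metal-site objective** — scans a 1 Å grid over the scaffold's Cβ cloud
  and scores each point g as S(g) = Σᵢ w(aaᵢ)·k(‖Cβᵢ − g‖), with donor
  propensities w (Cys 1.0, His 0.9, Asp/Glu 0.6) and a triangular kernel k
  on the Cβ–metal window [2.5, 6.5] Å peaked at 4.0 Å; the best point is the
  predicted metal position, scored σ(2S − 5).
- **sequence objective** — mean Kyte–Doolittle hydropathy (normalized to
  [−1, 1]) times a ±1 burial sign from Cα neighbor counts, minus a penalty
  λ = 0.5 per *gratuitous* donor (Cys/His/Asp/Glu whose Cβ is beyond 6.5 Å
  from the placed metal). Donors that reach the metal are exempt, so the two
  objectives conflict only over donors that buy no affinity.

Because these are closed forms, every number the engine produces can be
checked by hand, and the whole design loop runs in seconds on a laptop.
An adapter interface (`ObjectiveSpec`) lets users plug in any other scorer.

Alongside the engine, the package provides the analysis tooling such design
campaigns need:

- **Coordination-sphere analysis** (`deva.coordination`) — first-shell
  N/O/S donors within a cutoff (default 3.0 Å, inclusive) of every zinc,
  denticity, canonical donor patterns ("N2S2", "O1", …), open coordination
  sites against ideal tetrahedral zinc, dataset-level censuses (ligand-count
  histograms, fraction of zero-ligand and ≤2-residue sites), and the
  "Clean" curation filter that drops sites with fewer than three
  coordinating protein residues.
- **Structure I/O and validation** (`deva.structure_io`) — PDB reading
  (via gemmi) and writing, Kabsch superposition, Cα-RMSD between design
  models and experimental structures, and metal-displacement measurement
  after superposition.
- **Synthetic fixtures** (`deva.fixtures`) — deterministic idealized zinc
  sites, toy scaffolds (helix / hairpin / compact cluster), planted
  4-residue metal pockets, soak-like surface-zinc artefacts, and census
  sets with exact, requested coordination statistics. Everything is
  generated in memory; no downloads are needed anywhere.

## Worked example

Generate a 30-residue toy hairpin with a metal pocket planted at residues
5, 7, 22 and 24 (1-based), then run the design loop with default settings
(population 48, 60 generations, mutation rate 0.02, uniform crossover):

```bash
deva fixtures --kind planted_pocket --out fixtures/
printf '[ga]\nseed = 5\n' > deva.toml
deva design --scaffold fixtures/planted_pocket.pdb --config deva.toml --out rundir/
```

which prints

```
knee: KRKHCHHRRQRRNKRRKRNKQCHHKQQNRR (metal_site=0.9846 sequence=0.7530) front size 8
```

The knee design placed donors at all four pocket positions (His5, His7,
Cys22, His24 — plus supporting donors adjacent to them), reaching a metal
placement probability of 0.985 while keeping the sequence score high by
leaving the rest of the exposed scaffold hydrophilic. `rundir/` contains:

- `history.tsv` — per-generation best/mean of each objective and front
  size; best scores are non-decreasing by elitism (here best metal
  probability climbs 0.066 → 0.988 over 60 generations),
- `front.fasta` — the 8 deduplicated rank-0 sequences with their scores,
- `knee.fasta` — the selected design,
- `knee_metal.pdb` — the scaffold plus the predicted zinc as a HETATM
  (here at the planted inter-strand node).

The same machinery is a library:

```python
from deva import (ScaffoldContext, GAConfig, default_objectives, evolve,
                  pareto_front, knee_point, make_toy_scaffold, plant_pocket)

scaffold = plant_pocket(make_toy_scaffold(30, "hairpin"), (4, 6, 21, 23))
pop, history = evolve(ScaffoldContext(scaffold), default_objectives(),
                      GAConfig(seed=5), seed_sequence="A" * 30)
design = knee_point(pareto_front(pop))
```

For coordination censuses over real depositions:

```bash
deva coord scan --in my_pdb_dir/ --cutoff 3.0 --out sites.tsv
deva coord filter --in sites.tsv --min-residues 3 --out kept.tsv
```

and `deva superpose --model design.pdb --experimental xtal.pdb
--metal-displacement` reports the Cα-RMSD and the distance between the
designed and observed metal after superposition.

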