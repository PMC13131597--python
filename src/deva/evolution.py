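"""NSGA-II evolutionary loop over fixed-backbone sequence candidates.

The engine follows the canonical NSGA-II recipe: fast non-dominated sorting
into Pareto ranks, crowding-distance diversity within ranks, binary
tournament parent selection on (rank, crowding), residue-level uniform or
one-point crossover and per-position mutation, and fully elitist μ+λ
environmental selection.  After the final generation the rank-0 front is
extracted (deduplicated by sequence) and a single best-trade-off design is
chosen at the knee point of the normalized front.

All stochastic draws come from one seeded NumPy generator consumed in a fixed
order (selection → crossover → mutation, individuals in index order), so a
run is reproducible bit-for-bit from ``GAConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .objectives import (
    AMINO_ACIDS,
    ObjectiveSpec,
    ObjectiveVector,
    ScaffoldContext,
    SequenceCandidate,
    evaluate,
)
from .structure_io import Structure

__all__ = [
    "Individual",
    "GAConfig",
    "ParetoFront",
    "KneePoint",
    "initialize_population",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "evolve",
    "pareto_front",
    "knee_point",
]

#: crowding sentinel for front-boundary members
BOUNDARY = math.inf


@dataclass(eq=False)
class Individual:
    """A candidate with its objective vector, Pareto rank and crowding distance.

    ``rank`` and ``crowding`` are only meaningful relative to the population
    they were last computed in.
    """

    candidate: SequenceCandidate
    objectives: ObjectiveVector | None = None
    rank: int = -1
    crowding: float = 0.0

    @property
    def sequence(self) -> str:
        return self.candidate.sequence


@dataclass
class GAConfig:
    population_size: int = 48
    generations: int = 60
    mutation_rate: float = 0.02
    crossover: str = "uniform"
    crossover_rate: float = 0.9
    tournament_size: int = 2
    seed: int = 0
    knee_method: str = "perpendicular"  # or "max_sum"

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be an even integer >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.crossover not in {"uniform", "one_point"}:
            raise ValueError("crossover must be 'uniform' or 'one_point'")
        if self.knee_method not in {"perpendicular", "max_sum"}:
            raise ValueError("knee_method must be 'perpendicular' or 'max_sum'")


@dataclass
class ParetoFront:
    """Deduplicated rank-0 members, sorted by first objective descending."""

    members: list[Individual]

    def __post_init__(self) -> None:
        for i, a in enumerate(self.members):
            for b in self.members[i + 1:]:
                if dominates(a.objectives, b.objectives) or dominates(
                    b.objectives, a.objectives
                ):
                    raise ValueError("Pareto front contains a dominated member")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class KneePoint:
    """The selected best-trade-off design and its normalized knee distance."""

    individual: Individual
    normalized_distance: float


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _mutate(sequence: str, mask: np.ndarray, mu: float, rng: np.random.Generator) -> str:
    """Per-designable-position mutation to a uniformly chosen different residue.

    RNG draws are consumed at every designable position regardless of outcome
    so the stream stays aligned across candidates.
    """
    seq = list(sequence)
    for i in range(len(seq)):
        if not mask[i]:
            continue
        u = rng.random()
        j = rng.integers(19)
        if u < mu:
            alternatives = AMINO_ACIDS.replace(seq[i], "")
            seq[i] = alternatives[j]
    return "".join(seq)


def _crossover(
    a: str, b: str, mask: np.ndarray, kind: str, rng: np.random.Generator
) -> tuple[str, str]:
    """Residue-level crossover producing two complementary children."""
    ca, cb = list(a), list(b)
    if kind == "uniform":
        for i in range(len(ca)):
            if mask[i] and rng.random() < 0.5:
                ca[i], cb[i] = cb[i], ca[i]
    else:  # one_point
        cut = int(rng.integers(1, len(ca)))
        for i in range(cut, len(ca)):
            if mask[i]:
                ca[i], cb[i] = cb[i], ca[i]
    return "".join(ca), "".join(cb)


def initialize_population(
    seed_sequence: str,
    cfg: GAConfig,
    designable_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[SequenceCandidate]:
    """Seed + (population_size − 1) single-mutation variants of the seed."""
    if designable_mask is None:
        designable_mask = np.ones(len(seed_sequence), dtype=bool)
    designable_mask = np.asarray(designable_mask, dtype=bool)
    if len(designable_mask) != len(seed_sequence):
        raise ValueError("designable_mask length differs from seed sequence length")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = [SequenceCandidate(seed_sequence, designable_mask)]
    for _ in range(cfg.population_size - 1):
        pop.append(
            SequenceCandidate(
                _mutate(seed_sequence, designable_mask, cfg.mutation_rate, rng),
                designable_mask,
            )
        )
    return pop


# ---------------------------------------------------------------------------
# NSGA-II machinery
# ---------------------------------------------------------------------------

def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff a >= b component-wise with at least one strict inequality."""
    if a is None or b is None:
        raise ValueError("cannot compare unevaluated individuals")
    if len(a) != len(b):
        raise ValueError("objective vectors have different lengths")
    av, bv = a.scores, b.scores
    return bool(np.all(av >= bv) and np.any(av > bv))


def fast_nondominated_sort(pop: Sequence[Individual]) -> list[list[Individual]]:
    """Assign Pareto ranks in place and return the list of fronts.

    Rank 0 = dominated by nobody; rank k = dominated only by lower ranks.
    Standard NSGA-II bookkeeping with domination counts.
    """
    n = len(pop)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = [0] * n
    fronts: list[list[Individual]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(pop[i].objectives, pop[j].objectives):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif dominates(pop[j].objectives, pop[i].objectives):
                dominated_by[j].append(i)
                dom_count[i] += 1
    for i in range(n):
        if dom_count[i] == 0:
            pop[i].rank = 0
            fronts[0].append(pop[i])
    current = 0
    indices = {id(ind): i for i, ind in enumerate(pop)}
    while fronts[current]:
        nxt: list[Individual] = []
        for ind in fronts[current]:
            for j in dominated_by[indices[id(ind)]]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    pop[j].rank = current + 1
                    nxt.append(pop[j])
        current += 1
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(front: Sequence[Individual]) -> None:
    """Assign NSGA-II crowding distances within one front, in place.

    Per objective the front is sorted (stable, sequence-string tie-break);
    the two extremes receive the boundary sentinel (+inf) and interior
    members accumulate the normalized gap between their neighbors.
    Zero-range objectives contribute nothing.  Fronts of one or two members
    are all boundary.
    """
    if not front:
        raise ValueError("crowding_distance on an empty front")
    for ind in front:
        ind.crowding = 0.0
    if len(front) <= 2:
        for ind in front:
            ind.crowding = BOUNDARY
        return
    m = len(front[0].objectives)
    for k in range(m):
        ordered = sorted(front, key=lambda ind: (ind.objectives[k], ind.sequence))
        lo, hi = ordered[0].objectives[k], ordered[-1].objectives[k]
        if hi == lo:
            continue
        ordered[0].crowding = BOUNDARY
        ordered[-1].crowding = BOUNDARY
        for i in range(1, len(ordered) - 1):
            if ordered[i].crowding != BOUNDARY:
                ordered[i].crowding += (
                    ordered[i + 1].objectives[k] - ordered[i - 1].objectives[k]
                ) / (hi - lo)


def _selection_key(ind: Individual) -> tuple:
    return (ind.rank, -ind.crowding, ind.sequence)


def _tournament(pop: list[Individual], cfg: GAConfig, rng: np.random.Generator) -> Individual:
    picks = [pop[int(rng.integers(len(pop)))] for _ in range(cfg.tournament_size)]
    return min(picks, key=_selection_key)


def _rank_population(pop: list[Individual]) -> None:
    for front in fast_nondominated_sort(pop):
        crowding_distance(front)


def evolve(
    scaffold: Structure | ScaffoldContext,
    objectives: Sequence[ObjectiveSpec],
    cfg: GAConfig,
    seed_sequence: str | None = None,
    designable_mask: np.ndarray | None = None,
) -> tuple[list[Individual], list[dict]]:
    """Run the full NSGA-II loop and return (final population, history).

    ``history`` holds one record per generation (including generation 0, the
    evaluated initial population): per-objective best and mean over the
    population and the size of the deduplicated rank-0 front.  μ+λ truncation
    makes per-objective bests non-decreasing across generations.
    """
    ctx = scaffold if isinstance(scaffold, ScaffoldContext) else ScaffoldContext(scaffold)
    if seed_sequence is None:
        seed_sequence = "A" * ctx.n_residues
    if len(seed_sequence) != ctx.n_residues:
        raise ValueError("seed sequence length differs from scaffold length")
    rng = np.random.default_rng(cfg.seed)

    def _eval(c: SequenceCandidate, gen: int) -> Individual:
        try:
            return Individual(c, evaluate(c, objectives, ctx))
        except Exception as exc:
            raise RuntimeError(f"evaluation failed at generation {gen}: {exc}") from exc

    candidates = initialize_population(seed_sequence, cfg, designable_mask, rng)
    mask = candidates[0].designable_mask
    pop = [_eval(c, 0) for c in candidates]
    _rank_population(pop)
    history = [_history_record(0, pop, objectives)]

    for gen in range(1, cfg.generations + 1):
        offspring: list[Individual] = []
        for _ in range(cfg.population_size // 2):
            p1 = _tournament(pop, cfg, rng)
            p2 = _tournament(pop, cfg, rng)
            s1, s2 = p1.sequence, p2.sequence
            if rng.random() < cfg.crossover_rate:
                s1, s2 = _crossover(s1, s2, mask, cfg.crossover, rng)
            s1 = _mutate(s1, mask, cfg.mutation_rate, rng)
            s2 = _mutate(s2, mask, cfg.mutation_rate, rng)
            offspring.append(_eval(SequenceCandidate(s1, mask), gen))
            offspring.append(_eval(SequenceCandidate(s2, mask), gen))
        pool = pop + offspring
        _rank_population(pool)
        pool.sort(key=_selection_key)
        pop = pool[: cfg.population_size]
        _rank_population(pop)  # ranks/crowding valid within the surviving set
        history.append(_history_record(gen, pop, objectives))
    return pop, history


def _history_record(gen: int, pop: list[Individual], objectives) -> dict:
    scores = np.array([ind.objectives.scores for ind in pop])
    rec = {"generation": gen, "front_size": len(pareto_front(pop))}
    for k, spec in enumerate(objectives):
        rec[f"best_{spec.name}"] = float(scores[:, k].max())
        rec[f"mean_{spec.name}"] = float(scores[:, k].mean())
    return rec


# ---------------------------------------------------------------------------
# Front extraction and knee-point selection
# ---------------------------------------------------------------------------

def pareto_front(pop: Sequence[Individual]) -> ParetoFront:
    """Rank-0 members, deduplicated by sequence, first objective descending."""
    rank0 = [ind for ind in pop if ind.rank == 0]
    if not rank0 and pop:
        raise ValueError("ranks not assigned; run fast_nondominated_sort first")
    rank0 = sorted(rank0, key=lambda ind: (-ind.objectives[0], ind.sequence))
    seen: set[str] = set()
    members = []
    for ind in rank0:
        if ind.sequence not in seen:
            seen.add(ind.sequence)
            members.append(ind)
    return ParetoFront(members=members)


def _normalize(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    rng = hi - lo
    out = np.full_like(scores, 0.5)
    ok = rng > 0
    out[:, ok] = (scores[:, ok] - lo[ok]) / rng[ok]
    return out


def knee_point(front: ParetoFront, method: str = "perpendicular") -> KneePoint:
    """Best balanced trade-off on the front.

    Objectives are normalized over the front to [0, 1] (zero-range objectives
    become the constant 0.5).  With the default method the knee is the member
    with maximal perpendicular distance to the line (2 objectives) or
    hyperplane (m objectives) through the per-objective extreme points; this
    is invariant under independent positive affine rescaling of each raw
    objective.  Degenerate geometry (collinear front, coincident extremes) and
    fronts of at most two members fall back to the maximal normalized sum, as
    does ``method="max_sum"``.  Ties break to the lexicographically smallest
    sequence.
    """
    members = list(front.members)
    if not members:
        raise ValueError("knee_point of an empty front")
    raw = np.array([ind.objectives.scores for ind in members])
    norm = _normalize(raw)
    m = raw.shape[1]

    def _pick(values: np.ndarray) -> int:
        best = values.max()
        tied = [i for i in range(len(members)) if values[i] >= best - 1e-12]
        return min(tied, key=lambda i: members[i].sequence)

    use_sum = method == "max_sum" or len(members) <= 2
    distances = None
    if not use_sum:
        extremes = []
        for k in range(m):
            best = norm[:, k].max()
            tied = [i for i in range(len(members)) if norm[i, k] >= best - 1e-12]
            extremes.append(norm[min(tied, key=lambda i: members[i].sequence)])
        e = np.array(extremes)
        if m == 2:
            direction = e[1] - e[0]
            nrm = np.linalg.norm(direction)
            if nrm < 1e-12:
                use_sum = True
            else:
                normal = np.array([-direction[1], direction[0]]) / nrm
                distances = np.abs((norm - e[0]) @ normal)
        else:
            basis = e[1:] - e[0]
            # hyperplane normal = 1-d null space of the edge matrix
            _, s, vt = np.linalg.svd(basis)
            if basis.shape[0] < m - 1 or np.sum(s > 1e-9) < m - 1:
                use_sum = True
            else:
                normal = vt[-1]
                distances = np.abs((norm - e[0]) @ normal)
        if distances is not None and distances.max() < 1e-9:
            use_sum = True  # collinear / degenerate front
    if use_sum:
        i = _pick(norm.sum(axis=1))
        dist = float(distances[i]) if distances is not None else 0.0
        return KneePoint(individual=members[i], normalized_distance=dist)
    i = _pick(distances)
    return KneePoint(individual=members[i], normalized_distance=float(distances[i]))
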