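"""NSGA-II machinery: sorting, crowding, selection, knee point, full loop."""

import math

import numpy as np
import pytest

from deva import (
    GAConfig,
    Individual,
    ObjectiveVector,
    ParetoFront,
    ScaffoldContext,
    SequenceCandidate,
    crowding_distance,
    default_objectives,
    dominates,
    evolve,
    fast_nondominated_sort,
    initialize_population,
    knee_point,
    pareto_front,
)
from deva.evolution import BOUNDARY


def make_ind(scores, seq="AAAAAAAA"):
    return Individual(SequenceCandidate(seq), ObjectiveVector(np.array(scores, float)))


def brute_force_ranks(vectors):
    """Oracle: iterative peeling by the pairwise dominance definition."""
    n = len(vectors)
    remaining = set(range(n))
    ranks = {}
    level = 0
    while remaining:
        front = {
            i for i in remaining
            if not any(dominates(vectors[j], vectors[i]) for j in remaining if j != i)
        }
        for i in front:
            ranks[i] = level
        remaining -= front
        level += 1
    return [ranks[i] for i in range(n)]


class TestDominates:
    def test_strict_dominance(self):
        assert dominates(ObjectiveVector([2, 2]), ObjectiveVector([1, 1]))

    def test_incomparable_both_ways(self):
        a, b = ObjectiveVector([1, 2]), ObjectiveVector([2, 1])
        assert not dominates(a, b) and not dominates(b, a)

    def test_equal_vectors_do_not_dominate(self):
        a = ObjectiveVector([1.5, 2.5])
        assert not dominates(a, ObjectiveVector([1.5, 2.5]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dominates(ObjectiveVector([1]), ObjectiveVector([1, 2]))


class TestNondominatedSort:
    def test_identical_vectors_all_rank_zero(self):
        pop = [make_ind([1, 1], aa * 8) for aa in "ACDEF"]
        fast_nondominated_sort(pop)
        assert all(i.rank == 0 for i in pop)

    def test_dominance_chain(self):
        pop = [make_ind(v) for v in ([1, 1], [3, 3], [2, 2])]
        fast_nondominated_sort(pop)
        assert [i.rank for i in pop] == [2, 0, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(10, 60)), int(rng.integers(2, 5))
        vectors = [ObjectiveVector(rng.integers(0, 6, m).astype(float)) for _ in range(n)]
        pop = [Individual(SequenceCandidate("A" * 4), v) for v in vectors]
        fast_nondominated_sort(pop)
        assert [i.rank for i in pop] == brute_force_ranks(vectors)

    def test_rank_soundness(self):
        rng = np.random.default_rng(17)
        pop = [make_ind(rng.random(3)) for _ in range(40)]
        fast_nondominated_sort(pop)
        rank0 = [i for i in pop if i.rank == 0]
        for a in rank0:
            assert not any(dominates(b.objectives, a.objectives) for b in pop)
        for a in pop:
            if a.rank > 0:
                assert any(
                    b.rank == a.rank - 1 and dominates(b.objectives, a.objectives)
                    for b in pop
                )


class TestCrowdingDistance:
    def test_small_fronts_all_boundary(self):
        for k in (1, 2):
            front = [make_ind([i, k - i], "ACDEFGHI"[i] * 8) for i in range(k)]
            crowding_distance(front)
            assert all(i.crowding == BOUNDARY for i in front)

    def test_hand_computed_middle_member(self):
        front = [make_ind([0.0, 1.0], "AAAAAAAA"),
                 make_ind([0.5, 0.5], "CCCCCCCC"),
                 make_ind([1.0, 0.0], "DDDDDDDD")]
        crowding_distance(front)
        assert front[0].crowding == BOUNDARY
        assert front[2].crowding == BOUNDARY
        assert front[1].crowding == pytest.approx(2.0)

    def test_duplicate_extremes_deterministic(self):
        front = [make_ind([1.0, 0.0], "EEEEEEEE"),
                 make_ind([1.0, 0.0], "AAAAAAAA"),
                 make_ind([0.0, 1.0], "CCCCCCCC"),
                 make_ind([0.5, 0.5], "DDDDDDDD")]
        crowding_distance(front)
        again = [make_ind([i.objectives[0], i.objectives[1]], i.sequence) for i in front]
        crowding_distance(again)
        assert [i.crowding for i in front] == [i.crowding for i in again]

    def test_zero_range_objective_contributes_nothing(self):
        front = [make_ind([0.0, 5.0], "AAAAAAAA"),
                 make_ind([0.5, 5.0], "CCCCCCCC"),
                 make_ind([1.0, 5.0], "DDDDDDDD")]
        crowding_distance(front)
        assert front[1].crowding == pytest.approx(1.0)  # only the first objective


class TestInitializePopulation:
    def test_zero_mutation_rate_copies_seed(self):
        cfg = GAConfig(population_size=8, generations=1, mutation_rate=0.0, seed=1)
        pop = initialize_population("ACDEFGHIKL", cfg)
        assert all(c.sequence == "ACDEFGHIKL" for c in pop)

    def test_reproducible_and_valid(self):
        cfg = GAConfig(population_size=16, generations=1, mutation_rate=0.3, seed=9)
        mask = np.array([True] * 5 + [False] * 5)
        p1 = initialize_population("ACDEFGHIKL", cfg, designable_mask=mask)
        p2 = initialize_population("ACDEFGHIKL", cfg, designable_mask=mask)
        assert [c.sequence for c in p1] == [c.sequence for c in p2]
        assert p1[0].sequence == "ACDEFGHIKL"  # unmodified seed first
        for c in p1:
            assert all(aa in "ACDEFGHIKLMNPQRSTVWY" for aa in c.sequence)
            assert c.sequence[5:] == "GHIKL"  # masked positions untouched

    def test_mask_length_mismatch(self):
        cfg = GAConfig(population_size=4, generations=1)
        with pytest.raises(ValueError):
            initialize_population("ACDE", cfg, designable_mask=np.ones(3, bool))


class TestParetoFront:
    def test_single_and_chain(self):
        solo = [make_ind([1, 1])]
        fast_nondominated_sort(solo)
        assert len(pareto_front(solo)) == 1
        chain = [make_ind(v, s) for v, s in
                 ([[1, 1], "AAAAAAAA"], [[2, 2], "CCCCCCCC"], [[3, 3], "DDDDDDDD"])]
        fast_nondominated_sort(chain)
        front = pareto_front(chain)
        assert len(front) == 1 and front.members[0].sequence == "DDDDDDDD"

    def test_equals_brute_force_nondominated_set(self):
        rng = np.random.default_rng(23)
        pop = [make_ind(rng.integers(0, 5, 2).astype(float), seq)
               for seq in ("".join(rng.choice(list("ACDEFGHI"), 8)) for _ in range(30))]
        fast_nondominated_sort(pop)
        front = pareto_front(pop)
        expected = {
            i.sequence for i in pop
            if not any(dominates(j.objectives, i.objectives) for j in pop)
        }
        assert {m.sequence for m in front} == expected
        # deduplicated and sorted by first objective descending
        seqs = [m.sequence for m in front]
        assert len(seqs) == len(set(seqs))
        firsts = [m.objectives[0] for m in front]
        assert firsts == sorted(firsts, reverse=True)

    def test_no_member_dominates_another(self):
        with pytest.raises(ValueError):
            ParetoFront(members=[make_ind([2, 2], "AAAAAAAA"), make_ind([1, 1], "CCCCCCCC")])


class TestKneePoint:
    def test_asymmetric_front_perpendicular_distance(self):
        front = ParetoFront(members=[
            make_ind([0.0, 1.0], "AAAAAAAA"),
            make_ind([0.9, 0.9], "CCCCCCCC"),
            make_ind([1.0, 0.0], "DDDDDDDD"),
        ])
        knee = knee_point(front)
        assert knee.individual.sequence == "CCCCCCCC"
        assert knee.normalized_distance == pytest.approx(0.8 / math.sqrt(2), abs=1e-9)

    def test_single_member_front(self):
        front = ParetoFront(members=[make_ind([0.3, 0.7], "AAAAAAAA")])
        assert knee_point(front).individual.sequence == "AAAAAAAA"

    def test_collinear_front_falls_back_to_sum_then_lexicographic(self):
        front = ParetoFront(members=[
            make_ind([0.0, 1.0], "CCCCCCCC"),
            make_ind([0.5, 0.5], "DDDDDDDD"),
            make_ind([1.0, 0.0], "AAAAAAAA"),
        ])
        knee = knee_point(front)
        # all perpendicular distances are 0 and all normalized sums tie at 1.0
        assert knee.individual.sequence == "AAAAAAAA"

    def test_affine_invariance(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            pts = rng.random((6, 2))
            pop = [make_ind(list(p), "".join(rng.choice(list("ACDEFGHIKLMN"), 8)))
                   for p in pts]
            fast_nondominated_sort(pop)
            front = pareto_front(pop)
            knee = knee_point(front)
            a, b = rng.uniform(0.5, 3.0, 2), rng.uniform(-5, 5, 2)
            scaled = [make_ind([m.objectives[0] * a[0] + b[0],
                                m.objectives[1] * a[1] + b[1]], m.sequence)
                      for m in front.members]
            for s in scaled:
                s.rank = 0
            knee2 = knee_point(ParetoFront(members=scaled))
            assert knee2.individual.sequence == knee.individual.sequence

    def test_three_objective_hyperplane(self):
        front = ParetoFront(members=[
            make_ind([1.0, 0.0, 0.0], "AAAAAAAA"),
            make_ind([0.0, 1.0, 0.0], "CCCCCCCC"),
            make_ind([0.0, 0.0, 1.0], "DDDDDDDD"),
            make_ind([0.8, 0.8, 0.8], "EEEEEEEE"),
        ])
        knee = knee_point(front)
        assert knee.individual.sequence == "EEEEEEEE"

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            knee_point(ParetoFront(members=[]))

    def test_max_sum_method(self):
        front = ParetoFront(members=[
            make_ind([0.0, 1.0], "AAAAAAAA"),
            make_ind([0.9, 0.9], "CCCCCCCC"),
            make_ind([1.0, 0.0], "DDDDDDDD"),
        ])
        assert knee_point(front, method="max_sum").individual.sequence == "CCCCCCCC"


@pytest.fixture(scope="module")
def setup(planted_scaffold):
    return ScaffoldContext(planted_scaffold), default_objectives()


class TestEvolve:

    def test_static_run_returns_initial_population(self, setup):
        ctx, objectives = setup
        cfg = GAConfig(population_size=8, generations=1, mutation_rate=0.0,
                       crossover_rate=0.0, seed=3)
        pop, history = evolve(ctx, objectives, cfg, seed_sequence="A" * 30)
        assert all(i.sequence == "A" * 30 for i in pop)
        assert len(history) == 2
        assert history[0]["best_metal_site"] == history[1]["best_metal_site"]

    def test_same_seed_identical_history(self, setup):
        ctx, objectives = setup
        cfg = GAConfig(population_size=12, generations=5, seed=11)
        _, h1 = evolve(ctx, objectives, cfg, seed_sequence="A" * 30)
        _, h2 = evolve(ctx, objectives, cfg, seed_sequence="A" * 30)
        assert h1 == h2

    def test_elitism_best_scores_non_decreasing(self, setup):
        ctx, objectives = setup
        cfg = GAConfig(population_size=16, generations=12, seed=5)
        _, history = evolve(ctx, objectives, cfg, seed_sequence="A" * 30)
        for name in ("best_metal_site", "best_sequence"):
            vals = [rec[name] for rec in history]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_evaluator_failure_reports_generation(self, setup):
        from deva import ObjectiveSpec

        ctx, _ = setup
        calls = {"n": 0}

        def flaky(c, context):
            calls["n"] += 1
            if calls["n"] > 20:
                raise RuntimeError("surrogate exploded")
            return 0.5

        objectives = [default_objectives()[0], ObjectiveSpec("flaky", flaky)]
        cfg = GAConfig(population_size=8, generations=5, seed=2)
        with pytest.raises(RuntimeError, match="generation"):
            evolve(ctx, objectives, cfg, seed_sequence="A" * 30)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=7)
        with pytest.raises(ValueError):
            GAConfig(mutation_rate=1.5)
        with pytest.raises(ValueError):
            GAConfig(crossover="two_point")
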