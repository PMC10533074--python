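"""Genetic operators, selection and the search loop under surrogate fitness."""

import numpy as np
import pytest

from gaunet import (
    GAConfig,
    Genome,
    Individual,
    SearchSpace,
    count_parameters,
    decode_architecture,
    load_builtin,
    sample_genome,
)
from gaunet.errors import ConfigurationError, StateError
from gaunet.ga import (
    crossover_pair,
    environmental_selection,
    evaluate_population,
    generate_offspring,
    mutate,
    run_search,
    select_best,
)
from gaunet.genome import validate_genome


def _inds(fitnesses, start_id=0):
    g = load_builtin("lung")
    return [
        Individual(genome=g, fitness=f, id=start_id + i)
        for i, f in enumerate(fitnesses)
    ]


def test_gaconfig_defaults_and_validation():
    cfg = GAConfig()
    assert (cfg.generations, cfg.population_size, cfg.n_best_parents) == (5, 10, 5)
    assert (cfg.crossover_rate, cfg.mutation_rate, cfg.epochs_per_eval) == (0.5, 0.1, 20)
    with pytest.raises(ConfigurationError):
        GAConfig(population_size=4, n_best_parents=4)
    with pytest.raises(ConfigurationError):
        GAConfig(mutation_rate=1.5)


def test_crossover_fixed_cut_swaps_tail():
    p1 = Genome(5, 8, 5, 2, 1, 0, 0, 3, 1e-4, 8)
    p2 = Genome(7, 8, 4, 1, 1, 1, 0, 3, 1e-4, 4)
    c1, c2 = crossover_pair(p1, p2, rate=1.0, rng=np.random.default_rng(0), cut=5)
    assert c1 == Genome(5, 8, 5, 2, 1, 1, 0, 3, 1e-4, 4)
    assert c2 == Genome(7, 8, 4, 1, 1, 0, 0, 3, 1e-4, 8)


def test_crossover_rate_zero_and_identical_parents(space, rng):
    p1, p2 = sample_genome(space, rng), sample_genome(space, rng)
    assert crossover_pair(p1, p2, 0.0, rng) == (p1, p2)
    for cut in range(1, 10):
        c1, c2 = crossover_pair(p1, p1, 1.0, rng, cut=cut)
        assert c1 == p1 and c2 == p1


def test_crossover_children_always_valid(space, rng):
    for _ in range(100):
        c1, c2 = crossover_pair(sample_genome(space, rng), sample_genome(space, rng), 1.0, rng)
        validate_genome(c1, space)
        validate_genome(c2, space)


def test_mutation_rate_zero_is_identity(space, rng):
    g = sample_genome(space, rng)
    assert mutate(g, 0.0, space, rng) == g


def test_mutation_rate_one_stays_in_domains(space):
    rng = np.random.default_rng(5)
    g = load_builtin("lung")
    for _ in range(1000):
        m = mutate(g, 1.0, space, rng)
        validate_genome(m, space)
        assert m.n_blocks % 2 == 1


def test_mutation_event_rate_matches_binomial(space):
    # The learning-rate gene changes almost surely when resampled, so
    # counting changed LR genes counts mutation events exactly.
    rng = np.random.default_rng(17)
    g = load_builtin("lung")
    n = 10_000
    hits = sum(mutate(g, 0.1, space, rng).learning_rate != g.learning_rate for _ in range(n))
    p = 0.1
    sigma = np.sqrt(n * p * (1 - p))
    assert abs(hits - n * p) <= 3 * sigma


def test_select_best_sorts_and_breaks_ties_by_id():
    pop = _inds([0.2, 0.9, 0.5])
    assert [i.fitness for i in select_best(pop, 2)] == [0.9, 0.5]
    tied = _inds([0.4, 0.4, 0.4])
    assert [i.id for i in select_best(tied, 2)] == [0, 1]
    assert [i.fitness for i in select_best(pop, 3)] == [0.9, 0.5, 0.2]
    with pytest.raises(StateError):
        select_best(_inds([0.1, None]), 1)


def test_generate_offspring_counts_and_validity(space, rng):
    cfg = GAConfig(population_size=10, n_best_parents=5, master_seed=0)
    parents = [
        Individual(genome=sample_genome(space, rng), fitness=0.5, id=i) for i in range(5)
    ]
    q = generate_offspring(parents, cfg, space, rng, start_id=100)
    assert len(q) == 8  # 2 * (K - 1)
    assert [o.id for o in q] == list(range(100, 108))
    for o in q:
        assert o.fitness is None
        validate_genome(o.genome, space)
    assert len(generate_offspring(parents[:2], cfg, space, rng)) == 2
    with pytest.raises(ConfigurationError):
        generate_offspring(parents[:1], cfg, space, rng)


def test_environmental_selection_rule():
    pt = _inds([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
    qt = _inds([0.85, 0.65, 0.30, 0.20], start_id=10)
    nxt = environmental_selection(pt, qt, k=3)
    assert sorted(i.fitness for i in nxt) == [0.30, 0.65, 0.7, 0.8, 0.85, 0.9]
    assert len(nxt) == len(pt)
    assert max(i.fitness for i in nxt) >= max(i.fitness for i in pt)
    # boundary: exactly |Pt| - K offspring -> all admitted
    nxt2 = environmental_selection(pt, qt, k=2)
    assert {i.id for i in nxt2} >= {10, 11, 12, 13}
    with pytest.raises(ConfigurationError):
        environmental_selection(pt, qt[:2], k=3)


def test_evaluate_population_caches_and_clamps():
    cfg = GAConfig(population_size=4, n_best_parents=2)
    calls = []

    def fn(genome, seed):
        calls.append(seed)
        return 0.42

    pop = _inds([0.9, None, None])
    out = evaluate_population(pop, None, None, cfg, fitness_fn=fn)
    assert len(out) == 3
    assert out[0].fitness == 0.9  # cached elite untouched
    assert out[1].fitness == out[2].fitness == 0.42
    assert len(calls) == 2 and calls[0] == calls[1]  # identical genomes, same seed


def test_evaluate_population_degrades_nonfinite_to_zero():
    cfg = GAConfig(population_size=4, n_best_parents=2)
    pop = _inds([None])
    with pytest.warns(RuntimeWarning, match="non-finite"):
        out = evaluate_population(pop, None, None, cfg, fitness_fn=lambda g, s: float("nan"))
    assert out[0].fitness == 0.0


def _surrogate(genome, seed):
    return 1.0 / (1.0 + count_parameters(decode_architecture(genome, in_channels=1)))


def test_search_prefers_small_models_under_surrogate(space):
    cfg = GAConfig(population_size=10, generations=10, n_best_parents=5, master_seed=21)
    best, log = run_search(cfg, space=space, fitness_fn=_surrogate)
    best_count = count_parameters(decode_architecture(best.genome, in_channels=1))
    rng = np.random.default_rng(2024)
    random_counts = [
        count_parameters(decode_architecture(sample_genome(space, rng), in_channels=1))
        for _ in range(100)
    ]
    assert best_count <= np.median(random_counts)
    # elitism: non-decreasing best fitness; size conserved every generation
    trace = log.best_fitness_trace
    assert all(b >= a for a, b in zip(trace, trace[1:]))
    assert all(r["population_size"] == 10 for r in log.records)
    assert len(log.records) == 10


def test_search_is_reproducible(space):
    cfg = GAConfig(population_size=6, generations=3, n_best_parents=3, master_seed=77)
    best1, log1 = run_search(cfg, space=space, fitness_fn=_surrogate)
    best2, log2 = run_search(cfg, space=space, fitness_fn=_surrogate)
    assert best1.genome == best2.genome
    assert log1.best_fitness_trace == log2.best_fitness_trace


def test_search_requires_data_or_fitness():
    with pytest.raises(ConfigurationError):
        run_search(GAConfig(population_size=4, n_best_parents=2))
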