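"""Elitist genetic algorithm over the architecture search space.

The generational loop: initialize L random genomes; each generation,
evaluate unevaluated individuals (short training, fitness = validation
pixel accuracy), sort and keep the K best as parents, breed offspring from
successive parent pairs by single-point crossover and per-gene mutation,
evaluate them, and form the next population from the K elites plus the best
|P| − K offspring.  Elites keep their cached fitness, which makes the best
fitness non-decreasing across generations.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .architecture import build_network, decode_architecture
from .errors import ConfigurationError, DivergenceError, StateError
from .genome import (
    Genome,
    Individual,
    SearchSpace,
    genome_to_json,
    repair_genome,
    sample_genome,
)
from .nn.train import pixel_accuracy, train_model

__all__ = [
    "GAConfig",
    "SearchLog",
    "FitnessFn",
    "make_training_fitness",
    "evaluate_population",
    "select_best",
    "crossover_pair",
    "mutate",
    "generate_offspring",
    "environmental_selection",
    "run_search",
]

#: maps (genome, seed) to a fitness in [0, 1]
FitnessFn = Callable[[Genome, int], float]

_SEED_MOD = 2**31


@dataclasses.dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters; defaults are the published search settings
    (5 generations, population 10, K = 5 elites, crossover 0.5, mutation 0.1,
    20 training epochs per fitness evaluation)."""

    population_size: int = 10
    generations: int = 5
    n_best_parents: int = 5
    crossover_rate: float = 0.5
    mutation_rate: float = 0.1
    epochs_per_eval: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_best_parents < self.population_size):
            raise ConfigurationError(
                f"need 0 < K < L, got K={self.n_best_parents}, L={self.population_size}"
            )
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.generations < 1 or self.epochs_per_eval < 1:
            raise ConfigurationError("generations and epochs_per_eval must be >= 1")


@dataclasses.dataclass
class SearchLog:
    """Per-generation records of the search trajectory."""

    records: list[dict] = dataclasses.field(default_factory=list)

    def append(self, **record) -> None:
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)

    @property
    def best_fitness_trace(self) -> list[float]:
        return [r["best_fitness"] for r in self.records]


def _genome_seed(genome: Genome, master_seed: int) -> int:
    """Stable per-genome training seed: identical genomes train identically."""
    digest = zlib.crc32(genome_to_json(genome).encode())
    return (digest ^ (master_seed * 2654435761)) % _SEED_MOD


def make_training_fitness(
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    epochs: int,
) -> FitnessFn:
    """The default fitness: decode, build, train for ``epochs`` with the
    genome's own optimizer/learning-rate/batch-size, then score validation
    pixel accuracy at threshold 0.5."""
    train_images, train_masks = train_data
    val_images, val_masks = val_data
    if len(train_images) == 0 or len(val_images) == 0:
        raise ConfigurationError("training and validation data must be non-empty")
    in_channels = 1 if np.asarray(train_images).ndim == 3 else train_images.shape[-1]

    def fitness(genome: Genome, seed: int) -> float:
        spec = decode_architecture(genome, in_channels=in_channels)
        model = build_network(spec, seed=seed)
        train_model(
            model,
            train_images,
            train_masks,
            epochs=epochs,
            optimizer=genome.optimizer,
            learning_rate=genome.learning_rate,
            batch_size=genome.batch_size,
            seed=(seed + 1) % _SEED_MOD,
        )
        probs = np.concatenate(
            [model.predict(val_images[i : i + 8]) for i in range(0, len(val_images), 8)]
        )
        return pixel_accuracy(probs, np.asarray(val_masks))

    return fitness


def evaluate_population(
    pop: Sequence[Individual],
    train_data,
    val_data,
    config: GAConfig,
    fitness_fn: Optional[FitnessFn] = None,
) -> list[Individual]:
    """Assign fitness to every individual that lacks one; cached fitness
    (elite parents) is never recomputed.  A training divergence or non-finite
    score degrades to fitness 0.0 with a warning."""
    fitness_fn = fitness_fn or make_training_fitness(
        train_data, val_data, config.epochs_per_eval
    )
    for ind in pop:
        if ind.has_fitness():
            continue
        seed = _genome_seed(ind.genome, config.master_seed)
        try:
            f = float(fitness_fn(ind.genome, seed))
        except DivergenceError as exc:
            warnings.warn(f"individual {ind.id}: {exc}; fitness set to 0.0", RuntimeWarning)
            f = 0.0
        if not np.isfinite(f):
            warnings.warn(
                f"individual {ind.id}: non-finite fitness; set to 0.0", RuntimeWarning
            )
            f = 0.0
        ind.fitness = min(max(f, 0.0), 1.0)
    return list(pop)


def select_best(pop: Sequence[Individual], k: int) -> list[Individual]:
    """The k fittest individuals, descending; ties broken by smaller id."""
    if k > len(pop):
        raise ConfigurationError(f"K={k} exceeds population size {len(pop)}")
    if any(not ind.has_fitness() for ind in pop):
        raise StateError("select_best requires every individual to have a fitness")
    return sorted(pop, key=lambda ind: (-ind.fitness, ind.id))[:k]


def crossover_pair(
    p1: Genome,
    p2: Genome,
    rate: float,
    rng: np.random.Generator,
    space: Optional[SearchSpace] = None,
    cut: Optional[int] = None,
) -> tuple[Genome, Genome]:
    """Single-point crossover: with probability ``rate`` swap the gene tails
    at a uniform cut in {1..9} and repair; otherwise return parent copies."""
    if rng.random() >= rate:
        return p1, p2
    if cut is None:
        cut = int(rng.integers(1, len(p1.to_vector())))
    v1, v2 = p1.to_vector(), p2.to_vector()
    c1 = v1[:cut] + v2[cut:]
    c2 = v2[:cut] + v1[cut:]
    return repair_genome(c1, space), repair_genome(c2, space)


def mutate(
    g: Genome,
    rate: float,
    space: Optional[SearchSpace] = None,
    rng: Optional[np.random.Generator] = None,
) -> Genome:
    """Per-gene mutation: each gene is independently resampled from its
    domain (log-uniformly for the learning rate) with probability ``rate``."""
    space = space or SearchSpace()
    rng = rng if rng is not None else np.random.default_rng()
    if rate == 0.0:
        return g
    domains = [
        space.blocks_domain,
        space.filters_domain,
        space.kernel_domain,
        space.activation_domain,
        space.pooling_domain,
        space.bn_domain,
        space.dropout_domain,
        space.optimizer_domain,
        None,  # learning rate, continuous
        space.batch_domain,
    ]
    vec = g.to_vector()
    for i, domain in enumerate(domains):
        if rng.random() >= rate:
            continue
        if domain is None:
            lo, hi = space.lr_range
            vec[i] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            vec[i] = int(rng.choice(np.asarray(sorted(domain))))
    return repair_genome(vec, space)


def generate_offspring(
    p_best: Sequence[Individual],
    config: GAConfig,
    space: Optional[SearchSpace] = None,
    rng: Optional[np.random.Generator] = None,
    start_id: int = 0,
) -> list[Individual]:
    """Breed 2(K−1) offspring from the K sorted parents: each successive
    overlapping pair (1,2), (2,3), ... undergoes crossover, then both
    children are mutated.  Offspring get fresh ids and no fitness."""
    if len(p_best) < 2:
        raise ConfigurationError("offspring generation needs at least 2 parents")
    space = space or SearchSpace()
    rng = rng if rng is not None else np.random.default_rng()
    offspring: list[Individual] = []
    next_id = start_id
    for a, b in zip(p_best, p_best[1:]):
        c1, c2 = crossover_pair(a.genome, b.genome, config.crossover_rate, rng, space)
        for child in (c1, c2):
            child = mutate(child, config.mutation_rate, space, rng)
            offspring.append(Individual(genome=child, fitness=None, id=next_id))
            next_id += 1
    return offspring


def environmental_selection(
    pt: Sequence[Individual], qt: Sequence[Individual], k: int
) -> list[Individual]:
    """Next population = K best of Pt plus the |Pt|−K best of Qt; size is
    conserved and elites keep their cached fitness."""
    n_fill = len(pt) - k
    if len(qt) < n_fill:
        raise ConfigurationError(
            f"need at least {n_fill} offspring, got {len(qt)}"
        )
    return select_best(pt, k) + select_best(qt, n_fill)


def _better(a: Individual, b: Optional[Individual]) -> Individual:
    if b is None:
        return a
    return a if (a.fitness, -a.id) > (b.fitness, -b.id) else b


def run_search(
    config: GAConfig,
    train_data=None,
    val_data=None,
    space: Optional[SearchSpace] = None,
    fitness_fn: Optional[FitnessFn] = None,
) -> tuple[Individual, SearchLog]:
    """Full search loop; returns the best-ever individual and the log.

    Either datasets (for the default training fitness) or an explicit
    ``fitness_fn`` must be supplied.  Fully reproducible from
    ``config.master_seed``.
    """
    space = space or SearchSpace()
    if fitness_fn is None:
        if train_data is None or val_data is None:
            raise ConfigurationError("run_search needs datasets or a fitness_fn")
        fitness_fn = make_training_fitness(train_data, val_data, config.epochs_per_eval)

    init_ss, op_ss = np.random.SeedSequence(config.master_seed % _SEED_MOD).spawn(2)
    init_rng = np.random.default_rng(init_ss)
    op_rng = np.random.default_rng(op_ss)

    pop = [
        Individual(genome=sample_genome(space, init_rng), id=i)
        for i in range(config.population_size)
    ]
    next_id = config.population_size
    log = SearchLog()
    best_ever: Optional[Individual] = None
    evals = 0

    for t in range(config.generations):
        evals += sum(1 for ind in pop if not ind.has_fitness())
        pop = evaluate_population(pop, train_data, val_data, config, fitness_fn)
        parents = select_best(pop, config.n_best_parents)
        offspring = generate_offspring(parents, config, space, op_rng, start_id=next_id)
        next_id += len(offspring)
        evals += len(offspring)
        offspring = evaluate_population(offspring, train_data, val_data, config, fitness_fn)
        pop = environmental_selection(pop, offspring, config.n_best_parents)
        assert len(pop) == config.population_size
        gen_best = select_best(pop, 1)[0]
        best_ever = _better(gen_best, best_ever)
        log.append(
            generation=t,
            best_fitness=gen_best.fitness,
            mean_fitness=float(np.mean([ind.fitness for ind in pop])),
            best_genome_json=genome_to_json(gen_best.genome).replace("\n", " "),
            evals=evals,
            population_size=len(pop),
        )
    return best_ever, log
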