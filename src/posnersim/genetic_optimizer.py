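"""Island-model genetic algorithm for evolving the motor networks.

Five populations of 20 real-valued genomes (genes in ``[-3, 3)``) evolve
against the task fitness of :func:`posnersim.lif_network.evaluate_population`.
Each generation keeps the fittest genome of every population unchanged
(elitism) and fills the remaining slots with children produced by binary
tournament selection, uniform crossover and per-gene mutation (5% chance
of adding a uniform draw from ``[-0.3, 0.3)``, clipped back into the gene
interval).  Every 10 generations a copy of each population's fittest
genome migrates into a uniformly chosen other population, replacing a
random non-elite member there, so population sizes never change.

Fitness is re-evaluated every generation on freshly drawn trials (cue
durations and membrane noise), including the carried elite copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from posnersim.lif_network import (
    CUE_TYPES,
    Architecture,
    TaskSpec,
    evaluate_population,
    individual_error_rates,
    individual_median_rts,
)

__all__ = [
    "GAConfig",
    "EvolutionHistory",
    "init_populations",
    "tournament_select",
    "crossover",
    "mutate",
    "next_generation",
    "migrate",
    "evolve",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters."""

    n_populations: int = 5
    pop_size: int = 20
    generations: int = 300
    elite_count: int = 1
    tournament_size: int = 2
    mutation_rate: float = 0.05
    mutation_delta_range: tuple[float, float] = (-0.3, 0.3)
    gene_range: tuple[float, float] = (-3.0, 3.0)
    migration_interval: int = 10

    def __post_init__(self) -> None:
        if self.pop_size <= self.elite_count:
            raise ValueError("pop_size must exceed elite_count")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")

    @property
    def gene_max_inclusive(self) -> float:
        """Largest representable gene value below the half-open upper bound."""
        return float(np.nextafter(self.gene_range[1], self.gene_range[0]))


def init_populations(
    ga: GAConfig, genome_length: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Random initial populations, shape ``(n_populations, pop_size,
    genome_length)``, genes i.i.d. uniform on the gene interval."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo, hi = ga.gene_range
    return rng.uniform(lo, hi, size=(ga.n_populations, ga.pop_size, genome_length))


def tournament_select(
    population: np.ndarray, fitness: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Binary tournament: two distinct individuals are drawn uniformly
    and the fitter one is returned (exact ties decided by a coin)."""
    k = population.shape[0]
    if k == 1:
        return population[0].copy()
    i, j = rng.choice(k, size=2, replace=False)
    if fitness[i] > fitness[j]:
        winner = i
    elif fitness[j] > fitness[i]:
        winner = j
    else:
        winner = i if rng.random() < 0.5 else j
    return population[winner].copy()


def crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform crossover: each gene is copied from a uniformly chosen
    parent, independently."""
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must have equal length")
    take_a = rng.random(parent_a.shape[0]) < 0.5
    return np.where(take_a, parent_a, parent_b)


def mutate(genome: np.ndarray, ga: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene mutation: with probability ``mutation_rate`` add a
    uniform draw from the mutation interval, then clip back into the
    half-open gene interval."""
    out = np.asarray(genome, dtype=float).copy()
    mask = rng.random(out.shape[0]) < ga.mutation_rate
    if mask.any():
        lo_d, hi_d = ga.mutation_delta_range
        out[mask] += rng.uniform(lo_d, hi_d, size=int(mask.sum()))
        np.clip(out, ga.gene_range[0], ga.gene_max_inclusive, out=out)
    return out


def next_generation(
    population: np.ndarray,
    fitness: np.ndarray,
    ga: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Elite copy plus tournament/crossover/mutation children.

    The fittest individual (lowest index on ties) is carried unchanged to
    slot 0; the remaining ``pop_size - 1`` slots are children.
    """
    new = np.empty_like(population)
    elite = int(np.argmax(fitness))
    new[0] = population[elite]
    for c in range(1, population.shape[0]):
        parent_a = tournament_select(population, fitness, rng)
        parent_b = tournament_select(population, fitness, rng)
        new[c] = mutate(crossover(parent_a, parent_b, rng), ga, rng)
    return new


def migrate(
    populations: np.ndarray,
    fitness: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Copy each population's fittest genome into a uniformly chosen
    *other* population, replacing a uniformly chosen member that is not
    that population's fittest.  Sources keep their elite; sizes are
    unchanged.  Returns updated ``(populations, fitness)`` copies (the
    migrant carries its fitness value with it)."""
    n_pop, pop_size, _ = populations.shape
    populations = populations.copy()
    fitness = fitness.copy()
    if n_pop == 1:
        return populations, fitness
    elites = fitness.argmax(axis=1)
    migrants = [populations[p, elites[p]].copy() for p in range(n_pop)]
    migrant_fit = [fitness[p, elites[p]] for p in range(n_pop)]
    for p in range(n_pop):
        others = [q for q in range(n_pop) if q != p]
        dest = int(rng.choice(others))
        slots = [k for k in range(pop_size) if k != elites[dest]]
        slot = int(rng.choice(slots))
        populations[dest, slot] = migrants[p]
        fitness[dest, slot] = migrant_fit[p]
    return populations, fitness


@dataclass
class EvolutionHistory:
    """Per-generation record of an evolution run.

    ``populations_df`` has one row per (generation, population) with the
    best fitness and the elite's error rate and per-cue median RTs;
    ``median_rts`` holds every individual's median RT per cue type
    (generation, individual, cue ordered valid/neutral/invalid, NaN for
    null medians); ``error_rates`` the per-individual error rates.
    """

    populations_df: pd.DataFrame
    median_rts: np.ndarray  # (n_generations, G, 3)
    error_rates: np.ndarray  # (n_generations, G)
    final_populations: np.ndarray  # (n_populations, pop_size, genome_length)
    cue_order: tuple[str, ...] = CUE_TYPES

    @property
    def n_generations(self) -> int:
        return self.median_rts.shape[0]

    def mean_error_rate(self, generation: int = -1) -> float:
        """Population-wide mean error rate at a generation."""
        return float(self.error_rates[generation].mean())


def evolve(
    ga: GAConfig,
    architecture: Architecture,
    task: TaskSpec,
    rng: np.random.Generator | int | None = None,
    generations: int | None = None,
    evaluator=None,
    progress: bool = False,
) -> EvolutionHistory:
    """Run the full island-model loop and record its history.

    Each generation: evaluate all genomes (one vectorized simulation over
    the joined populations), record statistics, migrate elites on the
    migration schedule, then build the next generation of every
    population.  ``evaluator`` may replace the task evaluation (signature
    ``evaluator(genomes, rng) -> PopulationEvaluation``), e.g. to freeze
    the trial draws when testing elitism.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_gen = ga.generations if generations is None else generations
    if evaluator is None:
        def evaluator(genomes, rng):
            return evaluate_population(genomes, architecture, task, rng)

    pops = init_populations(ga, architecture.genome_length, rng)
    n_pop, pop_size, length = pops.shape
    g_total = n_pop * pop_size

    rows = []
    med_hist = np.empty((n_gen, g_total, len(CUE_TYPES)))
    err_hist = np.empty((n_gen, g_total))
    for gen in range(n_gen):
        ev = evaluator(pops.reshape(g_total, length), rng)
        fitness = ev.fitness.reshape(n_pop, pop_size)
        err = individual_error_rates(ev.outcome)
        med = individual_median_rts(ev.rt, ev.outcome, ev.cue_types)
        med_hist[gen] = med
        err_hist[gen] = err
        for p in range(n_pop):
            elite = int(np.argmax(fitness[p]))
            flat = p * pop_size + elite
            rows.append(
                {
                    "generation": gen,
                    "population": p,
                    "best_fitness": float(fitness[p, elite]),
                    "elite_error_rate": float(err[flat]),
                    "elite_median_rt_valid": med[flat, 0],
                    "elite_median_rt_neutral": med[flat, 1],
                    "elite_median_rt_invalid": med[flat, 2],
                }
            )
        if progress and gen % 10 == 0:
            best = float(fitness.max())
            print(f"generation {gen:4d}  best fitness {best:9.2f}  "
                  f"mean error {err.mean():.3f}", flush=True)
        if gen > 0 and gen % ga.migration_interval == 0:
            pops, fitness = migrate(pops, fitness, rng)
        pops = np.stack(
            [next_generation(pops[p], fitness[p], ga, rng) for p in range(n_pop)]
        )
    return EvolutionHistory(
        populations_df=pd.DataFrame(rows),
        median_rts=med_hist,
        error_rates=err_hist,
        final_populations=pops,
    )
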