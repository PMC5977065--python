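"""Real-coded genetic algorithm over box-bounded vectors.

A population of real vectors evolves for a fixed number of generations
under tournament selection (size 2), arithmetic (blend) crossover,
Gaussian mutation clipped to the bounds, and elitism.  Because elites are
carried over unchanged, the best fitness ever seen is non-worsening
across generations.  Termination is a fixed generation budget, which
keeps runs exactly reproducible under a seed.

The same engine serves two purposes in this package: searching the coded
design space over a fitted surrogate, and searching network weight space
in the hybrid trainer (optionally with a per-individual local-refinement
hook, the lamarckian variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAConfig",
    "Individual",
    "EvolutionHistory",
    "evolve",
    "tournament_select",
    "arithmetic_crossover",
    "gaussian_mutate",
]


@dataclass
class GAConfig:
    population_size: int = 30
    generations: int = 12
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_scale: float = 0.1  # fraction of each coordinate's range
    elitism_count: int = 2
    seed: int = 0
    maximize: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")


@dataclass(frozen=True)
class Individual:
    genome: np.ndarray
    fitness: float


@dataclass
class EvolutionHistory:
    """Per-generation best/mean fitness and the best genome so far."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_genome: list[np.ndarray] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": range(len(self.best_fitness)),
                "best": self.best_fitness,
                "mean": self.mean_fitness,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def tournament_select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    rng: np.random.Generator,
    maximize: bool = True,
) -> np.ndarray:
    """Size-2 tournament: sample two individuals, return the fitter genome."""
    i, j = rng.integers(0, len(population), size=2)
    better = (fitnesses[i] >= fitnesses[j]) if maximize else (fitnesses[i] <= fitnesses[j])
    return population[i if better else j].copy()


def arithmetic_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Blend crossover: children are complementary convex combinations.

    A single mixing weight u ~ U(0,1) per pair keeps children inside the
    parents' coordinate-wise intervals (hence inside any box both parents
    satisfy).
    """
    u = rng.uniform()
    return u * a + (1.0 - u) * b, (1.0 - u) * a + u * b


def gaussian_mutate(
    genome: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    mutation_prob: float,
    mutation_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene Gaussian perturbation (sd = scale·range), clipped to bounds."""
    lower, upper = bounds
    out = genome.copy()
    mask = rng.uniform(size=len(genome)) < mutation_prob
    if mask.any():
        sd = mutation_scale * (upper - lower)
        out[mask] += rng.normal(0.0, sd[mask])
        np.clip(out, lower, upper, out=out)
    return out


def _as_bounds(
    bounds: Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(bounds, tuple) and len(bounds) == 2 and np.ndim(bounds[0]) > 0:
        lower = np.asarray(bounds[0], dtype=float)
        upper = np.asarray(bounds[1], dtype=float)
    else:
        arr = np.asarray(bounds, dtype=float)
        lower, upper = arr[:, 0], arr[:, 1]
    if not np.all(lower < upper):
        raise ValueError("each lower bound must be strictly below its upper bound")
    return lower, upper


def evolve(
    fitness_fn: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    config: GAConfig,
    refine: Callable[[np.ndarray], np.ndarray] | None = None,
    init_bounds: Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[Individual, EvolutionHistory]:
    """Evolve a population on the box and return the best-ever individual.

    ``refine``, when given, maps each genome to a locally improved genome
    before fitness evaluation and the improvement is written back into the
    population (lamarckian local search, used by the hybrid trainer).
    ``init_bounds`` restricts the initial sampling to a sub-box of the
    feasible region — useful when the search box is deliberately generous,
    as for network weights where large initial values saturate every
    activation.  Raises if ``fitness_fn`` returns a non-finite value,
    reporting the offending genome.
    """
    lower, upper = _as_bounds(bounds)
    init_lower, init_upper = (
        (lower, upper) if init_bounds is None else _as_bounds(init_bounds)
    )
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, len(lower)

    def assess(pop: np.ndarray) -> np.ndarray:
        vals = np.empty(len(pop))
        for i, g in enumerate(pop):
            if refine is not None:
                pop[i] = np.clip(refine(g), lower, upper)
            v = float(fitness_fn(pop[i]))
            if not np.isfinite(v):
                raise ValueError(f"non-finite fitness {v} at genome {pop[i]!r}")
            vals[i] = v
        return vals

    population = rng.uniform(init_lower, init_upper, size=(n, d))
    fitnesses = assess(population)
    sign = 1.0 if config.maximize else -1.0

    best_idx = int(np.argmax(sign * fitnesses))
    best = Individual(population[best_idx].copy(), float(fitnesses[best_idx]))
    history = EvolutionHistory()

    def record() -> None:
        history.best_fitness.append(best.fitness)
        history.mean_fitness.append(float(fitnesses.mean()))
        history.best_genome.append(best.genome.copy())

    record()
    for _ in range(config.generations):
        order = np.argsort(-sign * fitnesses, kind="stable")
        elites = population[order[: config.elitism_count]].copy()
        children: list[np.ndarray] = [e for e in elites]
        while len(children) < n:
            p1 = tournament_select(population, fitnesses, rng, config.maximize)
            p2 = tournament_select(population, fitnesses, rng, config.maximize)
            if rng.uniform() < config.crossover_prob:
                c1, c2 = arithmetic_crossover(p1, p2, rng)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                if len(children) < n:
                    children.append(
                        gaussian_mutate(
                            child, (lower, upper),
                            config.mutation_prob, config.mutation_scale, rng,
                        )
                    )
        population = np.array(children)
        fitnesses = assess(population)
        gen_best = int(np.argmax(sign * fitnesses))
        if sign * fitnesses[gen_best] > sign * best.fitness:
            best = Individual(population[gen_best].copy(), float(fitnesses[gen_best]))
        record()
    return best, history
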