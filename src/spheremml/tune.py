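"""Differential-Evolution self-adjustment of the (att, bound) hyperparameters.

The two integers controlling the learning phase — the number of candidate
attributes kept after error ranking (``att``) and the number of progressive
boundaries / votes (``bound``) — are tuned by minimizing the training
error with a small integer-coded Differential Evolution loop: trial
vectors ``x_c + F (x_a - x_b)`` are rounded, repaired into bounds (and to
``bound <= att``), recombined with the target and kept when strictly
better.

Two crossover variants are available.  ``binomial`` (default) is the
canonical per-coordinate crossover with a guaranteed mutant coordinate.
``gate`` applies the recombination probability as a single all-or-nothing
gate on the trial evaluation, which never mixes coordinates between the
mutant and the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BoundaryModel, learn
from .dataset import LabeledDataset


@dataclass
class DEConfig:
    """Differential-Evolution controls.

    Defaults are canonical small-budget DE settings: population 20,
    mutation factor 0.5, recombination probability 0.9, 30 generations.
    ``att_bounds=None`` resolves to ``(bound_bounds[0], min(L, 200))`` at
    run time, where L is the attribute count of the training data.
    """

    population_size: int = 20
    mutation_factor: float = 0.5
    recombination_probability: float = 0.9
    generations: int = 30
    att_bounds: tuple[int, int] | None = None
    bound_bounds: tuple[int, int] = (1, 15)
    seed: int = 0
    crossover: str = "binomial"
    att_is_percent: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (three donors plus target)")
        if not 0 < self.mutation_factor <= 2:
            raise ValueError("mutation_factor must be in (0, 2]")
        if not 0 <= self.recombination_probability <= 1:
            raise ValueError("recombination_probability must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.crossover not in ("binomial", "gate"):
            raise ValueError(f"unknown crossover {self.crossover!r}")

    def resolve(self, n_attributes: int) -> "DEConfig":
        """Fill in data-dependent bounds and validate feasibility."""
        att_bounds = self.att_bounds
        if att_bounds is None:
            att_bounds = (self.bound_bounds[0], min(n_attributes, 200))
        if att_bounds[0] > att_bounds[1] or self.bound_bounds[0] > self.bound_bounds[1]:
            raise ValueError("empty hyperparameter interval")
        if self.bound_bounds[0] > att_bounds[1]:
            raise ValueError(
                f"bound lower limit {self.bound_bounds[0]} exceeds att upper "
                f"limit {att_bounds[1]}: no feasible (att, bound)"
            )
        return replace(self, att_bounds=att_bounds)


@dataclass
class Individual:
    """One candidate (att, bound) with its training-error fitness."""

    att: int
    bound: int
    fitness: int | None = None


def _round_half_away(v: np.ndarray) -> np.ndarray:
    return np.where(v >= 0, np.floor(v + 0.5), np.ceil(v - 0.5)).astype(int)


def _repair(att: int, bound: int, config: DEConfig) -> tuple[int, int]:
    att = int(np.clip(att, *config.att_bounds))
    bound = int(np.clip(bound, *config.bound_bounds))
    return att, min(bound, att)


def _evaluate(train: LabeledDataset, ind: Individual, config: DEConfig, cache: dict) -> int:
    key = (ind.att, ind.bound)
    if key not in cache:
        model = learn(train, ind.att, ind.bound, att_is_percent=config.att_is_percent)
        cache[key] = model.training_error
    return cache[key]


def initialize_population(
    train: LabeledDataset, config: DEConfig, rng: np.random.Generator
) -> list[Individual]:
    """Uniform integer draws from the bounded intervals, evaluated."""
    config = config.resolve(train.n_attributes)
    cache: dict = {}
    pop = []
    for _ in range(config.population_size):
        att = int(rng.integers(config.att_bounds[0], config.att_bounds[1] + 1))
        bound = int(rng.integers(config.bound_bounds[0], config.bound_bounds[1] + 1))
        att, bound = _repair(att, bound, config)
        ind = Individual(att, bound)
        ind.fitness = _evaluate(train, ind, config, cache)
        pop.append(ind)
    return pop


def propose(
    target_index: int,
    population: list[Individual],
    config: DEConfig,
    rng: np.random.Generator,
) -> Individual:
    """Build one trial individual for the target by mutation + crossover.

    Three distinct donors a, b, c (all different from the target) give
    the mutant ``x_c + F (x_a - x_b)``, rounded half-away-from-zero and
    repaired into bounds with ``bound <= att``.  Binomial crossover then
    mixes mutant and target per coordinate with probability
    ``recombination_probability``, guaranteeing at least one mutant
    coordinate; the ``gate`` variant returns the repaired mutant as is.
    """
    idx = [i for i in range(len(population)) if i != target_index]
    a, b, c = rng.choice(idx, size=3, replace=False)
    xa = np.array([population[a].att, population[a].bound], dtype=float)
    xb = np.array([population[b].att, population[b].bound], dtype=float)
    xc = np.array([population[c].att, population[c].bound], dtype=float)
    mutant = _round_half_away(xc + config.mutation_factor * (xa - xb))
    att, bound = _repair(int(mutant[0]), int(mutant[1]), config)
    if config.crossover == "binomial":
        target = population[target_index]
        trial = np.array([att, bound])
        keep = rng.random(2) < config.recombination_probability
        keep[int(rng.integers(2))] = True  # guaranteed mutant coordinate
        base = np.array([target.att, target.bound])
        trial = np.where(keep, trial, base)
        att, bound = _repair(int(trial[0]), int(trial[1]), config)
    return Individual(att, bound)


def evolve(
    train: LabeledDataset, config: DEConfig
) -> tuple[Individual, BoundaryModel, list[int]]:
    """Run DE and return the best individual, its model, and the history
    of best fitness (initial population first, then one entry per
    generation; non-increasing).

    Replacement is greedy minimization: a trial replaces its target only
    when its training error is strictly smaller.
    """
    config = config.resolve(train.n_attributes)
    rng = np.random.default_rng(config.seed)
    cache: dict = {}
    population = []
    for _ in range(config.population_size):
        att = int(rng.integers(config.att_bounds[0], config.att_bounds[1] + 1))
        bound = int(rng.integers(config.bound_bounds[0], config.bound_bounds[1] + 1))
        att, bound = _repair(att, bound, config)
        ind = Individual(att, bound)
        ind.fitness = _evaluate(train, ind, config, cache)
        population.append(ind)

    history = [min(ind.fitness for ind in population)]
    for _ in range(config.generations):
        for i in range(config.population_size):
            if config.crossover == "gate":
                # single all-or-nothing gate on the trial evaluation
                trial = propose(i, population, config, rng)
                if rng.random() >= config.recombination_probability:
                    continue
            else:
                trial = propose(i, population, config, rng)
            trial.fitness = _evaluate(train, trial, config, cache)
            if trial.fitness < population[i].fitness:
                population[i] = trial
        history.append(min(ind.fitness for ind in population))

    best = min(population, key=lambda ind: ind.fitness)
    model = learn(train, best.att, best.bound, att_is_percent=config.att_is_percent)
    return best, model, history
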