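"""Evolutionary joint selection of variables and a record bipartition.

A genome concatenates a boolean variable mask with a boolean record
assignment (subset A vs B).  Fitness is the blind two-way KNN accuracy —
train on A / test on B and vice versa, restricted to the masked variables —
minus a small parsimony pressure on the number of selected variables and a
soft penalty on the distributional divergence of the two subsets.  The
search is a seeded generational GA with tournament selection, uniform
crossover, per-bit mutation, elitism and an invariant-restoring repair step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .learners import KNNClassifier
from .validation import distribution_equivalence, two_subset_protocol

__all__ = ["EvolutionConfig", "TwistSolution", "fitness", "evolve", "export_selection"]


@dataclass(frozen=True)
class EvolutionConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.02
    elitism: int = 2
    tournament_size: int = 3
    stagnation_patience: int = 25
    seed: int = 0
    k: int = 1
    parsimony_weight: float = 0.01
    divergence_weight: float = 0.05

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must be in [0, population_size)")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.parsimony_weight < 0 or self.divergence_weight < 0:
            raise ValueError("penalty weights must be >= 0")


@dataclass
class TwistSolution:
    variable_mask: np.ndarray
    record_assignment: np.ndarray
    fitness: float
    divergence_penalty: float = 0.0

    @property
    def n_selected(self) -> int:
        return int(self.variable_mask.sum())


def _is_valid(mask: np.ndarray, assignment: np.ndarray, labels: np.ndarray) -> bool:
    if not mask.any():
        return False
    for part in (assignment, ~assignment):
        if not part.any():
            return False
        if len(np.unique(labels[part])) < 2:
            return False
    return True


def fitness(
    solution: TwistSolution,
    data: np.ndarray,
    labels: np.ndarray,
    config: EvolutionConfig,
) -> float:
    """Score a solution; invariant-violating solutions score exactly 0."""
    x = np.asarray(getattr(data, "values", data), dtype=float)
    y = np.asarray(labels, dtype=object)
    mask = np.asarray(solution.variable_mask, dtype=bool)
    assignment = np.asarray(solution.record_assignment, dtype=bool)
    if not _is_valid(mask, assignment, y):
        return 0.0
    report = two_subset_protocol(
        x[:, mask], y, lambda: KNNClassifier(k=config.k), assignment
    )
    divergence = distribution_equivalence(x[:, mask], assignment).max_divergence
    solution.divergence_penalty = config.divergence_weight * divergence
    score = (
        report.w_mean / 100.0
        - config.parsimony_weight * float(mask.mean())
        - solution.divergence_penalty
    )
    return float(np.clip(score, 0.0, 1.0))


def _repair(
    genome: np.ndarray, n_vars: int, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Restore solution invariants in place: non-empty mask, both classes in
    both subsets."""
    mask = genome[:n_vars]
    assignment = genome[n_vars:]
    if not mask.any():
        mask[rng.integers(n_vars)] = True
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        side = assignment[idx]
        if side.all():
            assignment[idx[rng.integers(len(idx))]] = False
        elif not side.any():
            assignment[idx[rng.integers(len(idx))]] = True
    return genome


def _stratified_assignment(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random ~50/50 assignment balanced within each class."""
    assignment = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        assignment[idx[: len(idx) // 2]] = True
    return assignment


def evolve(
    data,
    labels: np.ndarray,
    config: EvolutionConfig | None = None,
) -> tuple[TwistSolution, pd.DataFrame]:
    """Run the GA; returns the best-ever solution and a per-generation history.

    History columns: generation, best_fitness (best-ever, non-decreasing by
    elitism), mean_fitness, evaluations (cumulative distinct genomes scored).
    """
    config = config or EvolutionConfig()
    config.validate()
    x = np.asarray(getattr(data, "values", data), dtype=float)
    y = np.asarray(labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 records each")
    n_vars = x.shape[1]
    genome_len = n_vars + len(y)
    rng = np.random.default_rng(config.seed)

    cache: dict[bytes, float] = {}

    def score(genome: np.ndarray) -> float:
        key = np.packbits(genome).tobytes()
        if key not in cache:
            sol = TwistSolution(genome[:n_vars], genome[n_vars:], 0.0)
            cache[key] = fitness(sol, x, y, config)
        return cache[key]

    population = []
    for _ in range(config.population_size):
        genome = np.empty(genome_len, dtype=bool)
        genome[:n_vars] = rng.random(n_vars) < 0.5
        genome[n_vars:] = _stratified_assignment(y, rng)
        population.append(_repair(genome, n_vars, y, rng))
    scores = np.asarray([score(g) for g in population])

    best_idx = int(np.argmax(scores))
    best_genome = population[best_idx].copy()
    best_fitness = float(scores[best_idx])
    history_rows = []
    stagnant = 0

    def tournament() -> np.ndarray:
        contenders = rng.integers(config.population_size, size=config.tournament_size)
        return population[contenders[np.argmax(scores[contenders])]]

    for generation in range(config.generations):
        history_rows.append({
            "generation": generation,
            "best_fitness": best_fitness,
            "mean_fitness": float(scores.mean()),
            "evaluations": len(cache),
        })
        elite_order = np.argsort(-scores, kind="stable")[: config.elitism]
        offspring = [population[i].copy() for i in elite_order]
        while len(offspring) < config.population_size:
            parent_a = tournament()
            parent_b = tournament()
            if rng.random() < config.crossover_rate:
                take_b = rng.random(genome_len) < 0.5
                child = np.where(take_b, parent_b, parent_a)
            else:
                child = parent_a.copy()
            flip = rng.random(genome_len) < config.mutation_rate
            child = child ^ flip
            offspring.append(_repair(child, n_vars, y, rng))
        population = offspring
        scores = np.asarray([score(g) for g in population])
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_fitness:
            best_fitness = float(scores[gen_best])
            best_genome = population[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= config.stagnation_patience:
            break

    history_rows.append({
        "generation": len(history_rows),
        "best_fitness": best_fitness,
        "mean_fitness": float(scores.mean()),
        "evaluations": len(cache),
    })
    best = TwistSolution(
        variable_mask=best_genome[:n_vars].copy(),
        record_assignment=best_genome[n_vars:].copy(),
        fitness=best_fitness,
    )
    fitness(best, x, y, config)  # refresh divergence_penalty for reporting
    return best, pd.DataFrame(history_rows)


def export_selection(solution: TwistSolution, column_names: list[str]) -> pd.DataFrame:
    """Two-column selection report: every original variable vs the selected
    subset (blank where dropped), preserving input order."""
    if len(column_names) != len(solution.variable_mask):
        raise ValueError("column_names length does not match variable mask")
    return pd.DataFrame({
        "original_input": column_names,
        "selected": [
            name if keep else ""
            for name, keep in zip(column_names, solution.variable_mask)
        ],
    })
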