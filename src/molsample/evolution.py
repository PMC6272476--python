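"""Population management and evolutionary strategies.

Three strategies share the same operators and diversity machinery:

* ``evol``  -- steady-state: each member may spawn a crossover child (with a
  random partner) and/or a mutant per generation; offspring enter through
  the diversity rules below.
* ``sga``   -- generational: a full offspring population is bred and
  replaces the old one.
* ``ega``   -- elitist generational: like ``sga`` but the top 20% of the
  population is immune to replacement, mutation and randomization.

Diversity control rests on the pairwise-interaction-fingerprint (PIF)
originality ω -- the smallest fingerprint distance to any strictly fitter
individual.  An offspring first tries to replace the most redundant member
(energy excess compensated by diversity gain at an exchange rate ``div2e``
kcal/mol per unit distance); only if that fails does it compete against its
parents.  Once per generation, redundant members may additionally be
re-randomized in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fingerprints import ORIGINALITY_MAX, PIFLayout, compute_pif, \
    originality, pif_distance
from .operators import SamplingContext, cross, local_opt, mutate, random_init

REDUNDANCY_MARGIN = 1.1  # members with ω <= 1.1 * ω_min count as redundant


@dataclass
class Individual:
    """A conformation chromosome with cached score and fingerprint."""

    coords: np.ndarray
    energy: float
    pif: np.ndarray
    originality: float = ORIGINALITY_MAX


@dataclass
class EvolutionConfig:
    strategy: str = "evol"
    population_size: int = 50
    generations: int = 500
    p_mut: float = 0.1
    p_cross: float = 0.1
    minfpdiff: float = 0.01
    div2e: float = 100.0
    elite_fraction: float = 0.20
    seed: int = 0
    # orientation of the randomization trigger: the default targets
    # low-originality (redundant) members with probability
    # clip(1 - ω/minfpdiff); the literal printed formula rand() < ω/minfpdiff
    # (which targets original members) is available behind this flag.
    randomize_literal: bool = False
    randomize_attempts: int = 5

    def __post_init__(self):
        if self.strategy not in ("sga", "evol", "ega"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for p in (self.p_mut, self.p_cross, self.elite_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 2 or self.generations < 0:
            raise ValueError("population_size >= 2 and generations >= 0")

    @property
    def elite_count(self) -> int:
        return int(math.ceil(self.elite_fraction * self.population_size))


@dataclass
class EvolutionResult:
    population: list[Individual]
    archive: list[Individual]          # energy-sorted distinct poses
    best: Individual
    trace: list[dict] = field(default_factory=list)

    def log_tsv(self) -> str:
        header = "generation\tbest_energy\tmean_energy\tmin_delta\tmean_delta"
        lines = [header]
        for row in self.trace:
            lines.append("{generation}\t{best_energy:.6f}\t{mean_energy:.6f}"
                         "\t{min_delta:.6f}\t{mean_delta:.6f}".format(**row))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# individuals and bookkeeping
# ---------------------------------------------------------------------------

def make_individual(ctx: SamplingContext, layout: PIFLayout,
                    coords: np.ndarray) -> Individual:
    return Individual(coords=coords,
                      energy=ctx.model.energy(coords).total,
                      pif=compute_pif(layout, coords))


def refresh_originality(population: Sequence[Individual]) -> None:
    energies = [m.energy for m in population]
    pifs = [m.pif for m in population]
    for m in population:
        m.originality = originality(m.energy, m.pif, energies, pifs)


class Archive:
    """So-far-visited poses, deduplicated by rounded (energy, PIF)."""

    def __init__(self):
        self._store: dict[tuple, Individual] = {}

    def add(self, ind: Individual) -> None:
        key = (round(ind.energy, 3),
               tuple(np.round(ind.pif, 3).tolist()))
        old = self._store.get(key)
        if old is None or ind.energy < old.energy:
            self._store[key] = ind

    def sorted(self) -> list[Individual]:
        return sorted(self._store.values(), key=lambda m: m.energy)


# ---------------------------------------------------------------------------
# diversity-controlled entry rules
# ---------------------------------------------------------------------------

def replace_most_redundant(population: list[Individual],
                           offspring: Individual,
                           config: EvolutionConfig,
                           immune: Sequence[int] = ()) -> bool:
    """Try to let the offspring replace the most redundant (MR) member.

    MR is the least-fit member among those with ω <= 1.1 * ω_min.  The
    offspring enters iff it is strictly more original than MR and its energy
    excess is compensated: E(O) - E(MR) <= div2e * (ω(O) - ω(MR)).
    Mutates ``population`` in place and returns True on replacement.
    """
    candidates = [i for i in range(len(population)) if i not in set(immune)]
    if not candidates:
        return False
    omega_min = min(population[i].originality for i in candidates)
    redundant = [i for i in candidates
                 if population[i].originality <= REDUNDANCY_MARGIN * omega_min]
    mr = max(redundant, key=lambda i: population[i].energy)
    mr_omega = population[mr].originality
    if not np.isfinite(mr_omega):
        return False
    gain = offspring.originality - mr_omega
    if gain <= 0:
        return False
    if offspring.energy - population[mr].energy <= config.div2e * gain:
        population[mr] = offspring
        return True
    return False


def might_replace(population: list[Individual],
                  parent_indices: Sequence[int],
                  offspring: Individual,
                  immune: Sequence[int] = ()) -> bool:
    """Parent competition: replace the least-fit parent iff strictly fitter."""
    eligible = [i for i in parent_indices if i not in set(immune)]
    if not eligible:
        return False
    worst = max(eligible, key=lambda i: population[i].energy)
    if offspring.energy < population[worst].energy:
        population[worst] = offspring
        return True
    return False


def randomize_if_redundant(ctx: SamplingContext, layout: PIFLayout,
                           population: list[Individual],
                           config: EvolutionConfig,
                           rng: np.random.Generator,
                           immune: Sequence[int] = (),
                           archive: Optional[Archive] = None) -> int:
    """Once-per-generation in-place randomization of redundant members.

    Each non-immune member I is considered with a probability derived from
    its originality (see :class:`EvolutionConfig.randomize_literal`); when
    triggered, up to 5 random_init attempts seek a replacement M accepted
    when E(M) - E(I) < div2e * (ω(M) - ω(I)).  Returns the number of members
    replaced.
    """
    replaced = 0
    immune_set = set(immune)
    for idx in range(len(population)):
        if idx in immune_set:
            continue
        member = population[idx]
        omega = member.originality
        if config.randomize_literal:
            prob = math.inf if config.minfpdiff == 0 else \
                omega / config.minfpdiff
        else:
            prob = 0.0 if not np.isfinite(omega) else \
                min(max(1.0 - omega / config.minfpdiff, 0.0), 1.0)
        if not rng.uniform() < prob:
            continue
        energies = [m.energy for m in population]
        pifs = [m.pif for m in population]
        for _ in range(config.randomize_attempts):
            cand = make_individual(ctx, layout,
                                   random_init(ctx, member.coords, rng))
            cand.originality = originality(cand.energy, cand.pif,
                                           energies, pifs)
            omega_i = omega if np.isfinite(omega) else 0.0
            gain = cand.originality - omega_i
            if cand.energy - member.energy < config.div2e * gain:
                population[idx] = cand
                if archive is not None:
                    archive.add(cand)
                replaced += 1
                break
    return replaced


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def _trace_row(generation: int, population: Sequence[Individual]) -> dict:
    energies = np.array([m.energy for m in population])
    deltas = []
    for i in range(len(population)):
        for j in range(i + 1, len(population)):
            deltas.append(pif_distance(population[i].pif,
                                       population[j].pif))
    deltas = np.array(deltas) if deltas else np.array([0.0])
    return {"generation": generation,
            "best_energy": float(energies.min()),
            "mean_energy": float(energies.mean()),
            "min_delta": float(deltas.min()),
            "mean_delta": float(deltas.mean())}


def _spawn_offspring(ctx, layout, population, i, rng, config,
                     ) -> tuple[Optional[Individual], list[int]]:
    """Crossover and/or mutation for member i; returns (child, parents)."""
    if rng.uniform() < config.p_cross:
        j = int(rng.integers(len(population)))
        while j == i and len(population) > 1:
            j = int(rng.integers(len(population)))
        child = cross(ctx, population[i].coords, population[j].coords, rng)
        return make_individual(ctx, layout, child), [i, j]
    return None, [i]


def run(ctx: SamplingContext, layout: PIFLayout, config: EvolutionConfig,
        start_coords: np.ndarray,
        rng: Optional[np.random.Generator] = None) -> EvolutionResult:
    """Run one evolutionary sampling job.

    The initial population is ``population_size`` seeded random_init
    restarts from ``start_coords``.  Per generation: crossovers with
    probability p_cross, mutations with p_mut, strategy-specific
    replacement, then the redundancy randomization sweep.  Every LO-refined
    individual is archived; the archive's best energy is non-increasing in
    the generation index.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    archive = Archive()
    population = []
    for _ in range(config.population_size):
        ind = make_individual(ctx, layout, random_init(ctx, start_coords, rng))
        population.append(ind)
        archive.add(ind)
    refresh_originality(population)
    trace = [_trace_row(0, population)]

    for gen in range(1, config.generations + 1):
        if config.strategy == "evol":
            _steady_state_generation(ctx, layout, population, config, rng,
                                     archive)
            immune: list[int] = []
        else:
            immune = _generational_generation(ctx, layout, population,
                                              config, rng, archive)
        refresh_originality(population)
        randomize_if_redundant(ctx, layout, population, config, rng,
                               immune=immune, archive=archive)
        refresh_originality(population)
        trace.append(_trace_row(gen, population))

    best = min(population, key=lambda m: m.energy)
    arch = archive.sorted()
    if arch and arch[0].energy < best.energy:
        best = arch[0]
    return EvolutionResult(population=population, archive=arch,
                           best=best, trace=trace)


def _steady_state_generation(ctx, layout, population, config, rng,
                             archive) -> None:
    n = len(population)
    for i in range(n):
        child, parents = _spawn_offspring(ctx, layout, population, i, rng,
                                          config)
        if child is not None:
            _enter(population, child, parents, config, archive)
        if rng.uniform() < config.p_mut:
            mutant = make_individual(ctx, layout,
                                     mutate(ctx, population[i].coords, rng))
            _enter(population, mutant, [i], config, archive)


def _enter(population, offspring, parents, config, archive,
           immune: Sequence[int] = ()) -> None:
    archive.add(offspring)
    refresh_originality(population)
    offspring.originality = originality(offspring.energy, offspring.pif,
                                        [m.energy for m in population],
                                        [m.pif for m in population])
    if replace_most_redundant(population, offspring, config, immune=immune):
        return
    might_replace(population, parents, offspring, immune=immune)


def _generational_generation(ctx, layout, population, config, rng,
                             archive) -> list[int]:
    """SGA / EGA: breed a full offspring population.

    Returns the (new) indices of elite members for EGA, [] for SGA.
    """
    n = len(population)
    order = sorted(range(n), key=lambda i: population[i].energy)
    n_elite = config.elite_count if config.strategy == "ega" else 0
    elites = [population[order[r]] for r in range(n_elite)]
    offspring: list[Individual] = []
    while len(offspring) < n - n_elite:
        i = int(rng.integers(n))
        if rng.uniform() < config.p_cross:
            j = int(rng.integers(n))
            while j == i:
                j = int(rng.integers(n))
            child_coords = cross(ctx, population[i].coords,
                                 population[j].coords, rng)
        elif rng.uniform() < config.p_mut:
            child_coords = mutate(ctx, population[i].coords, rng)
        else:
            child_coords = local_opt(ctx, population[i].coords, rng)
        child = make_individual(ctx, layout, child_coords)
        archive.add(child)
        offspring.append(child)
    population[:] = elites + offspring
    return list(range(len(elites)))
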