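"""Continuous Golden Eagle Optimization (GEO).

GEO is a population metaheuristic modelled on golden-eagle hunting: each
eagle remembers the best point it has visited ("prey" memory), and at every
iteration combines an *attack* vector pointing from its current position to
the memory of a randomly chosen eagle with a *cruise* vector lying on the
hyperplane through its position perpendicular to the attack.  The relative
weight of the two components follows a linear propensity schedule that
shifts from cruising (exploration) to attacking (exploitation) over the run.

The step taken is

    dx = r1 * pa(t) * A  +  r2 * pc(t) * ||A|| * C/||C||

with r1, r2 ~ U(0,1): the attack term is proportional to the distance to the
prey and the cruise term is scaled to the same magnitude, so steps contract
as the population converges, giving geometric refinement of the optimum.
When the attack vector is degenerate (eagle sitting on its prey) the cruise
direction is a uniform random unit vector with unit scale, which keeps the
eagle moving.  Minimization convention throughout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """A box-bounded continuous search domain."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lower < upper):
            raise ValueError("require lower[d] < upper[d] for every dimension")

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass
class Eagle:
    """One search agent: current position plus elitist memory of its best."""

    position: np.ndarray
    fitness: float
    memory_position: np.ndarray
    memory_fitness: float


@dataclass(frozen=True)
class PropensitySchedule:
    """Linear attack/cruise propensity interpolation over T iterations.

    Defaults move from exploration (low attack, high cruise) to
    exploitation (high attack, low cruise).
    """

    pa0: float = 0.5
    paT: float = 2.0
    pc0: float = 1.0
    pcT: float = 0.5
    T: int = 100

    def __post_init__(self):
        if min(self.pa0, self.paT, self.pc0, self.pcT) < 0:
            raise ValueError("propensities must be nonnegative")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    def pa(self, t: float) -> float:
        return self.pa0 + (t / self.T) * (self.paT - self.pa0)

    def pc(self, t: float) -> float:
        return self.pc0 + (t / self.T) * (self.pcT - self.pc0)


@dataclass(frozen=True)
class GEOConfig:
    population_size: int = 50
    iterations: int = 100
    seed: int = 0
    epsilon: float = 1e-12
    schedule: Optional[PropensitySchedule] = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.schedule is None:
            object.__setattr__(self, "schedule", PropensitySchedule(T=self.iterations))


@dataclass
class GEOResult:
    best_position: np.ndarray
    best_fitness: float
    history: List[float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "best_position": [float(v) for v in self.best_position],
                "best_fitness": float(self.best_fitness),
                "history": [float(v) for v in self.history],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GEOResult":
        d = json.loads(text)
        return cls(
            best_position=np.asarray(d["best_position"], dtype=float),
            best_fitness=float(d["best_fitness"]),
            history=list(d["history"]),
        )


def _evaluate(objective: Objective, x: np.ndarray, strict: bool) -> float:
    value = float(objective(x))
    if not math.isfinite(value):
        if strict:
            raise ValueError(f"objective is non-finite at point {x.tolist()}")
        logger.warning("non-finite objective at %s; treated as +inf", x.tolist())
        return math.inf
    return value


def init_population(
    space: SearchSpace, config: GEOConfig, objective: Objective,
    rng: Optional[np.random.Generator] = None,
) -> List[Eagle]:
    """Place eagles at independent uniform positions; memory = own start."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eagles = []
    for _ in range(config.population_size):
        pos = rng.uniform(space.lower, space.upper)
        fit = _evaluate(objective, pos, strict=True)
        eagles.append(Eagle(pos, fit, pos.copy(), fit))
    return eagles


def select_prey(eagle_index: int, population: Sequence[Eagle],
                rng: np.random.Generator) -> np.ndarray:
    """Memory position of a uniformly chosen eagle (self allowed)."""
    if len(population) == 0:
        raise ValueError("population is empty")
    j = int(rng.integers(len(population)))
    return population[j].memory_position


def attack_vector(eagle: Eagle, prey: np.ndarray) -> np.ndarray:
    """Displacement from the eagle's position to the prey."""
    prey = np.asarray(prey, dtype=float)
    if prey.shape != eagle.position.shape:
        raise ValueError("prey and position dimensions differ")
    return prey - eagle.position


def cruise_vector(eagle: Eagle, attack: np.ndarray, space: SearchSpace,
                  rng: np.random.Generator, epsilon: float = 1e-12) -> np.ndarray:
    """A direction on the hyperplane through the position perpendicular to the attack.

    A destination point is drawn on the hyperplane {x : attack . (x - position) = 0}
    by fixing one coordinate k with |attack[k]| > epsilon (chosen uniformly among
    eligible indices), drawing the remaining coordinates uniformly within bounds and
    solving coordinate k from the hyperplane equation; the cruise vector is
    destination - position.  If the attack is degenerate (norm <= epsilon) a uniform
    random unit direction is returned instead.
    """
    attack = np.asarray(attack, dtype=float)
    if attack.shape != eagle.position.shape:
        raise ValueError("attack and position dimensions differ")
    dim = attack.shape[0]
    if np.linalg.norm(attack) <= epsilon:
        u = rng.standard_normal(dim)
        n = np.linalg.norm(u)
        while n <= epsilon:  # astronomically rare
            u = rng.standard_normal(dim)
            n = np.linalg.norm(u)
        return u / n
    eligible = np.flatnonzero(np.abs(attack) > epsilon)
    k = int(eligible[rng.integers(len(eligible))])
    dest = rng.uniform(space.lower, space.upper)
    # solve attack . dest = attack . position for coordinate k
    rhs = float(attack @ eagle.position) - (float(attack @ dest) - attack[k] * dest[k])
    dest[k] = rhs / attack[k]
    cruise = dest - eagle.position
    if np.linalg.norm(cruise) <= epsilon:
        # destination coincided with the position (measure zero, dim >= 2);
        # in 1-D the perpendicular hyperplane is the point itself
        if dim == 1:
            return np.zeros(1)
        u = rng.standard_normal(dim)
        u -= (u @ attack) / (attack @ attack) * attack
        n = np.linalg.norm(u)
        return u / n if n > epsilon else np.zeros(dim)
    return cruise


def step_update(eagle: Eagle, attack: np.ndarray, cruise: np.ndarray, t: float,
                schedule: PropensitySchedule, rng: np.random.Generator,
                space: SearchSpace, epsilon: float = 1e-12) -> np.ndarray:
    """New position after one attack-plus-cruise step, clipped to bounds.

    dx = r1*pa(t)*attack + r2*pc(t)*scale*cruise_hat, where scale is the
    attack norm (unit if the attack is degenerate); zero-norm terms drop out.
    """
    attack = np.asarray(attack, dtype=float)
    cruise = np.asarray(cruise, dtype=float)
    na = np.linalg.norm(attack)
    nc = np.linalg.norm(cruise)
    r1 = rng.uniform()
    r2 = rng.uniform()
    dx = np.zeros_like(eagle.position)
    if na > epsilon:
        dx = dx + r1 * schedule.pa(t) * attack
        scale = na
    else:
        scale = 1.0
    if nc > epsilon:
        dx = dx + r2 * schedule.pc(t) * scale * (cruise / nc)
    return space.clip(eagle.position + dx)


def run_geo(
    space: SearchSpace,
    config: GEOConfig,
    objective: Objective,
    initial_positions: Optional[Sequence[np.ndarray]] = None,
) -> GEOResult:
    """Full GEO loop: prey selection, attack/cruise step, elitist memory update.

    ``initial_positions`` optionally pins the first eagles to given start
    points (e.g. a known default configuration), guaranteeing the search can
    never return something worse than the best of those starts.
    """
    rng = np.random.default_rng(config.seed)
    eagles = init_population(space, config, objective, rng=rng)
    if initial_positions is not None:
        if len(initial_positions) > len(eagles):
            raise ValueError("more initial positions than eagles")
        for i, pos in enumerate(initial_positions):
            pos = space.clip(np.asarray(pos, dtype=float))
            fit = _evaluate(objective, pos, strict=True)
            eagles[i] = Eagle(pos, fit, pos.copy(), fit)
    schedule = config.schedule
    history: List[float] = []
    for t in range(config.iterations):
        for i, eagle in enumerate(eagles):
            prey = select_prey(i, eagles, rng)
            attack = attack_vector(eagle, prey)
            cruise = cruise_vector(eagle, attack, space, rng, config.epsilon)
            new_pos = step_update(eagle, attack, cruise, t, schedule, rng,
                                  space, config.epsilon)
            fit = _evaluate(objective, new_pos, strict=False)
            eagle.position = new_pos
            eagle.fitness = fit
            if fit < eagle.memory_fitness:
                eagle.memory_fitness = fit
                eagle.memory_position = new_pos.copy()
        history.append(min(e.memory_fitness for e in eagles))
    best = min(eagles, key=lambda e: e.memory_fitness)
    return GEOResult(best.memory_position.copy(), best.memory_fitness, history)
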