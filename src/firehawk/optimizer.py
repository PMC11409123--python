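"""Fire-hawk population optimizer (FHO) and its adaptive-step variant (IFHO).

The algorithm ranks a population of box-bounded candidate solutions,
promotes the best-ranked ones to "hawks", partitions the remaining "prey"
into hawk territories by nearest-hawk distance, and renews positions with
three stochastic moves: hawks drift toward the global best and another
hawk; prey move relative to their territory's hawk and the local mean prey
position, or relative to an alternative hawk and the global mean prey
position.  The IFHO variant multiplies the hawk step by an adaptive factor
``f = alpha + (1 - alpha) * exp(-gamma * t)`` that decays from 1 toward
``alpha``, shifting the search from exploration to exploitation.

Replacement is an elitist merge of the parent population with every
clamped, evaluated proposal, truncated back to the population size, which
makes the best-so-far trajectory monotone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


class ConfigurationError(ValueError):
    """Invalid optimizer configuration or arguments."""


class DimensionError(ValueError):
    """Mismatched vector dimensions."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box of feasible positions."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or upper.shape != lower.shape:
            raise DimensionError("lower and upper must be 1-D arrays of equal length")
        if lower.size < 1:
            raise ConfigurationError("search space needs at least one dimension")
        if np.any(lower > upper):
            raise ConfigurationError("lower bound exceeds upper bound in some dimension")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def d(self) -> int:
        return self.lower.size


@dataclass
class Population:
    """Candidate positions with (possibly not yet assigned) objective values."""

    positions: np.ndarray
    values: np.ndarray | None = None
    evaluations_used: int = 0

    @property
    def size(self) -> int:
        return self.positions.shape[0]


@dataclass
class TerritoryState:
    """Hawk/prey split plus the nearest-hawk partition of the prey."""

    hawk_indices: np.ndarray  # sorted best-fitness-first
    prey_indices: np.ndarray
    assignment: dict[int, list[int]]  # hawk index -> prey indices in its territory


@dataclass(frozen=True)
class AdaptiveSchedule:
    """Parameters of the adaptive hawk-step factor.

    ``alpha`` either stays at ``alpha0`` (mode ``fixed_alpha``) or ramps
    linearly from ``alpha0`` to ``alpha_end`` over the run
    (mode ``linear_alpha``); ``gamma`` is the exponential decay rate.
    """

    alpha0: float = 0.1
    alpha_end: float = 0.9
    gamma: float = 0.01
    mode: Literal["fixed_alpha", "linear_alpha"] = "fixed_alpha"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha0 < 1.0:
            raise ConfigurationError("alpha0 must lie in (0, 1)")
        if not 0.0 < self.alpha_end <= 1.0:
            raise ConfigurationError("alpha_end must lie in (0, 1]")
        if self.alpha0 > self.alpha_end:
            raise ConfigurationError("alpha0 must not exceed alpha_end")
        if self.gamma < 0.0:
            raise ConfigurationError("gamma must be nonnegative")
        if self.mode not in ("fixed_alpha", "linear_alpha"):
            raise ConfigurationError(f"unknown schedule mode {self.mode!r}")


@dataclass
class OptimizerConfig:
    pop_size: int = 25
    max_iters: int = 1000
    max_evals: int | None = None
    variant: Literal["fho", "ifho"] = "ifho"
    direction: Literal["minimize", "maximize"] = "minimize"
    hawk_fraction_cap: float = 0.2
    schedule: AdaptiveSchedule = field(default_factory=AdaptiveSchedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be at least 2")
        if self.max_iters < 1:
            raise ConfigurationError("max_iters must be at least 1")
        if self.max_evals is not None and self.max_evals < self.pop_size:
            raise ConfigurationError("max_evals too small for even the initial population")
        if not 0.0 < self.hawk_fraction_cap <= 0.5:
            raise ConfigurationError("hawk_fraction_cap must lie in (0, 0.5]")
        if self.variant not in ("fho", "ifho"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.direction not in ("minimize", "maximize"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")


@dataclass
class OptimizerResult:
    best_position: np.ndarray
    best_value: float
    history: list[float]
    evaluations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "best_position": [float(v) for v in self.best_position],
            "best_value": float(self.best_value),
            "history": [float(v) for v in self.history],
            "evaluations": int(self.evaluations),
            "seed": int(self.seed),
        }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def initialize_population(space: SearchSpace, size: int, rng: np.random.Generator) -> Population:
    """Uniform random positions ``lower + rand * (upper - lower)``."""
    if size < 2:
        raise ConfigurationError("population size must be at least 2")
    rand = rng.random((size, space.d))
    positions = space.lower + rand * (space.upper - space.lower)
    return Population(positions=positions)


def draw_hawk_count(pop_size: int, cap: float, rng: np.random.Generator) -> int:
    """Half-normal draw of the hawk count, clamped to ``[1, floor(cap * N)]``.

    The draw is ``round(|Normal(0,1)| * N / 5)``; the result additionally
    never exceeds ``pop_size - 1`` so at least one prey always remains.
    """
    if pop_size < 2:
        raise ConfigurationError("pop_size must be at least 2")
    draw = int(round(abs(rng.standard_normal()) * pop_size / 5.0))
    hi = min(math.floor(cap * pop_size), pop_size - 1)
    hi = max(hi, 1)
    return int(min(max(draw, 1), hi))


def pairwise_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-length position vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def assign_territories(
    population: Population,
    hawk_indices: Sequence[int],
    prey_indices: Sequence[int],
) -> TerritoryState:
    """Partition prey among hawks by nearest Euclidean distance.

    ``hawk_indices`` must be sorted best-fitness-first: distance ties go to
    the better-ranked hawk.
    """
    hawk_indices = np.asarray(hawk_indices, dtype=int)
    prey_indices = np.asarray(prey_indices, dtype=int)
    if hawk_indices.size == 0:
        raise ConfigurationError("territory assignment requires at least one hawk")
    hawks = population.positions[hawk_indices]
    assignment: dict[int, list[int]] = {int(h): [] for h in hawk_indices}
    if prey_indices.size:
        prey = population.positions[prey_indices]
        # distances: (m prey) x (n hawks); argmin returns the first (= best
        # ranked) hawk on ties
        dists = np.linalg.norm(prey[:, None, :] - hawks[None, :, :], axis=2)
        owners = np.argmin(dists, axis=1)
        for p_idx, owner in zip(prey_indices, owners):
            assignment[int(hawk_indices[owner])].append(int(p_idx))
    return TerritoryState(hawk_indices=hawk_indices, prey_indices=prey_indices, assignment=assignment)


def hawk_step(
    hawk: np.ndarray,
    global_best: np.ndarray,
    near_hawk: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hawk move toward the global best and away from another hawk's region."""
    r1, r2 = rng.random(), rng.random()
    return hawk + (r1 * np.asarray(global_best) - r2 * np.asarray(near_hawk))


def adaptive_factor(schedule: AdaptiveSchedule, t: int, max_iters: int | None = None) -> float:
    """``f = alpha + (1 - alpha) * exp(-gamma * t)``; equals 1 at ``t = 0``."""
    if t < 0:
        raise ConfigurationError("iteration index must be nonnegative")
    if schedule.mode == "linear_alpha":
        if not max_iters:
            raise ConfigurationError("linear_alpha schedule requires max_iters")
        frac = min(t / max_iters, 1.0)
        alpha = schedule.alpha0 + (schedule.alpha_end - schedule.alpha0) * frac
    else:
        alpha = schedule.alpha0
    return alpha + (1.0 - alpha) * math.exp(-schedule.gamma * t)


def hawk_step_adaptive(
    hawk: np.ndarray,
    global_best: np.ndarray,
    near_hawk: np.ndarray,
    schedule: AdaptiveSchedule,
    t: int,
    rng: np.random.Generator,
    max_iters: int | None = None,
) -> np.ndarray:
    """Hawk move with the step vector scaled by the adaptive factor."""
    f = adaptive_factor(schedule, t, max_iters)
    r1, r2 = rng.random(), rng.random()
    return hawk + (r1 * np.asarray(global_best) - r2 * np.asarray(near_hawk)) * f


def local_safe_place(territory_prey_positions: np.ndarray) -> np.ndarray:
    """Componentwise mean of one territory's prey positions."""
    positions = np.atleast_2d(np.asarray(territory_prey_positions, dtype=float))
    if positions.shape[0] == 0:
        raise ConfigurationError("local safe place is undefined for an empty territory")
    return positions.mean(axis=0)


def global_safe_place(all_prey_positions: np.ndarray) -> np.ndarray:
    """Componentwise mean of every prey position in the search space."""
    positions = np.atleast_2d(np.asarray(all_prey_positions, dtype=float))
    if positions.shape[0] == 0:
        raise ConfigurationError("global safe place is undefined without prey")
    return positions.mean(axis=0)


def prey_step_within(
    prey: np.ndarray,
    hawk: np.ndarray,
    local_safe: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Prey move inside its own territory."""
    r3, r4 = rng.random(), rng.random()
    return prey + (r3 * np.asarray(hawk) - r4 * np.asarray(local_safe))


def prey_step_outside(
    prey: np.ndarray,
    alter_hawk: np.ndarray,
    global_safe: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Prey move toward another hawk's region / the global safe place."""
    r5, r6 = rng.random(), rng.random()
    return prey + (r5 * np.asarray(alter_hawk) - r6 * np.asarray(global_safe))


def clamp_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Clip every component into the search-space box."""
    position = np.asarray(position, dtype=float)
    if position.shape != space.lower.shape:
        raise DimensionError("position dimension does not match the search space")
    return np.clip(position, space.lower, space.upper)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def _evaluate(objective: Objective, position: np.ndarray, sign: float) -> float:
    value = sign * float(objective(position))
    if not math.isfinite(value):
        logger.warning("objective returned non-finite value; ranked as worst")
        return math.inf
    return value


def run_optimizer(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    iteration_callback: Callable[[dict], None] | None = None,
) -> OptimizerResult:
    """Run the configured FHO/IFHO variant and return the best solution found.

    ``iteration_callback``, if given, receives a state dict per iteration
    (after the elitist merge) for instrumentation and invariant checking.

    Internally the run always minimizes; ``direction='maximize'`` negates
    the objective and reports results on the caller's scale.
    """
    rng = np.random.default_rng(config.seed)
    sign = 1.0 if config.direction == "minimize" else -1.0

    pop = initialize_population(space, config.pop_size, rng)
    values = np.array([_evaluate(objective, p, sign) for p in pop.positions])
    evaluations = config.pop_size

    history: list[float] = []
    for t in range(config.max_iters):
        order = np.argsort(values, kind="stable")
        positions = pop.positions[order]
        values = values[order]
        global_best = positions[0].copy()

        n_hawks = draw_hawk_count(config.pop_size, config.hawk_fraction_cap, rng)
        hawk_idx = np.arange(n_hawks)
        prey_idx = np.arange(n_hawks, config.pop_size)
        territory = assign_territories(Population(positions, values), hawk_idx, prey_idx)

        new_positions: list[np.ndarray] = []
        new_values: list[float] = []

        def propose(candidate: np.ndarray) -> float:
            clamped = clamp_to_bounds(candidate, space)
            value = _evaluate(objective, clamped, sign)
            new_positions.append(clamped)
            new_values.append(value)
            return value

        # hawk moves
        for l in hawk_idx:
            if n_hawks > 1:
                others = np.delete(hawk_idx, l)
            else:
                others = np.delete(np.arange(config.pop_size), l)
            near = positions[rng.choice(others)]
            if config.variant == "ifho":
                cand = hawk_step_adaptive(
                    positions[l], global_best, near, config.schedule, t, rng, config.max_iters
                )
            else:
                cand = hawk_step(positions[l], global_best, near, rng)
            propose(cand)

        # prey moves: two candidates each, keep the better
        g_safe = global_safe_place(positions[prey_idx]) if prey_idx.size else None
        for l in hawk_idx:
            members = territory.assignment[int(l)]
            if not members:
                continue
            l_safe = local_safe_place(positions[members])
            for q in members:
                cand_a = clamp_to_bounds(prey_step_within(positions[q], positions[l], l_safe, rng), space)
                if n_hawks > 1:
                    alter = positions[rng.choice(np.delete(hawk_idx, l))]
                else:
                    alter = positions[l]
                cand_b = clamp_to_bounds(prey_step_outside(positions[q], alter, g_safe, rng), space)
                val_a = _evaluate(objective, cand_a, sign)
                val_b = _evaluate(objective, cand_b, sign)
                evaluations += 2
                if val_a <= val_b:
                    new_positions.append(cand_a)
                    new_values.append(val_a)
                else:
                    new_positions.append(cand_b)
                    new_values.append(val_b)
        evaluations += n_hawks

        # elitist merge: parents + proposals, truncated to pop_size
        merged_pos = np.vstack([positions, np.array(new_positions)])
        merged_val = np.concatenate([values, np.array(new_values)])
        keep = np.argsort(merged_val, kind="stable")[: config.pop_size]
        pop = Population(merged_pos[keep], merged_val[keep], evaluations)
        values = merged_val[keep]

        history.append(sign * float(values[0]))

        if iteration_callback is not None:
            iteration_callback(
                {
                    "iteration": t,
                    "positions": pop.positions.copy(),
                    "values": values.copy(),
                    "hawk_indices": hawk_idx.copy(),
                    "prey_indices": prey_idx.copy(),
                    "assignment": {k: list(v) for k, v in territory.assignment.items()},
                    "best_value": history[-1],
                    "evaluations": evaluations,
                }
            )

        if config.max_evals is not None and evaluations >= config.max_evals:
            break

    best_internal = float(values[0])
    return OptimizerResult(
        best_position=pop.positions[0].copy(),
        best_value=sign * best_internal,
        history=history,
        evaluations=evaluations,
        seed=config.seed,
    )
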