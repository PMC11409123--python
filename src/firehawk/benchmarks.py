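"""Classical continuous test functions with seeded random shifts.

Stand-ins for heavyweight benchmark suites that need external data files:
sphere, Rastrigin, Rosenbrock and Ackley, each optionally shifted so the
optimum sits at a random in-bounds point.  Every spec self-verifies its
optimum on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from firehawk.optimizer import SearchSpace


class UnknownBenchmarkError(KeyError):
    pass


def _sphere(z: np.ndarray) -> float:
    return float(np.sum(z * z))


def _rastrigin(z: np.ndarray) -> float:
    return float(10.0 * z.size + np.sum(z * z - 10.0 * np.cos(2.0 * np.pi * z)))


def _rosenbrock(z: np.ndarray) -> float:
    return float(np.sum(100.0 * (z[1:] - z[:-1] ** 2) ** 2 + (1.0 - z[:-1]) ** 2))


def _ackley(z: np.ndarray) -> float:
    d = z.size
    term1 = -20.0 * np.exp(-0.2 * np.sqrt(np.sum(z * z) / d))
    term2 = -np.exp(np.sum(np.cos(2.0 * np.pi * z)) / d)
    return float(term1 + term2 + 20.0 + np.e)


# name -> (base function, per-dimension bounds, unshifted optimum coordinate)
_CATALOG: dict[str, tuple[Callable[[np.ndarray], float], tuple[float, float], float]] = {
    "sphere": (_sphere, (-5.12, 5.12), 0.0),
    "rastrigin": (_rastrigin, (-5.12, 5.12), 0.0),
    "rosenbrock": (_rosenbrock, (-2.048, 2.048), 1.0),
    "ackley": (_ackley, (-32.768, 32.768), 0.0),
}

BENCHMARK_NAMES = tuple(_CATALOG)


@dataclass
class ObjectiveSpec:
    name: str
    dim: int
    bounds: SearchSpace
    known_optimum_position: np.ndarray
    known_optimum_value: float
    shift: np.ndarray
    evaluator: Callable[[np.ndarray], float] = field(repr=False, default=None)  # type: ignore[assignment]

    def __call__(self, x: np.ndarray) -> float:
        return self.evaluator(np.asarray(x, dtype=float))


def make_benchmark(
    name: str,
    dim: int,
    shift: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ObjectiveSpec:
    """Build a (possibly shifted) benchmark objective.

    ``shift`` translates the whole landscape; if ``rng`` is given and
    ``shift`` is None, a shift is drawn so the optimum lands uniformly in
    the central 60 % of the box.  The constructed spec asserts that its own
    evaluator reproduces the known optimum value.
    """
    if name not in _CATALOG:
        raise UnknownBenchmarkError(f"unknown benchmark {name!r}; choose from {BENCHMARK_NAMES}")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    base_fn, (lo, hi), base_opt_coord = _CATALOG[name]
    base_opt = np.full(dim, base_opt_coord)

    if shift is None and rng is not None:
        margin = 0.2 * (hi - lo)
        target = rng.uniform(lo + margin, hi - margin, size=dim)
        shift = target - base_opt
    elif shift is None:
        shift = np.zeros(dim)
    shift = np.asarray(shift, dtype=float)
    if shift.shape != (dim,):
        raise ValueError("shift must have length dim")

    optimum = base_opt + shift

    def evaluator(x: np.ndarray, _fn=base_fn, _s=shift) -> float:
        return _fn(np.asarray(x, dtype=float) - _s)

    space = SearchSpace(lower=np.full(dim, lo), upper=np.full(dim, hi))
    if np.any(optimum < space.lower) or np.any(optimum > space.upper):
        raise ValueError("shift places the optimum outside the bounds")
    value_at_opt = evaluator(optimum)
    if abs(value_at_opt) > 1e-9:
        raise AssertionError(f"{name}: optimum self-check failed ({value_at_opt})")

    return ObjectiveSpec(
        name=name,
        dim=dim,
        bounds=space,
        known_optimum_position=optimum,
        known_optimum_value=0.0,
        shift=shift,
        evaluator=evaluator,
    )


def benchmark_suite(dim: int, seed: int) -> list[ObjectiveSpec]:
    """The four named functions with seed-reproducible shifts."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    return [make_benchmark(name, dim, rng=rng) for name in BENCHMARK_NAMES]
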