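"""Snow ablation optimizer (SAO) for bound-constrained minimization.

A population metaheuristic patterned on seasonal snow melt.  Each iteration
the population is split into an *exploration* subset (snow sublimating —
broad stochastic moves around the incumbent best and the population
centroid) and an *exploitation* subset (snow melting — contraction toward
the best solution, modulated by a melt factor built from an exponential
temperature schedule and a degree-day factor DDF).  The exploration share
decays linearly from 1.0 to 0.5 so late iterations refine rather than roam.

Moves (position z, incumbent best g, centroid m, elite e drawn from the top
half, B a standard-normal vector, r ~ U(0,1)):

* exploration:  z <- e + B .* [r (g - z) + (1 - r)(m - z)]
* exploitation: z <- M(t) g + B .* [r (g - z) + (1 - r)(m - z)]

with melt factor M(t) = DDF(t) * exp(-t/T) and
DDF(t) = 0.35 + 0.25 (e^{t/T} - 1)/(e - 1), DDF in [0.35, 0.6].
Out-of-bounds coordinates are clipped; integer dimensions are kept
continuous during the search and rounded only at evaluation time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["Dimension", "SearchSpace", "SAOConfig", "OptimizationTrace", "run_sao",
           "random_search"]


@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    kind: Literal["continuous", "integer"] = "continuous"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"dimension {self.name!r}: lower must be < upper")


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    @classmethod
    def from_dict(
        cls, spec: dict[str, tuple[float, float] | tuple[float, float, str]]
    ) -> "SearchSpace":
        dims = []
        for name, bounds in spec.items():
            kind = bounds[2] if len(bounds) > 2 else "continuous"
            dims.append(Dimension(name, float(bounds[0]), float(bounds[1]), kind))
        return cls(tuple(dims))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dimensions])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dimensions])

    def round_integers(self, z: np.ndarray) -> np.ndarray:
        out = np.array(z, dtype=float)
        for i, d in enumerate(self.dimensions):
            if d.kind == "integer":
                out[i] = float(int(round(out[i])))
        return out

    def to_params(self, z: np.ndarray) -> dict[str, float | int]:
        zr = self.round_integers(z)
        return {
            d.name: int(zr[i]) if d.kind == "integer" else float(zr[i])
            for i, d in enumerate(self.dimensions)
        }


@dataclass(frozen=True)
class SAOConfig:
    population_size: int = 15
    iterations: int = 20
    ddf_range: tuple[float, float] = (0.35, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class OptimizationTrace:
    """Per-iteration best-so-far record (monotone non-increasing)."""

    best_value: list[float] = field(default_factory=list)
    best_position: list[np.ndarray] = field(default_factory=list)
    n_explore: list[int] = field(default_factory=list)
    n_exploit: list[int] = field(default_factory=list)
    n_evaluations: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.best_value)),
                "best_value": self.best_value,
                "n_explore": self.n_explore,
                "n_exploit": self.n_exploit,
            }
        )


def _evaluate(
    objective: Callable[[np.ndarray], float],
    z: np.ndarray,
    space: SearchSpace,
    trace: OptimizationTrace,
) -> float:
    trace.n_evaluations += 1
    val = objective(space.round_integers(z))
    if not np.isfinite(val):
        warnings.warn(
            f"objective returned non-finite value at {z}; candidate discarded",
            stacklevel=3,
        )
        return math.inf
    return float(val)


def run_sao(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    cfg: SAOConfig | None = None,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Minimize ``objective`` over the box; returns (best z, best value, trace)."""
    cfg = cfg or SAOConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = space.lower, space.upper
    d = len(lo)
    N, T = cfg.population_size, cfg.iterations
    ddf_lo, ddf_hi = cfg.ddf_range

    pop = lo + rng.random((N, d)) * (hi - lo)
    trace = OptimizationTrace()
    vals = np.array([_evaluate(objective, pop[i], space, trace) for i in range(N)])
    if not np.any(np.isfinite(vals)):
        raise RuntimeError("entire initial population evaluated to non-finite values")
    ib = int(np.argmin(vals))
    best, best_val = pop[ib].copy(), float(vals[ib])
    trace.best_value.append(best_val)
    trace.best_position.append(best.copy())
    trace.n_explore.append(N)
    trace.n_exploit.append(0)

    for t in range(1, T + 1):
        theta = math.exp(-t / T)
        ddf = ddf_lo + (ddf_hi - ddf_lo) * (math.exp(t / T) - 1.0) / (math.e - 1.0)
        melt = ddf * theta
        frac_explore = 1.0 - 0.5 * t / T  # linear 1.0 -> 0.5
        n_explore = int(round(frac_explore * N))
        explore_mask = np.zeros(N, dtype=bool)
        explore_mask[rng.choice(N, size=n_explore, replace=False)] = True

        centroid = pop.mean(axis=0)
        order = np.argsort(vals)
        elite_pool = order[: max(1, N // 2)]

        new_pop = np.empty_like(pop)
        for i in range(N):
            B = rng.standard_normal(d)
            r = rng.random()
            pull = r * (best - pop[i]) + (1.0 - r) * (centroid - pop[i])
            if explore_mask[i]:
                elite = pop[rng.choice(elite_pool)]
                z = elite + B * pull
            else:
                z = melt * best + B * pull
            new_pop[i] = np.clip(z, lo, hi)
        pop = new_pop
        vals = np.array([_evaluate(objective, pop[i], space, trace) for i in range(N)])
        ib = int(np.argmin(vals))
        if vals[ib] < best_val:
            best, best_val = pop[ib].copy(), float(vals[ib])
        trace.best_value.append(best_val)
        trace.best_position.append(best.copy())
        trace.n_explore.append(n_explore)
        trace.n_exploit.append(N - n_explore)

    return space.round_integers(best), best_val, trace


def random_search(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    n_evaluations: int,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Uniform random-search baseline with the same evaluation budget."""
    rng = np.random.default_rng(seed)
    lo, hi = space.lower, space.upper
    best, best_val = None, math.inf
    for _ in range(n_evaluations):
        z = lo + rng.random(len(lo)) * (hi - lo)
        val = float(objective(space.round_integers(z)))
        if val < best_val:
            best, best_val = z, val
    return space.round_integers(best), best_val
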