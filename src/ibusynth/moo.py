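"""Constrained NSGA-II over surrogate-predicted (RT, CR, Cost).

The optimizer searches a subset of the design variables (by default the
three coordinates that dominate the response: H+ concentration ``x3``,
catalyst precursor concentration ``x5`` and the dehydration rate constant
``x6``), holding the remaining inputs at the reference operating point.
Objectives are minimize RT, maximize CR, minimize Cost, evaluated through
the trained surrogates; industrial feasibility constraints are

* 0.5 h <= RT <= 72 h,
* 0.85 <= CR <= 0.98,
* Cost <= 800 units.

Constraint handling follows Deb's feasibility rule: feasible beats
infeasible, infeasible points compare by total violation, feasible points
compare by (rank, crowding distance).  Variation uses simulated binary
crossover and polynomial mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import INPUT_NAMES, DESIGN_BOUNDS, reference_inputs

__all__ = [
    "MooProblem",
    "ParetoFront",
    "Strategy",
    "fast_nondominated_sort",
    "crowding_distance",
    "run_nsga2",
    "select_strategies",
    "hypervolume_3d",
]

#: Feasibility window: (RT low h, RT high h, CR low, CR high, Cost high)
CONSTRAINTS = {"rt": (0.5, 72.0), "cr": (0.85, 0.98), "cost_max": 800.0}

DEFAULT_DECISION_VARIABLES = ("x3", "x5", "x6")


@dataclass(frozen=True)
class MooProblem:
    """Decision-variable subset, fixed complement, and constraint set."""

    decision_variables: tuple[str, ...] = DEFAULT_DECISION_VARIABLES
    fixed_values: dict[str, float] = field(default_factory=dict)
    rt_bounds: tuple[float, float] = CONSTRAINTS["rt"]
    cr_bounds: tuple[float, float] = CONSTRAINTS["cr"]
    cost_max: float = CONSTRAINTS["cost_max"]

    def __post_init__(self) -> None:
        unknown = set(self.decision_variables) - set(INPUT_NAMES)
        if unknown:
            raise ValueError(f"unknown decision variables: {sorted(unknown)}")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([DESIGN_BOUNDS[v][0] for v in self.decision_variables])
        hi = np.array([DESIGN_BOUNDS[v][1] for v in self.decision_variables])
        return lo, hi

    def full_inputs(self, Z: np.ndarray) -> pd.DataFrame:
        """Embed decision vectors into complete 14-column design rows."""
        ref = reference_inputs().to_array()
        fixed = {**dict(zip(INPUT_NAMES, ref)), **self.fixed_values}
        Z = np.atleast_2d(Z)
        out = pd.DataFrame(
            np.tile([fixed[n] for n in INPUT_NAMES], (len(Z), 1)), columns=INPUT_NAMES
        )
        for j, v in enumerate(self.decision_variables):
            out[v] = Z[:, j]
        return out


def fast_nondominated_sort(points: np.ndarray) -> list[np.ndarray]:
    """Partition objective vectors (all minimized) into nondomination fronts.

    Returns index arrays: front 1 is the nondominated set; each later front
    is nondominated once earlier fronts are removed.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or len(P) == 0:
        raise ValueError("points must be a non-empty 2-D array")
    n = len(P)
    # domination matrix: D[i, j] true iff i dominates j
    le = (P[:, None, :] <= P[None, :, :]).all(axis=2)
    lt = (P[:, None, :] < P[None, :, :]).any(axis=2)
    D = le & lt
    n_dominators = D.sum(axis=0)
    fronts = []
    remaining = n_dominators.copy()
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        current = np.nonzero((remaining == 0) & ~assigned)[0]
        if len(current) == 0:  # pragma: no cover — cannot happen for finite inputs
            raise RuntimeError("nondominated sort failed to progress")
        fronts.append(current)
        assigned[current] = True
        remaining = remaining - D[current].sum(axis=0)
    return fronts


def crowding_distance(front: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance for one front of objective vectors.

    Boundary points per objective get infinity; interior points accumulate
    the normalized gap between their neighbours, summed over objectives.
    Fronts of size <= 2 are all-infinite.
    """
    F = np.asarray(front, dtype=float)
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span == 0:
            continue
        gaps = (fj[2:] - fj[:-2]) / span
        interior = order[1:-1]
        finite = np.isfinite(dist[interior])
        dist[interior[finite]] += gaps[finite]
    return dist


@dataclass(frozen=True)
class ParetoFront:
    """Feasible nondominated archive with decisions and objective values."""

    decisions: pd.DataFrame          # decision-variable columns
    rt: np.ndarray
    cr: np.ndarray
    cost: np.ndarray
    problem: MooProblem

    def __len__(self) -> int:
        return len(self.decisions)

    @property
    def objectives(self) -> np.ndarray:
        """Minimization view: (RT, -CR, Cost)."""
        return np.column_stack([self.rt, -self.cr, self.cost])

    def to_frame(self) -> pd.DataFrame:
        out = self.decisions.copy()
        out["rt_h"] = self.rt
        out["cr"] = self.cr
        out["cost"] = self.cost
        return out


def _predict_objectives(models: dict, X: pd.DataFrame) -> np.ndarray:
    rt = np.asarray(models["y1"].predict(X)).ravel()
    cr = np.asarray(models["y2"].predict(X)).ravel()
    cost = np.asarray(models["y3"].predict(X)).ravel()
    return np.column_stack([rt, cr, cost])


def _violation(problem: MooProblem, ycr: np.ndarray) -> np.ndarray:
    """Total normalized constraint violation per row of (RT, CR, Cost)."""
    rt, cr, cost = ycr[:, 0], ycr[:, 1], ycr[:, 2]
    rt_lo, rt_hi = problem.rt_bounds
    cr_lo, cr_hi = problem.cr_bounds
    v = (
        np.maximum(rt_lo - rt, 0) / rt_lo
        + np.maximum(rt - rt_hi, 0) / rt_hi
        + np.maximum(cr_lo - cr, 0) / cr_lo
        + np.maximum(cr - cr_hi, 0) / cr_hi
        + np.maximum(cost - problem.cost_max, 0) / problem.cost_max
    )
    return v


def _sbx_crossover(p1, p2, lo, hi, rng, eta=15.0, rate=0.9):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > rate:
        return c1, c2
    for j in range(len(p1)):
        if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14:
            continue
        x1, x2 = sorted((p1[j], p2[j]))
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[j] = 0.5 * ((x1 + x2) - beta * (x2 - x1))
        c2[j] = 0.5 * ((x1 + x2) + beta * (x2 - x1))
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(z, lo, hi, rng, eta=20.0, rate=None):
    rate = 1.0 / len(z) if rate is None else rate
    out = z.copy()
    for j in range(len(z)):
        if rng.random() > rate:
            continue
        u = rng.random()
        delta = (2 * u) ** (1 / (eta + 1)) - 1 if u < 0.5 else 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        out[j] = np.clip(z[j] + delta * (hi[j] - lo[j]), lo[j], hi[j])
    return out


def _rank_and_crowd(objs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = fast_nondominated_sort(objs)
    rank = np.empty(len(objs), dtype=int)
    crowd = np.empty(len(objs))
    for r, idx in enumerate(fronts):
        rank[idx] = r
        crowd[idx] = crowding_distance(objs[idx])
    return rank, crowd


def _tournament(rng, feas, viol, rank, crowd):
    i, j = rng.integers(0, len(feas), size=2)
    if feas[i] != feas[j]:
        return i if feas[i] else j
    if not feas[i]:
        return i if viol[i] < viol[j] else j
    if rank[i] != rank[j]:
        return i if rank[i] < rank[j] else j
    return i if crowd[i] >= crowd[j] else j


def run_nsga2(
    problem: MooProblem,
    models: dict,
    population: int = 200,
    generations: int = 500,
    seed: int = 0,
    return_history: bool = False,
):
    """Constrained NSGA-II; returns the feasible nondominated archive.

    ``models`` maps output names ("y1" RT, "y2" CR, "y3" Cost) to fitted
    surrogates.  Raises if no feasible individual exists at termination.
    """
    rng = np.random.default_rng(seed)
    lo, hi = problem.bounds()
    d = len(lo)
    Z = lo + rng.random((population, d)) * (hi - lo)

    def eval_pop(Zp):
        y = _predict_objectives(models, problem.full_inputs(Zp))
        objs = np.column_stack([y[:, 0], -y[:, 1], y[:, 2]])
        viol = _violation(problem, y)
        return y, objs, viol

    y, objs, viol = eval_pop(Z)
    history = []
    for gen in range(generations):
        feas = viol == 0
        rank, crowd = _rank_and_crowd(objs)
        children = np.empty_like(Z)
        for i in range(0, population, 2):
            a = _tournament(rng, feas, viol, rank, crowd)
            b = _tournament(rng, feas, viol, rank, crowd)
            c1, c2 = _sbx_crossover(Z[a], Z[b], lo, hi, rng)
            children[i] = _poly_mutation(c1, lo, hi, rng)
            if i + 1 < population:
                children[i + 1] = _poly_mutation(c2, lo, hi, rng)
        yc, objs_c, viol_c = eval_pop(children)
        Z_all = np.vstack([Z, children])
        y_all = np.vstack([y, yc])
        objs_all = np.vstack([objs, objs_c])
        viol_all = np.concatenate([viol, viol_c])
        # environmental selection under Deb's rule: feasible first by
        # (rank, crowding), then infeasible by ascending violation
        feas_all = viol_all == 0
        chosen: list[int] = []
        fi = np.nonzero(feas_all)[0]
        if len(fi):
            fronts = fast_nondominated_sort(objs_all[fi])
            for idx in fronts:
                cand = fi[idx]
                if len(chosen) + len(cand) <= population:
                    chosen.extend(cand.tolist())
                else:
                    cd = crowding_distance(objs_all[cand])
                    keep = np.argsort(-cd, kind="stable")[: population - len(chosen)]
                    chosen.extend(cand[keep].tolist())
                    break
        if len(chosen) < population:
            infe = np.nonzero(~feas_all)[0]
            order = infe[np.argsort(viol_all[infe], kind="stable")]
            chosen.extend(order[: population - len(chosen)].tolist())
        sel = np.asarray(chosen[:population])
        Z, y, objs, viol = Z_all[sel], y_all[sel], objs_all[sel], viol_all[sel]
        if return_history:
            front = _feasible_front(problem, Z, y, viol)
            history.append(front)

    front = _feasible_front(problem, Z, y, viol)
    if len(front) == 0:
        raise RuntimeError(
            "no feasible solution found; consider relaxing the RT/CR/Cost constraints"
        )
    return (front, history) if return_history else front


def _feasible_front(problem, Z, y, viol) -> ParetoFront:
    feas = np.nonzero(viol == 0)[0]
    if len(feas) == 0:
        return ParetoFront(
            decisions=pd.DataFrame(
                np.empty((0, len(problem.decision_variables))),
                columns=list(problem.decision_variables),
            ),
            rt=np.empty(0),
            cr=np.empty(0),
            cost=np.empty(0),
            problem=problem,
        )
    objs = np.column_stack([y[feas, 0], -y[feas, 1], y[feas, 2]])
    nd = feas[fast_nondominated_sort(objs)[0]]
    # de-duplicate identical decision vectors
    _, uniq = np.unique(np.round(Z[nd], 12), axis=0, return_index=True)
    nd = nd[np.sort(uniq)]
    return ParetoFront(
        decisions=pd.DataFrame(Z[nd], columns=list(problem.decision_variables)),
        rt=y[nd, 0],
        cr=y[nd, 1],
        cost=y[nd, 2],
        problem=problem,
    )


@dataclass(frozen=True)
class Strategy:
    """A named operating point drawn from the Pareto front."""

    name: str
    decision: dict[str, float]
    rt: float
    cr: float
    cost: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "decision": self.decision,
            "rt_h": self.rt,
            "cr": self.cr,
            "cost": self.cost,
        }


def select_strategies(front: ParetoFront) -> tuple[dict[str, Strategy], pd.DataFrame]:
    """Extract the four industrial strategies plus their similarity matrix.

    max_output = argmin RT, max_yield = argmax CR, min_cost = argmin Cost,
    balanced = argmin Euclidean distance to the ideal point after min-max
    normalization of (RT, 1-CR, Cost) over the front.  Similarity between
    strategies is the cosine similarity of bound-normalized decision vectors.
    """
    if len(front) == 0:
        raise ValueError("empty Pareto front")
    G = np.column_stack([front.rt, 1.0 - front.cr, front.cost])
    span = G.max(axis=0) - G.min(axis=0)
    span[span == 0] = 1.0
    norm = (G - G.min(axis=0)) / span
    dist = np.sqrt((norm**2).sum(axis=1))
    picks = {
        "balanced": int(np.argmin(dist)),
        "max_output": int(np.argmin(front.rt)),
        "max_yield": int(np.argmax(front.cr)),
        "min_cost": int(np.argmin(front.cost)),
    }
    strategies = {}
    for name, i in picks.items():
        strategies[name] = Strategy(
            name=name,
            decision={c: float(front.decisions.iloc[i][c]) for c in front.decisions},
            rt=float(front.rt[i]),
            cr=float(front.cr[i]),
            cost=float(front.cost[i]),
        )
    lo, hi = front.problem.bounds()
    names = list(picks)
    vecs = []
    for name in names:
        z = np.array([strategies[name].decision[c] for c in front.decisions.columns])
        vecs.append((z - lo) / (hi - lo))
    sim = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            a, b = vecs[i], vecs[j]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            sim[i, j] = 1.0 if na == 0 and nb == 0 else float(a @ b / (na * nb or 1.0))
    return strategies, pd.DataFrame(sim, index=names, columns=names)


def hypervolume_3d(points: np.ndarray, reference: Sequence[float]) -> float:
    """Exact hypervolume of a 3-D minimization front w.r.t. a reference point.

    Slices along the first objective and accumulates 2-D dominated areas;
    points not strictly below the reference in every coordinate contribute
    nothing.
    """
    P = np.asarray(points, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("expected an (n, 3) array")
    P = P[(P < ref).all(axis=1)]
    if len(P) == 0:
        return 0.0
    nd = fast_nondominated_sort(P)[0]
    P = P[nd]
    order = np.argsort(P[:, 0], kind="stable")
    P = P[order]
    hv = 0.0
    zs = np.append(P[:, 0], ref[0])
    active: list[np.ndarray] = []
    for i in range(len(P)):
        active.append(P[i, 1:])
        depth = zs[i + 1] - zs[i]
        if depth <= 0:
            continue
        hv += _area_2d(np.array(active), ref[1:]) * depth
    return hv


def _area_2d(pts: np.ndarray, ref: np.ndarray) -> float:
    """Dominated area of 2-D minimization points w.r.t. ref."""
    pts = pts[(pts < ref).all(axis=1)]
    if len(pts) == 0:
        return 0.0
    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    area = 0.0
    best_y = ref[1]
    x_prev = None
    for x, ycoord in pts:
        if ycoord >= best_y:
            continue
        area += (ref[0] - x) * (best_y - ycoord)
        best_y = ycoord
        x_prev = x
    return area
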