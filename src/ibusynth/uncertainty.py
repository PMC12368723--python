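"""Monte Carlo perturbation analysis and strategy robustness scoring.

Process inputs are jittered with multiplicative-scale Gaussian noise,
``x'_j = x_j + delta_j`` with ``delta_j ~ N(0, (w_j * sigma * |x_j|)^2)``
(sigma is a *standard deviation* factor, not a variance), propagated
through the trained surrogates, and summarized as percentile 95%
confidence intervals.  Relative uncertainty is the CI width over the
unperturbed baseline prediction, in percent.

Strategy robustness at a fixed sigma combines, per metric, the relative
mean shift and the coefficient of variation; lower combined scores mean
more robust operating points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .kinetics import INPUT_NAMES, DESIGN_BOUNDS

__all__ = [
    "PerturbationConfig",
    "perturb",
    "mc_uncertainty",
    "sensitivity_surface",
    "assess_robustness",
]

METRICS = ("y1", "y2", "y3")


@dataclass(frozen=True)
class PerturbationConfig:
    """Perturbation magnitudes and replication plan."""

    sigmas: tuple[float, ...] = (0.1, 0.2, 0.3, 0.5)
    replicates: int = 500
    weights: np.ndarray | None = None  # per-feature multipliers on sigma
    clip_to_bounds: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigmas):
            raise ValueError("sigma levels must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def weight_vector(self, d: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(d)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (d,):
            raise ValueError(f"weights must have shape ({d},)")
        return w


def perturb(
    x: np.ndarray | Sequence[float],
    sigma: float,
    weights: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    clip_to_bounds: bool = True,
    size: int | None = None,
) -> np.ndarray:
    """Draw perturbed copies of a design vector.

    Returns shape ``(size, d)`` when ``size`` is given, else ``(d,)``.
    Clipping keeps perturbed points inside the design bounds, where the
    surrogates were trained; disable it to verify the raw noise law.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    d = x.shape[-1]
    w = np.ones(d) if weights is None else np.asarray(weights, dtype=float)
    n = size or 1
    delta = rng.standard_normal((n, d)) * (w * sigma * np.abs(x))
    out = x[None, :] + delta
    if clip_to_bounds:
        lo = np.array([DESIGN_BOUNDS[k][0] for k in INPUT_NAMES])
        hi = np.array([DESIGN_BOUNDS[k][1] for k in INPUT_NAMES])
        out = np.clip(out, lo, hi)
    return out if size else out[0]


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    return float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5))


def mc_uncertainty(
    models: Mapping[str, object],
    samples: pd.DataFrame,
    cfg: PerturbationConfig | None = None,
) -> pd.DataFrame:
    """Monte Carlo uncertainty report per sample, sigma level and metric.

    Columns: sample, sigma, metric, baseline, mean, ci_low, ci_high,
    rel_uncertainty_pct (NaN when the baseline is ~0; the absolute CI
    width is always kept).
    """
    cfg = cfg or PerturbationConfig()
    X = samples[list(INPUT_NAMES)].to_numpy(dtype=float)
    w = cfg.weight_vector(X.shape[1])
    rng = np.random.default_rng(cfg.seed)
    baselines = {m: np.asarray(models[m].predict(samples)).ravel() for m in METRICS}
    records = []
    for i in range(len(X)):
        for sigma in cfg.sigmas:
            Xp = perturb(
                X[i], sigma, w, rng, clip_to_bounds=cfg.clip_to_bounds,
                size=cfg.replicates,
            )
            Xp_df = pd.DataFrame(Xp, columns=list(INPUT_NAMES))
            for m in METRICS:
                base = float(baselines[m][i])
                preds = np.asarray(models[m].predict(Xp_df)).ravel()
                lo, hi = _percentile_ci(preds)
                width = hi - lo
                rel = 100.0 * width / abs(base) if abs(base) >= 1e-9 else math.nan
                records.append(
                    {
                        "sample": i,
                        "sigma": sigma,
                        "metric": m,
                        "baseline": base,
                        "mean": float(preds.mean()),
                        "ci_low": lo,
                        "ci_high": hi,
                        "ci_width": width,
                        "rel_uncertainty_pct": rel,
                    }
                )
    return pd.DataFrame(records)


def sensitivity_surface(
    models: Mapping[str, object],
    grid: tuple[np.ndarray, np.ndarray],
    sigma: float,
    base_point: pd.DataFrame | None = None,
    features: tuple[str, str] = ("x5", "x3"),
    cfg: PerturbationConfig | None = None,
    dense: int = 60,
    metric: str = "y1",
) -> pd.DataFrame:
    """RT relative-uncertainty field over a 2-D slice of the design space.

    Computes the Monte Carlo relative uncertainty of ``metric`` at each
    node of the (f1, f2) grid (all other inputs at the base point), then
    interpolates onto a ``dense x dense`` grid with a thin-plate-spline
    RBF.  The interpolant reproduces the node values exactly.
    """
    from .kinetics import reference_inputs

    cfg = cfg or PerturbationConfig()
    g1, g2 = (np.atleast_1d(np.asarray(g, dtype=float)) for g in grid)
    if g1.size * g2.size < 2:
        raise ValueError("grid must contain at least 2 nodes")
    if base_point is None:
        base_point = pd.DataFrame(
            [reference_inputs().to_array()], columns=list(INPUT_NAMES)
        )
    f1, f2 = features
    nodes, vals = [], []
    rng = np.random.default_rng(cfg.seed)
    for v1 in g1:
        for v2 in g2:
            pt = base_point.copy()
            pt[f1] = v1
            pt[f2] = v2
            x = pt[list(INPUT_NAMES)].to_numpy(dtype=float)[0]
            base = float(np.asarray(models[metric].predict(pt)).ravel()[0])
            Xp = perturb(
                x, sigma, cfg.weight_vector(len(x)), rng,
                clip_to_bounds=cfg.clip_to_bounds, size=cfg.replicates,
            )
            preds = np.asarray(
                models[metric].predict(pd.DataFrame(Xp, columns=list(INPUT_NAMES)))
            ).ravel()
            lo, hi = _percentile_ci(preds)
            rel = 100.0 * (hi - lo) / abs(base) if abs(base) >= 1e-9 else 0.0
            nodes.append([v1, v2])
            vals.append(rel)
    nodes = np.asarray(nodes)
    vals = np.asarray(vals)
    interp = RBFInterpolator(nodes, vals, kernel="thin_plate_spline")
    d1 = np.linspace(g1.min(), g1.max(), dense)
    d2 = np.linspace(g2.min(), g2.max(), dense)
    D1, D2 = np.meshgrid(d1, d2, indexing="ij")
    dense_pts = np.column_stack([D1.ravel(), D2.ravel()])
    Z = interp(dense_pts)
    out = pd.DataFrame({f1: dense_pts[:, 0], f2: dense_pts[:, 1], "rel_uncertainty_pct": Z})
    out.attrs["nodes"] = nodes
    out.attrs["node_values"] = vals
    return out


def assess_robustness(
    strategies: Mapping[str, object],
    models: Mapping[str, object],
    sigma: float = 0.2,
    replicates: int = 30,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Robustness scores for named operating strategies.

    For each strategy the full design vector is perturbed ``replicates``
    times at the given sigma; per metric we report the relative mean
    shift % ``100*|mean - baseline|/|baseline|`` and the coefficient of
    variation % ``100*sd/|mean|``.  The combined score is the mean over
    the three metrics of ``(shift% + CV%)/2``; *lower is more robust*.
    Rows are ordered most-robust first.
    """
    from .kinetics import reference_inputs

    rows = []
    for name, strat in strategies.items():
        # common random numbers: every strategy sees the same noise stream,
        # so identical strategies score identically and comparisons are paired
        rng = np.random.default_rng(seed)
        decision = strat.decision if hasattr(strat, "decision") else dict(strat)
        ref = dict(zip(INPUT_NAMES, reference_inputs().to_array()))
        full = {**ref, **decision}
        x = np.array([full[k] for k in INPUT_NAMES])
        Xp = perturb(x, sigma, weights, rng, clip_to_bounds=True, size=replicates)
        Xp_df = pd.DataFrame(Xp, columns=list(INPUT_NAMES))
        base_df = pd.DataFrame([x], columns=list(INPUT_NAMES))
        rec = {"strategy": name}
        combined = []
        for m in METRICS:
            base = float(np.asarray(models[m].predict(base_df)).ravel()[0])
            preds = np.asarray(models[m].predict(Xp_df)).ravel()
            mean = float(preds.mean())
            sd = float(preds.std(ddof=1)) if len(preds) > 1 else 0.0
            shift = 100.0 * abs(mean - base) / abs(base) if abs(base) >= 1e-9 else 0.0
            cv = 100.0 * sd / abs(mean) if abs(mean) >= 1e-9 else 0.0
            rec[f"{m}_shift_pct"] = shift
            rec[f"{m}_cv_pct"] = cv
            combined.append((shift + cv) / 2.0)
        rec["combined_score"] = float(np.mean(combined))
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values("combined_score", kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
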