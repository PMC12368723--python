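"""Labeled-dataset generation over the design space.

Samples the 14-dimensional design space (5 initial concentrations, 9 rate
constants — each range spanning two decades), labels every point with the
kinetic simulator (RT, CR) and the cost model (Cost), and prepares
train/validation/test splits.  Log-uniform sampling is the default: with
100x ranges it is the natural uninformative design, giving each decade
equal weight.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import qmc

from .economics import compute_cost
from .kinetics import (
    INPUT_NAMES,
    DESIGN_BOUNDS,
    IntegrationError,
    KineticsConfig,
    SimulationInput,
    compile_mechanism,
    extract_metrics,
    simulate,
)
from .mechanism import MechanismSpec, canonical_mechanism

__all__ = [
    "SamplingConfig",
    "LabeledDataset",
    "sample_inputs",
    "build_dataset",
    "split_dataset",
    "summarize_correlations",
]

OUTPUT_NAMES = ("y1", "y2", "y3")  # RT (h), CR (fraction), Cost (units)


@dataclass(frozen=True)
class SamplingConfig:
    """Design-space sampling plan."""

    n_samples: int = 8000
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DESIGN_BOUNDS)
    )
    law: Literal["log-uniform", "uniform", "lhs-log"] = "log-uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name} must satisfy 0 < min < max")
        if self.law not in ("log-uniform", "uniform", "lhs-log"):
            raise ValueError(f"unknown sampling law {self.law!r}")


def sample_inputs(cfg: SamplingConfig) -> pd.DataFrame:
    """Draw an ``n x 14`` design table; deterministic under a fixed seed."""
    names = list(cfg.bounds)
    lo = np.array([cfg.bounds[n][0] for n in names])
    hi = np.array([cfg.bounds[n][1] for n in names])
    d = len(names)
    if cfg.law == "lhs-log":
        sampler = qmc.LatinHypercube(d=d, seed=cfg.seed)
        u = sampler.random(cfg.n_samples)
    else:
        u = np.random.default_rng(cfg.seed).random((cfg.n_samples, d))
    if cfg.law == "uniform":
        x = lo + u * (hi - lo)
    else:
        x = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    # guard against float round-out at the edges
    x = np.clip(x, lo, hi)
    return pd.DataFrame(x, columns=names)


def _config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).values.tobytes()
    ).hexdigest()[:16]


@dataclass(frozen=True)
class LabeledDataset:
    """Row-aligned inputs (x1..x14), outputs (y1 RT h, y2 CR, y3 Cost),
    censoring flags, and provenance hashes."""

    inputs: pd.DataFrame
    outputs: pd.DataFrame
    censored: pd.Series
    provenance: dict

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.outputs) or len(self.inputs) != len(self.censored):
            raise ValueError("inputs, outputs and censoring flags must be row-aligned")
        if self.outputs.isna().any().any() or self.inputs.isna().any().any():
            raise ValueError("dataset contains missing values")
        y2 = self.outputs["y2"]
        if ((y2 < 0) | (y2 > 1)).any():
            raise ValueError("conversion y2 outside [0, 1]")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.inputs, self.outputs, self.censored.rename("censored")], axis=1
        )

    def content_hash(self) -> str:
        return _table_hash(self.frame)

    def save(self, path: str | Path, format: Literal["csv", "parquet"] = "csv") -> None:
        """Persist the table plus a JSON provenance sidecar."""
        path = Path(path)
        if format == "parquet":
            self.frame.to_parquet(path, index=False)
        else:
            # %.17g round-trips float64 exactly, keeping the content hash stable
            self.frame.to_csv(path, index=False, float_format="%.17g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({**self.provenance, "content_hash": self.content_hash()}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path, check_hash: bool = True) -> "LabeledDataset":
        path = Path(path)
        frame = (
            pd.read_parquet(path)
            if path.suffix == ".parquet"
            else pd.read_csv(path, float_precision="round_trip")
        )
        sidecar = path.with_suffix(path.suffix + ".json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        ds = cls(
            inputs=frame[list(INPUT_NAMES)].copy(),
            outputs=frame[list(OUTPUT_NAMES)].copy(),
            censored=frame["censored"].astype(bool).copy(),
            provenance=prov,
        )
        if check_hash and "content_hash" in prov and ds.content_hash() != prov["content_hash"]:
            raise ValueError(
                f"{path}: content hash mismatch — dataset file corrupted or edited"
            )
        return ds


def _label_row(row: np.ndarray, compiled, kcfg: KineticsConfig):
    # rows come from the (bounds-respecting) sampler or from deliberate
    # perturbation studies, so skip the in-bounds check here
    inp = SimulationInput.from_array(row, perturbed=True)
    try:
        traj = simulate(inp, compiled, kcfg)
    except IntegrationError as exc:
        return None, str(exc)
    rt, cr, cens = extract_metrics(traj, inp, kcfg)
    cost = compute_cost(inp, rt, cr).total
    return (rt, cr, cost, cens), None


def build_dataset(
    inputs: pd.DataFrame,
    mech: MechanismSpec | None = None,
    kcfg: KineticsConfig | None = None,
    n_jobs: int = 1,
    max_failure_fraction: float = 0.01,
    provenance: dict | None = None,
) -> LabeledDataset:
    """Label a design table with one simulation + cost evaluation per row.

    Rows are independent, so evaluation order (and ``n_jobs``) cannot change
    any result.  Integrator failures are flagged per row; more than
    ``max_failure_fraction`` of them aborts with diagnostics.
    """
    mech = mech or canonical_mechanism()
    kcfg = kcfg or KineticsConfig()
    compiled = compile_mechanism(mech)
    X = inputs[list(INPUT_NAMES)].to_numpy()
    results = Parallel(n_jobs=n_jobs)(
        delayed(_label_row)(X[i], compiled, kcfg) for i in range(len(X))
    )
    failures = [(i, err) for i, (res, err) in enumerate(results) if res is None]
    if len(failures) > max_failure_fraction * max(len(X), 1):
        examples = "; ".join(f"row {i}: {err}" for i, err in failures[:5])
        raise RuntimeError(
            f"{len(failures)}/{len(X)} simulations failed "
            f"(> {max_failure_fraction:.0%} allowed): {examples}"
        )
    ok = [i for i, (res, _) in enumerate(results) if res is not None]
    labels = np.array([results[i][0][:3] for i in ok])
    censored = pd.Series([bool(results[i][0][3]) for i in ok], name="censored")
    prov = {
        "mechanism_hash": _config_hash(mech.to_dict()),
        "kinetics_hash": _config_hash(kcfg),
        "n_requested": len(X),
        "n_failed": len(failures),
        "failed_rows": [i for i, _ in failures],
        **(provenance or {}),
    }
    return LabeledDataset(
        inputs=inputs.iloc[ok].reset_index(drop=True),
        outputs=pd.DataFrame(labels, columns=list(OUTPUT_NAMES)),
        censored=censored,
        provenance=prov,
    )


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive, seed-deterministic train/validation/test split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(ds)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"empty split for n={n} with fractions {fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    parts = (perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :])
    out = []
    for name, idx in zip(("train", "validation", "test"), parts):
        idx = np.sort(idx)
        out.append(
            LabeledDataset(
                inputs=ds.inputs.iloc[idx].reset_index(drop=True),
                outputs=ds.outputs.iloc[idx].reset_index(drop=True),
                censored=ds.censored.iloc[idx].reset_index(drop=True),
                provenance={**ds.provenance, "split": name, "split_seed": seed},
            )
        )
    return tuple(out)


def summarize_correlations(ds: LabeledDataset) -> pd.DataFrame:
    """Pearson correlation matrix of the 14 inputs and 3 outputs (17 x 17).

    Zero-variance columns yield NaN entries (flagged by pandas semantics)
    rather than failing.
    """
    if len(ds) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    return ds.frame[list(INPUT_NAMES) + list(OUTPUT_NAMES)].corr(method="pearson")
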