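"""End-to-end pipeline orchestration.

Stages (in dependency order): ``simulate`` (reference trajectory export),
``generate-data``, ``tune``, ``train``, ``explain``, ``optimize``,
``assess``.  Each stage reads its upstream artifacts from the output
directory, writes its own artifacts plus a manifest entry (config hash,
output hashes, derived seed), and is skipped on rerun when nothing
changed.  All stage seeds derive deterministically from the single global
seed, so the whole pipeline is reproducible from the config file alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import economics
from .dataset import (
    LabeledDataset,
    SamplingConfig,
    build_dataset,
    sample_inputs,
    split_dataset,
    summarize_correlations,
)
from .kinetics import (
    INPUT_NAMES,
    DESIGN_BOUNDS,
    KineticsConfig,
    reference_inputs,
    simulate,
    extract_metrics,
    trajectory_to_frame,
)
from .mechanism import canonical_mechanism, load_mechanism
from .moo import MooProblem, run_nsga2, select_strategies
from .sao import SAOConfig
from .sensitivity import attribute, interaction_surface, rank_importance
from .surrogate import (
    DEFAULT_HYPERPARAMETERS,
    GradientBoostedSurrogate,
    evaluate,
    tune_hyperparameters,
)
from .uncertainty import PerturbationConfig, assess_robustness, mc_uncertainty

log = logging.getLogger("ibusynth.pipeline")

STAGES = ("simulate", "generate-data", "tune", "train", "explain", "optimize", "assess")

#: Recognized config sections and keys, with defaults. Unknown sections or
#: keys are rejected before any stage runs.
CONFIG_SCHEMA: dict[str, dict[str, Any]] = {
    "seed": 0,
    "outdir": "artifacts",
    "mechanism": None,  # path; None -> shipped canonical network
    "kinetics": {"t_end": 259_200.0, "rtol": 1e-7, "atol": 1e-12, "n_grid": 400,
                 "theta": 0.99},
    "sampling": {"n_samples": 8000, "law": "log-uniform"},
    "split": {"fractions": [0.70, 0.15, 0.15]},
    "tuning": {"population": 15, "iterations": 20, "targets": ["y1", "y3"]},
    "training": {"backend": "lightgbm", "cr_hyperparameters": dict(DEFAULT_HYPERPARAMETERS)},
    "moo": {"population": 200, "generations": 100,
            "decision_variables": ["x3", "x5", "x6"]},
    "uncertainty": {"sigmas": [0.1, 0.2, 0.3, 0.5], "replicates": 500,
                    "robustness_replicates": 30, "robustness_sigma": 0.2,
                    "n_samples": 20},
}


class ConfigError(ValueError):
    pass


class MissingArtifactError(FileNotFoundError):
    pass


def validate_config(raw: dict) -> dict:
    """Merge a raw config onto the schema defaults, rejecting unknown keys."""
    cfg: dict[str, Any] = {}
    for key, default in CONFIG_SCHEMA.items():
        if isinstance(default, dict):
            section = dict(default)
            extra = raw.get(key) or {}
            unknown = set(extra) - set(default)
            if unknown:
                raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            section.update(extra)
            cfg[key] = section
        else:
            cfg[key] = raw.get(key, default)
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    return cfg


def load_config(path: str | Path | None) -> dict:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data: dict = json.loads(self.path.read_text()) if self.path.exists() else {}

    def is_current(self, stage: str, config_hash: str, outdir: Path) -> bool:
        entry = self.data.get(stage)
        if not entry or entry["config_hash"] != config_hash:
            return False
        for rel, h in entry["outputs"].items():
            f = outdir / rel
            if not f.exists() or _file_hash(f) != h:
                return False
        return True

    def record(self, stage: str, config_hash: str, seed: int, outputs: list[Path],
               outdir: Path) -> None:
        self.data[stage] = {
            "config_hash": config_hash,
            "seed": seed,
            "outputs": {str(p.relative_to(outdir)): _file_hash(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _mechanism(cfg):
    return load_mechanism(cfg["mechanism"]) if cfg["mechanism"] else canonical_mechanism()


def _kcfg(cfg) -> KineticsConfig:
    return KineticsConfig(**cfg["kinetics"])


def _require(outdir: Path, rel: str, needed_by: str, produced_by: str) -> Path:
    p = outdir / rel
    if not p.exists():
        raise MissingArtifactError(
            f"stage {needed_by!r} needs {rel} — run stage {produced_by!r} first"
        )
    return p


def _load_splits(cfg, outdir: Path, needed_by: str):
    path = _require(outdir, "dataset.csv", needed_by, "generate-data")
    ds = LabeledDataset.load(path)
    return split_dataset(
        ds, tuple(cfg["split"]["fractions"]), seed=stage_seed(cfg["seed"], "split")
    )


def _load_models(cfg, outdir: Path, needed_by: str) -> dict:
    models = {}
    for tgt in ("y1", "y2", "y3"):
        path = _require(outdir, f"model_{tgt}.txt", needed_by, "train")
        import lightgbm as lgb

        booster = lgb.Booster(model_file=str(path))
        meta = json.loads(path.with_suffix(".txt.json").read_text())
        model = GradientBoostedSurrogate(
            target=tgt, **meta["hyperparameters"], random_state=meta["random_state"]
        )
        # re-wrap the persisted booster in a fitted estimator shell
        model.model_ = _BoosterShell(booster)
        model.n_features_in_ = booster.num_feature()
        model.feature_names_in_ = np.asarray(meta["feature_names"], dtype=object)
        model._feature_names = meta["feature_names"]
        model.data_hash_ = meta["data_hash"]
        models[tgt] = model
    return models


class _BoosterShell:
    """Duck-typed stand-in for LGBMRegressor around a loaded Booster."""

    def __init__(self, booster):
        self.booster_ = booster

    def predict(self, X):
        return self.booster_.predict(X)


def run_stage(name: str, config: dict, force: bool = False) -> list[Path]:
    """Run one pipeline stage; returns the artifact paths it produced."""
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}; stages are {STAGES}")
    cfg = config
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir)
    relevant = {k: cfg[k] for k in cfg}
    chash = _config_hash({**relevant, "stage": name})
    if not force and manifest.is_current(name, chash, outdir):
        log.info("stage %s up to date; skipping", name)
        return [outdir / rel for rel in manifest.data[name]["outputs"]]
    seed = stage_seed(cfg["seed"], name)
    t0 = time.time()
    outputs = _STAGE_FUNCS[name](cfg, outdir, seed)
    log.info("stage %s finished in %.1f s", name, time.time() - t0)
    manifest.record(name, chash, seed, outputs, outdir)
    return outputs


def run_all(config: dict, force: bool = False) -> dict[str, list[Path]]:
    return {name: run_stage(name, config, force=force) for name in STAGES}


# ---------------------------------------------------------------- stages

def _stage_simulate(cfg, outdir: Path, seed: int) -> list[Path]:
    mech = _mechanism(cfg)
    kcfg = _kcfg(cfg)
    inp = reference_inputs()
    traj = simulate(inp, mech, kcfg)
    rt, cr, censored = extract_metrics(traj, inp, kcfg)
    cost = economics.compute_cost(inp, rt, cr)
    out = outdir / "reference_trajectory.csv"
    trajectory_to_frame(traj).to_csv(out, index=False)
    summary = outdir / "reference_metrics.json"
    summary.write_text(json.dumps(
        {"rt_h": rt, "cr": cr, "censored": censored, **cost.to_dict()}, indent=2
    ))
    return [out, summary]


def _stage_generate(cfg, outdir: Path, seed: int) -> list[Path]:
    scfg = SamplingConfig(
        n_samples=int(cfg["sampling"]["n_samples"]),
        law=cfg["sampling"]["law"],
        seed=seed,
    )
    inputs = sample_inputs(scfg)
    ds = build_dataset(
        inputs, mech=_mechanism(cfg), kcfg=_kcfg(cfg),
        provenance={"sampling_seed": seed, "law": scfg.law},
    )
    ds_path = outdir / "dataset.csv"
    ds.save(ds_path)
    corr = summarize_correlations(ds)
    corr_path = outdir / "correlations.csv"
    corr.to_csv(corr_path, float_format="%.17g")
    return [ds_path, ds_path.with_suffix(".csv.json"), corr_path]


def _stage_tune(cfg, outdir: Path, seed: int) -> list[Path]:
    train, val, _ = _load_splits(cfg, outdir, "tune")
    sao_cfg = SAOConfig(
        population_size=int(cfg["tuning"]["population"]),
        iterations=int(cfg["tuning"]["iterations"]),
        seed=seed,
    )
    outputs = []
    best: dict[str, dict] = {}
    for tgt in cfg["tuning"]["targets"]:
        params, _, trace = tune_hyperparameters(train, val, target=tgt, cfg=sao_cfg)
        best[tgt] = params
        trace_path = outdir / f"sao_trace_{tgt}.csv"
        trace.to_frame().to_csv(trace_path, index=False, float_format="%.17g")
        outputs.append(trace_path)
    hp_path = outdir / "hyperparameters.json"
    hp_path.write_text(json.dumps(best, indent=2))
    return [hp_path, *outputs]


def _stage_train(cfg, outdir: Path, seed: int) -> list[Path]:
    train, val, test = _load_splits(cfg, outdir, "train")
    hp_path = _require(outdir, "hyperparameters.json", "train", "tune")
    tuned = json.loads(hp_path.read_text())
    outputs = []
    reports = {}
    for tgt in ("y1", "y2", "y3"):
        params = tuned.get(tgt, dict(cfg["training"]["cr_hyperparameters"]))
        model = GradientBoostedSurrogate(
            target=tgt, backend=cfg["training"]["backend"], random_state=seed, **params
        )
        model.fit(train.inputs, train.outputs[tgt])
        path = outdir / f"model_{tgt}.txt"
        model.save(path)
        outputs += [path, path.with_suffix(".txt.json")]
        reports[tgt] = {
            split: evaluate(model, part.inputs, part.outputs[tgt], split).to_dict()
            for split, part in (("validation", val), ("test", test))
        }
    rep_path = outdir / "evaluation.json"
    rep_path.write_text(json.dumps(reports, indent=2))
    return [*outputs, rep_path]


def _stage_explain(cfg, outdir: Path, seed: int) -> list[Path]:
    _, _, test = _load_splits(cfg, outdir, "explain")
    models = _load_models(cfg, outdir, "explain")
    rng = np.random.default_rng(seed)
    n_bg = min(256, len(test.inputs))
    bg = test.inputs.iloc[np.sort(rng.choice(len(test.inputs), n_bg, replace=False))]
    outputs = []
    ranking = {}
    for tgt, model in models.items():
        attr = attribute(model, test.inputs)
        imp = rank_importance(attr)
        ranking[tgt] = imp.to_dict(orient="records")
        attr_path = outdir / f"attributions_{tgt}.csv"
        attr.values.to_csv(attr_path, index=False, float_format="%.8g")
        outputs.append(attr_path)
    surf = interaction_surface(
        models["y2"], ("x5", "x3"),
        (np.geomspace(*DESIGN_BOUNDS["x5"], 15), np.geomspace(*DESIGN_BOUNDS["x3"], 15)),
        bg,
    )
    surf_path = outdir / "interaction_x5_x3_y2.csv"
    surf.to_csv(surf_path, index=False, float_format="%.8g")
    rank_path = outdir / "importance.json"
    rank_path.write_text(json.dumps(ranking, indent=2))
    return [rank_path, surf_path, *outputs]


def _stage_optimize(cfg, outdir: Path, seed: int) -> list[Path]:
    models = _load_models(cfg, outdir, "optimize")
    problem = MooProblem(
        decision_variables=tuple(cfg["moo"]["decision_variables"])
    )
    front = run_nsga2(
        problem, models,
        population=int(cfg["moo"]["population"]),
        generations=int(cfg["moo"]["generations"]),
        seed=seed,
    )
    strategies, similarity = select_strategies(front)
    front_path = outdir / "pareto_front.csv"
    front.to_frame().to_csv(front_path, index=False, float_format="%.17g")
    strat_path = outdir / "strategies.json"
    strat_path.write_text(json.dumps({k: s.to_dict() for k, s in strategies.items()}, indent=2))
    sim_path = outdir / "strategy_similarity.csv"
    similarity.to_csv(sim_path, float_format="%.8g")
    return [front_path, strat_path, sim_path]


def _stage_assess(cfg, outdir: Path, seed: int) -> list[Path]:
    models = _load_models(cfg, outdir, "assess")
    _, _, test = _load_splits(cfg, outdir, "assess")
    strat_path = _require(outdir, "strategies.json", "assess", "optimize")
    raw = json.loads(strat_path.read_text())
    from .moo import Strategy

    strategies = {
        k: Strategy(name=k, decision=v["decision"], rt=v["rt_h"], cr=v["cr"], cost=v["cost"])
        for k, v in raw.items()
    }
    ucfg = cfg["uncertainty"]
    n = min(int(ucfg["n_samples"]), len(test.inputs))
    samples = test.inputs.iloc[:n]
    pcfg = PerturbationConfig(
        sigmas=tuple(ucfg["sigmas"]), replicates=int(ucfg["replicates"]), seed=seed
    )
    report = mc_uncertainty(models, samples, pcfg)
    unc_path = outdir / "uncertainty.csv"
    report.to_csv(unc_path, index=False, float_format="%.8g")
    rob = assess_robustness(
        strategies, models,
        sigma=float(ucfg["robustness_sigma"]),
        replicates=int(ucfg["robustness_replicates"]),
        seed=seed,
    )
    rob_path = outdir / "robustness.csv"
    rob.to_csv(rob_path, index=False, float_format="%.8g")
    return [unc_path, rob_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "generate-data": _stage_generate,
    "tune": _stage_tune,
    "train": _stage_train,
    "explain": _stage_explain,
    "optimize": _stage_optimize,
    "assess": _stage_assess,
}
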