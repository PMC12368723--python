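# ibusynth

Kinetics-driven surrogate multiobjective optimization of batch ibuprofen
synthesis.

`ibusynth` is for process-modeling and cheminformatics researchers who want
to study how machine-learning pipelines behave on a realistic multistep
catalytic synthesis, end to end and fully reproducibly. It couples:

1. **a mass-action kinetic simulator** of the Pd-catalysed carbonylation
   route — nine reactions over twelve tracked species, from acid-catalysed
   dehydration of 1-(4-isobutylphenyl)ethanol through catalyst activation,
   oxidative addition, CO insertion and hydrolysis to ibuprofen, plus a
   reversible esterification side reaction — integrated with a stiff
   adaptive solver;
2. **a seven-component production-cost model**
   `Cost = C_catalyst + C_reagent + C_fixed + C_energy + C_maint + C_purif + C_labor`
   with `C_catalyst = 8000·x₅^1.2`, `C_energy = 15·√y₁`,
   `C_purif = 500·(1−y₂)^1.5`, …;
3. **gradient-boosted surrogates** (one per output: reaction time RT,
   conversion rate CR, cost), hyperparameter-tuned by a **snow ablation
   optimizer** against validation MSE;
4. **TreeSHAP sensitivity analysis** (exact tree-path Shapley values) and
   two-variable partial-dependence surfaces;
5. **constrained NSGA-II** over the surrogate-predicted objectives
   (min RT, max CR, min Cost subject to RT ∈ [0.5, 72] h, CR ∈ [0.85, 0.98],
   Cost ≤ 800), from whose Pareto front four industrial strategies are
   extracted (balanced / max output / max yield / min cost);
6. **Monte Carlo uncertainty propagation** (x′ = x + N(0, (σ|x|)²)) with
   percentile confidence intervals and strategy robustness scoring.

The simulator defines the ground truth: there is no external data
anywhere in the pipeline, so every number below regenerates from a seed.

## Worked example

```python
from ibusynth import (reference_inputs, canonical_mechanism, KineticsConfig,
                      simulate, extract_metrics, compute_cost)

inp = reference_inputs()                    # the nominal operating point
traj = simulate(inp, canonical_mechanism(), KineticsConfig())
rt, cr, censored = extract_metrics(traj, inp, KineticsConfig())
cost = compute_cost(inp, rt, cr)
print(f"RT = {rt:.2f} h, CR = {cr:.3f}, Cost = {cost.total:.2f}")
```

prints

```
RT = 2.92 h, CR = 0.990, Cost = 487.24
```

i.e. at the reference conditions the reaction plateaus after ~3 hours,
essentially all of the substrate ends up as ibuprofen (CR is capped at
0.99 by the plateau definition), and the batch costs ~487 units — mostly
the fixed (200), labor (165), reagent (44) and catalyst (40) components.

The full pipeline runs from a YAML config:

```bash
ibusynth run-all --config config.yaml     # simulate → … → assess
```

Each stage writes its artifacts (CSV/JSON) plus a manifest of config and
output hashes into the configured output directory; rerunning with an
unchanged config is a no-op, and a corrupted intermediate file is caught
by checksum before any downstream stage uses it.

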