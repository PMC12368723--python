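# Methods

## Scope

`ibusynth` models the Pd-catalysed carbonylation route to ibuprofen as a
batch, isothermal, perfectly mixed reactor, and wraps that simulator in a
surrogate-assisted optimization pipeline: simulator-labeled data →
gradient-boosted meta-models tuned by a snow-ablation metaheuristic →
TreeSHAP sensitivity analysis → constrained NSGA-II → Monte Carlo
robustness assessment. Everything downstream of the simulator treats it as
ground truth; no experimental data enters the pipeline.

## Kinetic model

The reaction network ships as a YAML mechanism file
(`ibusynth/data/ibuprofen_carbonylation.yaml`) interpreted by a generic
mass-action engine, so the network can be revised without code changes.
Twelve species are integrated (substrate alcohol `roh`, alkene `ren`,
benzylic chloride `rcl`, product `ibu`, ibuprofen–substrate `ester`, `H+`,
`Cl-`, `H2O`, and the four palladium pools `pd1`–`pd4`); dissolved CO is
held at a constant 1.0 mol/m³, absorbing gas–liquid saturation into the
carbonylation rate constant. Kinetic orders are dictated by the units of
the nine rate constants: second-order rates for constants in m³/(s·mol),
third-order for m⁶/(s·mol²).

The nine steps: acid-catalysed dehydration (k1), hydrohalogenation (k2)
and its base-mediated reverse (k3), hydrolytic activation of the L2PdCl2
precursor releasing 2H⁺ + 2Cl⁻ (k4, second order in water, consuming one),
oxidative addition of `rcl` (k5), CO insertion (k6), hydrolysis releasing
ibuprofen and regenerating the active catalyst (k7), and the reversible
acid-catalysed esterification of ibuprofen with the substrate alcohol
(k8f/k8r). This network is a reconstruction from the step names and the
rate-constant units — the original source's rate expressions are not
public — and three structural invariants pin it down in tests: the four Pd
pools sum to the initial precursor charge; the aryl backbone is conserved
across `roh + ren + rcl + pd3 + pd4 + ibu + 2·ester`; and chlorine is
conserved across `Cl⁻ + rcl + 2·pd1 + pd3 + pd4`.

**Integration.** `scipy.integrate.solve_ivp` with LSODA, an analytical
Jacobian, `rtol = 1e-7`, `atol = 1e-12` (mol/m³). The right-hand side is
kept in raw polynomial form with no clipping: with integer orders it is
smooth everywhere and self-correcting for the ~1e-20-scale negative
excursions adaptive solvers produce, which keeps step-size control stable
(clipping inside the RHS was measured to cause occasional 100-fold
slowdowns). Outputs below 1e-12 mol/m³ are clipped to zero on the output
grid only. Conservation holds to ~1e-9 relative at these tolerances,
two orders inside the 1e-6 test tolerance; halving the tolerances moves
RT by <0.5% and CR by <0.1% (tested on 100 random designs).

**Output grid and metrics.** Concentrations are reported on a 400-point
grid: t=0 plus a geometric ladder from 0.1 s to the 72 h horizon, which
resolves reaction times spanning five decades equally well in relative
terms. Reaction time RT is the first time the product reaches θ = 0.99 of
its terminal value — the plateau criterion; the crossing is refined by
linear interpolation between grid points, making RT smooth in the inputs
to ~1e-7 relative. Conversion CR is the product concentration at RT over
the initial substrate concentration, hence never above θ. Runs whose
terminal product stays below 1e-9 mol/m³ are censored: RT is set to the
horizon and flagged. RT is reported in hours everywhere, including inside
the cost model.

## Cost model

Seven additive components (abstract currency units): catalyst
`8000·x5^1.2`, reagents `40·x1 + 20·x2 + 30·x3 + 10·x4`, fixed 200,
energy `15·√y1`, maintenance `10·(1 + 0.05·y1^1.5)`, purification
`500·(1−y2)^1.5`, labor `150 + 5·y1` (y1 in hours, y2 a fraction). The
model is a relative comparator, not an absolute estimate; its floor is
360 units. Surrogate-predicted conversions are clamped to [0, 1] before
costing, with a warning, because the purification term has a fractional
exponent.

## Data generation

The 14 design variables (5 initial concentrations, 9 rate constants) each
span two decades (0.1× to 10× the reference operating point), so
independent log-uniform sampling is the default design: it weights every
decade equally and is the natural uninformative choice; Latin-hypercube
in log space is available. The default desk-scale dataset is n = 8,000
rows (~4 minutes of simulation), split 70/15/15 into
train/validation/test with a seeded permutation. Each row stores the
simulator metrics and the cost-model label; the cost label is exactly
reproducible from the row's inputs and metrics, which the tests use as a
self-oracle. Datasets persist as CSV (written at %.17g and re-read in
round-trip mode so content hashes are stable) with a JSON sidecar holding
seeds and mechanism/config hashes.

Under this independent design the input–input correlations vanish
(|r| < 0.05 at n = 10⁴, tested), and the catalyst–conversion correlation
is *positive* (~+0.17): within the 72 h horizon more catalyst means more
complete reaction. A correlated or manifold-style design — which the
upstream study evidently used, given its reported strong input–input
correlations — would change both facts; neither is asserted as a property
of real chemistry, only of this sampling design.

## Surrogates

One LightGBM regressor per output (RT, CR, Cost), exposed as a
scikit-learn estimator (`GradientBoostedSurrogate`) with the four tuned
hyperparameters under their CatBoost-style names: `depth` (mapped to both
`max_depth` and a `2^depth` leaf budget, capped at 64 leaves),
`learning_rate`, `l2_leaf_reg` (`reg_lambda`), `iterations`
(`n_estimators`). Feature histograms use 127 bins — on these smooth
14-feature responses the accuracy difference from 255 bins is below
measurement noise while training is ~30% faster. Training is
single-threaded and deterministic given the seed. The backend is recorded in the model's JSON sidecar; an XGBoost
backend exists for cross-checking but TreeSHAP attributions require the
LightGBM one.

Evaluation reports MSE/RMSE/MAE/R²/MAPE (MAPE excludes exact-zero labels,
with the exclusion count), plus an observed-vs-predicted OLS line with
slope/intercept/t/p and the mean 95% prediction-interval half-width
(statsmodels). Learning curves use seeded k-fold assignment with
subsampled training folds.

**Tuning.** `SnowAblationSearch` minimizes validation-split MSE of a
surrogate trained at each candidate configuration over depth ∈ [4, 10],
learning rate ∈ [0.01, 0.3], L2 ∈ [0, 10], iterations ∈ [100, 1000]
(integers handled by rounding at evaluation only). The default budget is
population 15 × 20 iterations ≤ 315 trainings per output. RT and Cost are
tuned; the CR surrogate trains at the default configuration (depth 6,
learning rate 0.1, L2 3, 500 iterations) to keep the end-to-end runtime
at desk scale.

## Snow ablation optimizer

A population metaheuristic for bound-constrained minimization. Iteration
t of T uses temperature Θ(t) = e^(−t/T), degree-day factor
DDF(t) = 0.35 + 0.25·(e^(t/T) − 1)/(e − 1) and melt factor
M(t) = DDF·Θ. The population splits each iteration into an exploration
subset (fraction decaying linearly 1.0 → 0.5, membership resampled) moving
around an elite (drawn from the top half) plus a Gaussian-modulated pull
toward the incumbent best and the centroid, and an exploitation subset
contracting toward M(t)·best with the same pull term. Out-of-bounds
coordinates are clipped; non-finite objective values discard the candidate
with a warning. These update equations are this package's concrete
realization of the qualitative description available for the method
(stochastic perturbation around best and centroid; temperature-modulated
attraction); they are validated behaviourally: ≥95/100 seeded runs reach
1e-3 on the 2-D sphere with a 15×100 budget, best-so-far is monotone, and
SAO beats an equal-budget random search on shifted quadratic bowls in
≥80/100 paired runs.

## Sensitivity analysis

Per-sample attributions come from LightGBM's native `pred_contrib`
(the exact tree-path TreeSHAP algorithm), so baseline + Σ attributions
equals the prediction to numerical precision — asserted on every call and
cross-checked against an exhaustive-coalition Shapley oracle on a depth-2
tree over the full 2³ binary grid. Global importance is mean |attribution|
with ties broken by feature order. Pairwise effects are two-variable
partial-dependence grids over a fixed 256-row background (the alternative
— SHAP interaction values — answers a subtly different question; partial
dependence is the reproducible, model-agnostic choice).

## Multiobjective optimization

A hand-implemented NSGA-II (vectorized fast nondominated sort, standard
crowding distance with per-objective min–max normalization, binary
tournaments, SBX crossover η = 15 at rate 0.9, polynomial mutation η = 20
at rate 1/d) over surrogate-predicted objectives (min RT, max CR, min
Cost), with Deb's feasibility rule for the constraints RT ∈ [0.5, 72] h,
CR ∈ [0.85, 0.98], Cost ≤ 800. Decision variables default to the three
most influential coordinates — H⁺ concentration (x3), catalyst precursor
concentration (x5) and the dehydration constant (x6) — with the remaining
inputs fixed at the reference point (10× the lower bounds); an all-14 mode
exists. The returned archive is the feasible nondominated set of the final
population, de-duplicated, and every run is audited against a brute-force
pairwise domination check in the tests.

Four named strategies are drawn from the front: `max_output` (argmin RT),
`max_yield` (argmax CR), `min_cost` (argmin Cost), and `balanced` — the
member closest (Euclidean) to the ideal point after min–max normalization
of (RT, 1−CR, Cost) over the front. Strategy similarity is cosine
similarity of bound-normalized decision vectors. Both selection rules are
this package's own concrete definitions of informally-described choices.

## Uncertainty and robustness

Inputs are perturbed by x′ = x + δ, δ ~ N(0, (w·σ·|x|)²) — σ is a standard
deviation factor (the conventional reading), w an optional per-feature
weight (default 1). Perturbed points are clipped to the design bounds by
default because the surrogates are untrained outside them; an unclipped
mode exists and is what the noise-law test uses. Uncertainty per sample,
σ level, and metric is the percentile (2.5, 97.5) interval over 500
surrogate evaluations; relative uncertainty is interval width over
|baseline| (reported missing when the baseline is below 1e-9). 2-D
sensitivity fields interpolate node values with a thin-plate-spline RBF.

Strategy robustness at σ = 0.2 (30 replicates, common random numbers
across strategies so the comparison is paired) combines, per metric, the
relative mean shift and the coefficient of variation; the combined score
is the mean over the three metrics of (shift% + CV%)/2, lower = more
robust. This formula is the package's own documented choice.

## Reproducibility

Every stage seed derives from one global seed by hashing
(`stage_seed(seed, stage)` < 2³¹); datasets, traces, fronts and reports
are all seed-deterministic, and each pipeline stage records config and
output hashes in a manifest, making reruns no-ops and corruption
detectable before downstream stages run.

## Problem sizes

Default desk-scale sizes: 8,000-row dataset; tuning budget 15×20 per
tuned output; NSGA-II population 200 over 100 generations in the pipeline
configuration (500 generations remains the module default for standalone
runs); 500 Monte Carlo replicates per sample and σ; 30 replicates for
strategy robustness. The unit-test fixtures use a 600-row dataset with the
same generator.

## Known limitations

- The mechanism is a units-consistent reconstruction, not the source
  model's exact rate laws; structural conclusions that depend on which
  species dominates a rate law can differ from the source. At the default
  8,000-row scale the catalyst concentration (x5) tops the conversion-rate
  SHAP ranking with H⁺ (x3) second; at much smaller sample sizes the two
  can swap, so attribution rankings should be read at adequate n.
- Isothermal batch only: no energy balance, no transport, no catalyst
  deactivation.
- Under independent log-uniform sampling the surrogate task is genuinely
  14-dimensional; held-out R² at n = 8,000 is materially below what is
  achievable on low-dimensional correlated designs at n ≈ 40,000. The
  learning-curve module quantifies this directly.
- The CR surrogate's error concentrates near the completion cliff (runs
  that barely finish within the horizon); percentile CIs through it are
  conservative there.
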