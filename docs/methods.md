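# Methods

## Model and notation

All modeling happens on a *split* genome-scale metabolic model: every
reaction with a negative lower bound is decomposed into a forward
(`<id>_fwd`) and a reverse (`<id>_rev`) reaction with negated stoichiometry,
so every flux is non-negative and uptake through an exchange reaction is the
positive flux of its `_rev` member. `S` (m metabolites × n reactions) is the
split stoichiometric matrix, `Pin` (n_in × n) selects the measured input
exchanges (one +1 per row, on the directional reaction carrying the
measurement), and `Pref` (k × n) maps fluxes to the measured reference
panel; a reference measured as a net flux of a split pair gets a
`+1/−1` row. Fluxes are in mmol·gDW⁻¹·h⁻¹, growth in h⁻¹.

The MINN is `V = refine(nn(X))`:

* `nn`: one hidden layer, `V0 = ReLU(X·Wh + bh)·Wout + bout`, inverted
  dropout on the hidden activation during training only.
* `refine`: `k_iter` explicit gradient-descent steps `V ← V − lr·∇L_FBA(V)`
  with

  `L_FBA(V) = (1/m)‖S·V‖² + (1/n_in)‖ReLU(Pin·V − Vin)‖² + (1/n)‖ReLU(−V)‖²`

  where `Vin` is the sample's measured input-exchange vector. `1/n` uses
  n = number of split reactions (the network's output width). The loop is
  unrolled, so training gradients flow through it: each step's Jacobian is
  `I − lr·H(V_t)` with `H` the generalized Hessian of `L_FBA`
  (sub-gradients 0/1 at the ReLU kinks, strict inequality on the active
  side). Reverse-mode products with `H`, and the partials with respect to
  `Vin` (needed when the bounds are themselves predicted), are written out
  by hand in numpy and checked against central finite differences in the
  test suite (worst relative error ~1e-7 over random instances).

Training loss: `total = c_data·L1 + c_mech·(L2+L3+L4)` with `L1` the
normalized error, per sample the ratio of residual norm to reference norm,
averaged over the batch (an element-wise relative-error variant and a plain
MSE mode exist behind `ne_mode`). Batch aggregation is the mean throughout.

## Balancing strategies

Every strategy reduces, for the purpose of backpropagation, to scalar
coefficients `(c_data, c_mech)` applied to the data and mechanistic terms:

* `unbalanced` (1, 1); `mse_base` the same with MSE as the data term;
* `c_balanced` (c, 1), `c` a tuned hyperparameter (log-uniform 1…1e4 in the
  default search space);
* `divided` (1, 0): data-only ablation; the mechanistic layer still runs in
  the forward pass;
* `bound`: the mechanistic loss passes through unchanged below a threshold;
  the excess above it is multiplied by `factor` (continuous at the
  threshold; defaults threshold 0.01, factor 10 — chosen once as a mild
  penalty roughly one order of magnitude);
* `ema`: each loss is divided by the exponential moving average of its own
  history (decay 0.9, averages excluded from gradients; first step
  normalizes each loss by itself so the total starts at exactly 2);
* `scheduler`: data weight 0.1 for epochs 0–29, linear ramp over epochs
  30–69 to `final_data_weight` (tuned in [0.8, 1.0]), constant thereafter;
  weights always sum to 1. `scheduler_bound` composes both.

## Optimization and numerical choices

* Adam (β₁ 0.9, β₂ 0.999) with decoupled L2 weight decay on the weight
  matrices only; biases are not decayed. Full-batch gradient descent by
  default — the target regime is tens of samples.
* Fan-in-scaled Gaussian initialization (std √(2/d_in) into the ReLU layer,
  √(1/d_h) for the linear output); output bias starts at 0.
* `lr_mech` defaults to `0.9 / L` with
  `L = 2λ_max(SᵀS)/m + 2λ_max(PinᵀPin)/n_in + 2/n`, a Lipschitz bound on
  `∇L_FBA`; descent at that step provably never increases the loss, which
  the tests verify numerically. `k_iter` defaults to 10.
* Feature scaling: per-feature standardization fitted strictly on the
  training samples of the active split; targets are never scaled (NE is
  scale-free). Zero-variance features get unit scale.
* Non-finite losses abort training naming the offending component.
* All randomness (initialization, dropout, batch order, data simulation,
  hyperparameter draws) flows from explicit integer seeds through
  `numpy.random.Generator`; identical seeds give bit-identical results.

## Constraint-based services

FBA, parsimonious FBA (two-stage: fix the optimum, minimize total flux) and
flux variability analysis are delegated to cobra/optlang with the GLPK
backend. FVA-based reduction keeps reactions whose variability span exceeds
1e-9 *or* whose range is pinned away from zero (a forced maintenance flux
must survive), plus the objective and any protected exchanges; by default
the objective is not constrained to its optimum during the FVA
(`fraction_of_optimum = 0`), so alternative pathways silent at maximal
growth are retained. FBA-sampling reduction runs seeded parsimonious-FBA
simulations under random single-gene knockouts and uniformly drawn glucose
capacity, discards infeasible or growthless simulations (a lethal knockout
marks every reaction inactive and carries no information), and removes
reactions that never exceed 1e-9 in any informative simulation.

Measured reference fluxes generally lie outside the solution space of a
full GEM (they were estimated with a much smaller isotope-tracing model).
`fit_to_solution_space` projects them back: minimize
`‖W(Pref·v − v_measured)‖²` subject to `S·v = 0` and bounds, solved with
scipy's trust-region constrained optimizer (analytic gradient and constant
Hessian; weights optional and uniform by default), started from the
parsimonious solution. Solutions are accepted only if
`‖S·v‖_∞ ≤ 1e-6`.

## Reservoir

The reservoir dataset draws each of the five exchange fluxes (glucose and
oxygen uptake; CO₂, ethanol and acetate secretion) uniformly within the
ranges observed in the training data, pins them (opposite direction zeroed)
and records the solver's solution; infeasible draws are redrawn and counted,
and a feasibility rate below 1% aborts. Records use parsimonious FBA: plain
FBA optima are degenerate, and letting the solver pick an arbitrary vertex
per record teaches the surrogate an inconsistent choice among alternative
pathways — pFBA attains the same objective value and is the canonical
representative. The pretrained block is a MINN with the five exchange values
as its only input, trained with the full composite loss against the recorded
flux distributions; a held-out fraction (20%) reports its generalization NE
before the weights are frozen.

The front network (same architecture, its own hyperparameters) maps omics
features to the five exchange values; its output bias is initialized at the
block's training-mean exchange vector, because the block is only a faithful
surrogate near the region it was trained on and a zero start stalls
optimization far off that manifold. Gradients flow through the frozen
block's network and refinement loop — including the refinement's dependence
on its `Vin` input — but update only the front weights.

At prediction time the exchange constraints handed to parsimonious FBA are
extracted from the block's *refined output* (`Pin·V_out`), which is already
near-feasible, rather than from the raw front prediction. Measured glucose
uptake is fixed exactly (a chemostat feed must be consumed); measured oxygen
can instead be imposed as a capacity `(0, value)`, the standard treatment of
a measured maximal uptake. Predicted exchanges are imposed as tight bound
pairs (±1e-6). Infeasible combinations are relaxed in logged steps of ±1%,
±5%, ±10% of `max(|value|, 1.0)` — the absolute floor of one flux unit
matters when a near-zero prediction conflicts with a knocked-out secretion
route — and, as a last resort, the lower bounds drop to zero so the
constraint weakens to "at most the predicted value" (reported as relaxation
level 1.0): the model is never forced to produce a secretion it cannot
achieve.

## Evaluation protocol

Nested cross-validation: an outer leave-one-out over samples; within each
outer split, a randomized hyperparameter search (default 3 candidates)
scored by mean validation NE over an inner 5-fold split of the training
samples; the winner is retrained on all training samples and scored on the
held-out sample with R², MAE, RMSE, NE across its reference fluxes, plus
the steady-state violation `(1/m)‖S·V‖²` of the full predicted
distribution. R² is per held-out sample across fluxes and reported as
missing (never faked) when the reference vector is constant. Every fit is
fingerprinted with its training-sample ids and fitted scaler so absence of
leakage is checkable after the fact. The scheduler strategy tunes only
`final_data_weight`, per its design. Aggregates are the plain mean and
standard deviation over splits and are recomputable from the per-split
table.

The parsimonious-FBA baseline fixes each sample's measured uptakes (oxygen
optionally as a capacity), applies the sample's knockout via the
gene–reaction rules (or directly by reaction id for synthetic metadata),
and projects the solution onto the reference panel.

## Synthetic data generator

The generator emulates the structure of a chemostat multi-omics study of a
glucose-fed bacterium: 29 samples by default — five wild-type samples at a
glucose-level series standing in for the dilution-rate series, and 24
single-gene-knockout samples — with 79 transcript features, 60 protein
features and the two measured uptakes. Knockout samples draw their glucose
level uniformly across the series range (a deliberate departure from the
fixed-dilution knockout design: with only a handful of distinct conditions
a large simulated dataset would be degenerate and unlearnable).

The toy network routes glucose through a chain with a parallel two-step
bypass and a reversible step into a hub metabolite that is either respired
(consuming oxygen, feeding biomass), fully oxidized (different O₂:CO₂
ratio, giving the exchange fluxes an internal degree of freedom), or
secreted as acetate (cheapest), succinate, or ethanol (dearest); a dead-end
reaction exercises the variability reduction. Ground-truth fluxes come from
parsimonious FBA per condition. Omics features are saturating Michaelis–
Menten-like functions `gain·s/(s+K)` of weighted 1–3-reaction flux subsets
(a linear mode exists for identifiability tests) plus Gaussian noise
(default sd 0.05 on the feature scale; reference-flux noise defaults to 0).
Measured inputs are copied from the true solution.

Two knobs reproduce the study's central difficulties. `offspace_delta`
adds a per-sample perturbation of stated magnitude along a random
stoichiometric row-space direction — orthogonal to the null space, hence
genuinely infeasible, and exactly removable by the quadratic flux-fit.
`overflow_frac` forces a fixed fraction of the glucose feed through
fermentation even when oxygen would allow full respiration, emulating
regulatory overflow metabolism that parsimonious optimality cannot predict
from the uptakes alone; without it, pFBA-generated truth makes the
uptake-only pFBA baseline trivially perfect and comparisons against it
vacuous.

What passing on this generator does *not* show: real transcript/protein
abundances are not monotone single-valued functions of fluxes; real
measurement error is not i.i.d. Gaussian; the toy network's ~25 split
reactions are two orders of magnitude below a genome-scale model, so
results here demonstrate correctness and qualitative behavior of the
machinery, not expected accuracy on organism-scale data.

## Problem sizes in the shipped experiments

The test suite and the reproduction script run the pipeline at sizes chosen
to exercise every code path on a single CPU in minutes: 200-sample
noiseless datasets for generalization and ablation checks, 400-record
reservoir datasets, 60-sample secretion-active datasets for the
reservoir-vs-baseline comparison, 6-sample datasets for protocol-integrity
checks, and the bundled E. coli central-metabolism model (95 reactions,
141 after splitting) for the genome-scale reduction demonstration with
2000 sampling simulations.

## Known limitations

* Exact reproduction of published model-reduction reaction counts for the
  large E. coli and L. lactis reconstructions requires those SBML files
  and depends on the splitting convention and the zero-flux tolerance of
  the tool that produced them; this package ships its own convention
  (split every reaction with a negative lower bound) and documents the
  tolerances.
* The quadratic flux-fit uses a dense general-purpose NLP solver; it is
  sized for reduced models (hundreds of reactions), not for unreduced
  genome-scale QPs.
* The mechanistic layer enforces constraints softly; refined outputs can
  retain small negative entries (bounded in tests at 2% of the flux scale)
  — downstream consumers needing exact feasibility should use the
  reservoir's pFBA coupling, whose output is an LP solution.
* One hidden layer only, CPU only, by design.
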