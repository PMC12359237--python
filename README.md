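# minnflux

Hybrid constraint-based / deep-learning prediction of genome-scale metabolic
flux distributions from multi-omics data.

## The problem

Flux balance analysis (FBA) predicts metabolic fluxes from a genome-scale
metabolic model (GEM) alone: maximize an objective (usually growth) subject
to the steady-state constraint `S v = 0` and flux bounds. It cannot use
transcriptomic or proteomic measurements, and real cells — especially
knockout strains before adaptive evolution — deviate from its optimality
assumptions. Pure machine learning can learn fluxes from omics profiles but
ignores stoichiometry and needs more data than a typical fluxomics study
provides (tens of samples).

`minnflux` implements a metabolic-informed neural network (MINN) that sits
between the two. A one-hidden-layer network maps a sample's concatenated
omics profile `X` (transcripts + proteins + measured exchange fluxes) to an
initial flux estimate

```
V0 = ReLU(X·Wh + bh)·Wout + bout
```

which a differentiable *mechanistic layer* refines by unrolled gradient
descent on the FBA-constraint loss

```
L_FBA(V) = (1/m)‖S·V‖² + (1/n_in)‖ReLU(Pin·V − Vin)‖² + (1/n)‖ReLU(−V)‖²
```

(steady state, measured uptake bounds, non-negativity on the reversibly-split
model). Training minimizes `c·L1 + L2 + L3 + L4`, where `L1` is the
normalized error `‖Pref·V − Vref‖/‖Vref‖` against measured reference fluxes
and `L2..L4` are the constraint terms; several balancing strategies (fixed
multiplier, excess-penalty bound, exponential-average normalization, phased
weight scheduler, data-only ablation) trade prediction accuracy against
mechanistic fidelity. A *reservoir* variant pretrains a frozen MINN as a
neural FBA surrogate, learns to predict exchange fluxes from omics in front
of it, and hands those predictions to parsimonious FBA as extra constraints,
so the final output is a true LP solution.

The package also covers the surrounding workflow: SBML model loading,
reversible-reaction splitting, flux-variability and FBA-sampling model
reduction, quadratic projection of measured fluxes onto the solution space
("FBA fit"), leave-one-out + inner 5-fold nested cross-validation, and a
synthetic-data generator that emulates a chemostat multi-omics study
(dilution-rate series + single-gene knockouts) on a toy overflow-metabolism
network with known ground truth.

## Worked example

```python
import numpy as np
import minnflux as mf

model = mf.split_reversible(mf.make_toy_gem())
ctx = mf.MechanisticContext.from_model(
    model, ["EX_glc_rev", "EX_o2_rev"], reference_ids=list(mf.TOY_REFERENCE_PANEL)
)
spec = mf.SyntheticSpec(n_samples=60, omics_noise_sd=0.0, target_noise_sd=0.0,
                        reference_ids=list(mf.TOY_REFERENCE_PANEL), seed=7)
ds = mf.simulate_dataset(model, spec)
cfg = mf.MinnConfig(dh=64, lr_nn=3e-3, epochs=300, strategy="c_balanced",
                    c=10.0, seed=0)
trained = mf.train_minn(ds.subset(ds.sample_ids[10:]), ctx, cfg)
V, proj = mf.predict(trained, ds.subset(ds.sample_ids[:10]).features)
ne, _ = mf.data_loss(proj, ds.subset(ds.sample_ids[:10]).reference_fluxes.to_numpy())
print(f"held-out NE: {ne:.4f}")
print(f"steady-state violation: {mf.steady_state_violation(V, ctx.S):.2e}")
```

prints

```
held-out NE: 0.0081
steady-state violation: 1.45e-03
```

i.e. the predictions deviate from the held-out reference fluxes by about
0.8% in relative norm, while the full predicted flux distributions stay
close to the steady-state solution space. A command-line shell is included
for the scripted workflow: `minnflux fixtures` writes a demo workspace (toy
SBML + omics CSV tables), `minnflux reduce` splits and reduces an SBML
model, `minnflux evaluate` runs the nested cross-validation protocol.

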