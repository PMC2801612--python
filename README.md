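# pxkinetics

Quiescent/active cell-proliferation kinetics from DNA-analog pulse-chase
labeling after partial pancreatectomy.

## The problem

After a regenerative stimulus such as 60% partial pancreatectomy (PX),
islet β-cells and pancreatic ductal epithelial cells proliferate.  A
measured labeling index — the percentage of cells positive for a
thymidine analog (BrdU, CldU or IdU) administered over a known window —
confounds two very different scenarios: *every* cell dividing slowly, or
a small *active* subpopulation dividing quickly while the rest stay
quiescent.  Dual-analog pulse-chase designs (CldU then IdU, protocols
named `pulse1-pulse2-measureday`: 2-2-4, 2-2-14, 7-7-14) plus single
BrdU pulses at days 0, 1, 2 and 14 give ten labeling ratios per group,
enough to fit a kinetic model that separates the two.

`pxkinetics` is aimed at quantitative biologists analyzing such
experiments.  It provides the forward model, the published labeling
tables of the four study groups (wild-type and Cdk4-R24C mutant mice ×
islet β-cells and duct cells) as a built-in fixture, a
parallel-tempering Monte Carlo fitter, Bayesian model comparison over
the quiescent:active ratio, a synthetic-data generator for end-to-end
validation, and the derived summaries (active-cell rates, proliferated
proportions, β-cell-mass accounting).

## The model

Two populations: quiescent cells (`N_Q = f`, never divide) and active
cells (`N_A(0) = 1`) dividing at a per-cell rate shaped as a product of
a rising and a falling logistic,

    r(t) = r0 · S_up(t) · S_down(t),
    S_up   = 1 / (1 + exp(−(t − t_rise)/τ_rise)),
    S_down = 1 / (1 + exp( (t − t_fall)/τ_fall)).

A division during an analog window removes one active cell and creates
two labeled cells; labeled cells do not re-divide (double-labeled cells
are structurally absent).  Hence `N_A(t) = exp(−∫ r)` and the predicted
labeling ratio for window `[a, b]` measured at day `T` is

    L = 2 (N_A(a) − N_A(b)) / (f + 2 − N_A(T)).

Fitting minimizes / samples the replicate-SD-weighted cost
`χ = Σ (d_i − m_i)² / σ_i²` with ten tempered Metropolis chains (levels
0.1 … 1.0, replica-exchange swaps every 20 steps), a detection-scale
factor η = 3 relating CldU/IdU to BrdU ratios, and posterior statistics
from the untempered chain.  Model evidence over a grid of fixed `f`
values comes from thermodynamic integration of the temperature-averaged
cost.  See `docs/methods.md` for the full account.

## Worked example

```python
import pxkinetics as px

dataset = px.builtin_table1("R24C:beta")          # ten observations
config = px.FitConfig(n_equilibration=60_000, n_production=50_000, seed=12)
fit = px.parallel_tempering_fit(dataset, config)

print(f"best cost {fit.best_cost:.2f}")
print(f"posterior f = {fit.posterior_mean['f']:.2f} +/- {fit.posterior_sd['f']:.2f}")
mg, pct = px.proliferation_mass_contribution(fit.best_params, initial_mass=0.38)
print(f"proliferation adds {mg:.3f} mg = {pct:.1f}% of initial beta-cell mass")
```

prints

```
best cost 6.16
posterior f = 1.09 +/- 0.62
proliferation adds 0.129 mg = 33.9% of initial beta-cell mass
```

meaning: the mutant β-cell labeling data are best explained by roughly
one quiescent cell per active cell, and the divisions implied by the
fitted kinetics add ~0.13 mg of new β-cell mass over the two weeks
after PX — about a third of the initial 0.38 mg, leaving most of the
observed mass increase to non-proliferative sources.

The same workflow is available from the shell:

```sh
pxkinetics fit --builtin R24C:beta --seed 12 --out runs/r24c-beta
pxkinetics compare --builtin WT:duct --f-grid 0,1,2,5,10,20,50,100 --out runs/wt-duct-evidence
pxkinetics simulate --preset r24c-like --seed 7 --out runs/synthetic
pxkinetics report --fit runs/r24c-beta/fit.json --initial-mass 0.38 --out runs/report
```

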