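# Methods

## The model

`pxkinetics` models the proliferative response of a tissue to a
regenerative stimulus (here, partial pancreatectomy at day 0) with two
cell populations:

* **quiescent cells**, present in the fixed ratio `f = N_Q / N_A(0)`
  relative to the initial active pool, which never divide;
* **active cells**, which divide at a time-dependent per-cell rate
  `r(t)` and, upon division during a thymidine-analog administration
  window, are replaced by two analog-labeled daughters.

Re-division of labeled cells is neglected (double-labeled cells are rare
over the two-week horizon), so the active pool depletes as

    N_A(t) = exp(-∫ r(s) ds),        N_Q(t) = f,

and every division removes one active cell and adds two labeled ones.
The rate is a product of a rising and a falling logistic,

    r(t) = r0 · S_up(t) · S_down(t),
    S_up(t)   = 1 / (1 + exp(-(t - t_rise)/tau_rise)),
    S_down(t) = 1 / (1 + exp( (t - t_fall)/tau_fall)),

whose left tail supplies the basal pre-stimulus rate (the model is
evaluated for t < 0 as well).  A predicted labeling ratio for a window
`[a, b]` read out at day `T` is labeled cells over all cells counted,

    L = 2 (N_A(a) - N_A(b)) / (f + 2 - N_A(T)).

"Labeled over total" was chosen over "labeled over unlabeled" because
the study tables report percentages of labeled cells among counted
cells; the two conventions differ only at large labeling fractions.

### Bookkeeping origin

All observations of one experiment share a common origin: the start of
the earliest labeling window (day −1, the single-analog pulse before the
day-0 measurement).  Divisions from the origin onward are counted in
every later denominator.  A standalone `labeled_fraction` call anchors
at its own window start instead (an explicit `origin` argument overrides
this), which makes time-translation invariance exact and matches the
whole-dataset predictor when the shared origin is passed.

### Parameters

| name       | meaning                                   | units | bounds (fit) |
|------------|-------------------------------------------|-------|--------------|
| `f`        | quiescent : initial-active cell ratio     | –     | [0, 200]     |
| `r0`       | peak proliferation rate of active cells   | /day  | [0, 1]       |
| `t_rise`   | half-maximum day of the rising phase      | day   | [−5, 30]     |
| `t_fall`   | half-maximum day of the falling phase     | day   | [−5, 30]     |
| `tau_rise` | rise time scale                           | day   | [0.05, 20]   |
| `tau_fall` | fall time scale                           | day   | [0.05, 20]   |
| `eta`      | CldU/IdU detection scale                  | –     | fixed at 3 (or [0.5, 10]) |

`eta` reconciles drinking-water CldU/IdU labeling with injected BrdU:
raw dual-analog ratios are multiplied by `eta` before comparison with
the model.  Published tables already carry the conventional 3-fold
rescaling, so with `eta = 3` (the default policy) stored values enter
the cost unchanged; the `eta_policy="free"` mode samples `eta` as a 7th
parameter.

The 16-hour BrdU pulse is modeled as a 1-day labeling window ending at
the measurement day; the day-0 point uses the window [−1, 0] and the
basal rate.

## Cost and sampling

The fit minimizes / samples the replicate-SD-weighted squared deviation

    chi(θ) = Σ_i (d_i − m_i)² / σ_i²

over the ten observations of a group (four BrdU days, three protocols ×
two analogs), with σ_i the printed replicate SD floored at
`sigma_min = 0.1` percentage points (the smallest SD actually printed)
to keep weights finite.  Sampling targets `exp(−level·chi)`; the
level-1.0 chain is the untempered target.  Note this convention — taken
over unchanged from the study design — is a factor 2 sharper than the
Gaussian-likelihood convention `exp(−chi/2)`; posterior SDs reported
here inherit that extra confidence.

`parallel_tempering_fit` proceeds in two phases:

1. **Equilibration / global search.**  `n_replicas` (default 4)
   independent copies of the ten-level ladder 0.1 … 1.0 run
   simultaneously (vectorized), each with Metropolis acceptance
   `exp(−level·Δchi)`, random-pair replica-exchange swaps every 20
   steps inside each copy, and per-chain proposal widths adapted toward
   20–40% acceptance.  The tau time scales random-walk on a log scale
   (with the corresponding Hastings factor), which is essential for
   locating sharp-onset solutions near the lower tau bound: the duct
   landscape of the mutant group has a deep, narrow optimum with
   `tau_rise` at its bound that per-parameter linear walks find only
   rarely.  Replicated ladders turn that residual discovery probability
   into a reliability guarantee; all replicas of all tested seeds now
   agree on the optimum basin for every group.
2. **Production / posterior statistics.**  One ladder restarts from the
   global best point, swaps stay on (replica exchange preserves the
   per-level marginals), adaptation is frozen after a short discarded
   warmup, and the level-1.0 chain supplies posterior means and SDs.
   Production proposals are correlated Gaussian jumps shaped by the
   empirical covariance of the late-equilibration cold chains (in
   log-tau coordinates).  Independent per-parameter proposals were
   tried first and under-dispersed the posterior by one to two orders
   of magnitude along the strong `f`–`r0`–`t_fall` ridge of this model;
   the covariance-shaped proposals reproduce the posterior of an
   affine-invariant ensemble sampler (emcee) run on the identical
   target, which the test suite checks.

Defaults are 2×10⁵ equilibration and 10⁵ production steps; the packaged
refit workflows use 6×10⁴ / 5×10⁴, at which split-half convergence
checks pass for every group.  Everything is driven by one
`numpy.random.Generator`, so results are bit-for-bit reproducible given
the seed.

## Model evidence

`model_probability` treats a fixed quiescent:active ratio `f` as the
model index, samples the remaining parameters at every ladder level
*without* exchange moves, and estimates the log evidence by
thermodynamic integration: `d log Z / d level = −⟨chi⟩_level`,
integrated across the ladder with the trapezoidal rule.  The prior is
uniform over the fit bounds; its volume term is a constant across `f`
and is dropped.  The ladder does not extend below level 0.1, so the
integral omits the `[0, 0.1]` tail; the omission is shared across the
profile and has negligible effect on the normalized probabilities
(`evidence_profile`), which is the object actually interpreted.
Chains whose temperature-averaged cost still trends between the two
halves of the measurement phase attach a convergence warning.

## Synthetic data

`generate_dataset` emulates the labeling experiment for a known truth:
model ratios for the ten-cell design (same shared-origin bookkeeping as
the fit), CldU/IdU truths divided by the true detection factor, a small
number of animal-level replicates drawn per cell — binomial counting
noise with 1000 scored cells per replicate by default, matching the
stated counting effort of the study design, or Gaussian noise with a
fixed CV — and replicate mean ± SD stored in the published convention
(dual-analog values ×3, `scale_applied=True`).

Two truth presets ship with the package (chosen by the implementers to
bracket the observed contrast; they are not published values):
`WT_LIKE` (f=40, r0=0.30/day, rise at day 1.5, fall at day 3) with a
large quiescent pool and a brief response, and `R24C_LIKE` (f=2,
r0=0.25/day, rise at day 1.0, fall at day 8) with a small quiescent
pool and a sustained response.

What the generator does **not** emulate: staining/detection artifacts
beyond the scalar `eta`, animal-to-animal kinetic heterogeneity, and
re-division of labeled cells.  Passing recovery tests therefore show
that the estimator inverts its own generative assumptions, not that
those assumptions hold in tissue.

## Numerical choices

* Fast inference path: the rate integral is evaluated by composite
  16-point Gauss–Legendre panels (≤ 0.5 d) between protocol knots,
  vectorized across chains; agreement with adaptive quadrature is at
  machine precision for tau ≳ 0.2 d and ~2×10⁻³ relative in the worst
  corner (tau at its 0.05 d bound), far below the data SDs.
* Public kinetics API: adaptive quadrature (`scipy.integrate.quad`,
  epsabs 10⁻¹², split at the logistic midpoints);
  `integrate_trajectory` uses cumulative Simpson on its grid (default
  step 0.01 d).
* Proposal reflection at the box bounds keeps proposals symmetric;
  log-walked dimensions reflect in log space.
* Ties and degenerate inputs: zero replicate SDs require the
  `sigma_min` floor (or raise); non-finite costs at initialization are
  re-drawn up to 100 times before erroring.

## Known limitations

* Posterior summaries inherit the `exp(−chi)` convention and
  small-replicate SD weights; they are overconfident in the frequentist
  sense.  One-SD posterior intervals cover the generating truth well
  below the nominal Gaussian 68% in recovery experiments (~20–40% for
  `r0`); three-SD intervals are the calibrated working contract and are
  what the recovery tests assert.
* The quiescent:active ratio `f` is only weakly identified by labeling
  ratios: a cumulative labeled fraction `L` at the final day bounds the
  supported region to roughly `f ≲ 2/L − 2`, and within it `f` trades
  off against the depletion depth along a likelihood ridge.  Posterior
  means of `f` for the wild-type groups are therefore small (≈ 5) and
  prior-sensitive; published summaries derived from a flatter sampling
  convention can be much larger.
* The mutant-duct table is internally inconsistent under the stated
  weights (three tight rows cannot be fit jointly by any single
  rise/fall rate curve); the refit settles at the weighted compromise
  with the lowest cost, which is lower than the cost of the published
  model column.
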