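# Methods

## Model

For district `i` and year `t`, observed case counts are modelled as
`Y(i,t) ~ Poisson(E(i,t)·λ(i,t))` with

```
log λ(i,t) = α + Σ_k β_k x_k(i,t) + U_i + V_i + X_t + ε(i,t)
```

The expected counts `E` come from indirect age standardisation: reference
age-specific incidence rates (one national reference year) multiplied by the
district's female population per age group and summed. `λ` is therefore a
relative risk against that reference schedule, and the raw analogue of the
model's estimand is the SMR `Y/E`.

Random-effect structure (the BYM convolution plus time):

* `U` — intrinsic CAR: the joint (improper) density is
  `p(U) ∝ exp(−τ_u/2 · Σ_{i~j} (U_i − U_j)²)` over the adjacency graph;
  the full conditional of `U_i` is normal with mean the average of its
  neighbours and precision `τ_u·deg(i)`. The level is unidentified, so the
  field is recentred to sum to zero after every sweep. Isolated districts
  (no neighbours) carry `U_i ≡ 0`; their between-district variation is
  absorbed by `V_i`. This is the standard identifiable treatment of islands.
* `V_i ~ N(0, 1/τ_v)` iid; `X_t ~ N(0, 1/τ_x)` iid (years exchangeable, no
  random-walk structure); `ε(i,t) ~ N(0, 1/τ_eps)` iid — the saturated
  space-time interaction.

Priors: `α, β_k ~ N(0, 1000)`; all precisions `~ Gamma(0.5, rate 0.0005)`
— conventional diffuse disease-mapping defaults, overridable in
`RunConfig.priors`. Covariates are centred and scaled to unit SD before
fitting (sampler conditioning); the transform is stored with the draws and
`beta_original_scale()` / `alpha_original_scale()` undo it. The default
covariate set is {YOS, URB, COMP}; the wealth index can be added via
`covariate_selection`.

Unobserved cells (e.g. a fully missing year) contribute nothing to the
likelihood; the model still produces `λ` there — the spatial and temporal
effects interpolate — which is how missing-year estimates and hold-out
predictions are obtained.

## Sampler

Metropolis-within-Gibbs, 2 chains by default (chain `c` seeded
`seed + c`), 15,000 iterations each with 5,000 burn-in (20,000 retained
draws total, matching the reference analysis protocol; smaller presets are
used for testing).

Update cycle per iteration:

1. `α`, each `β_k`: scalar random-walk Metropolis. Because a shift `d` in a
   scalar moves the linear predictor by a known pattern, the likelihood
   delta is computed from cached intensities without re-evaluating the full
   model.
2. `U`: the graph is properly colored (greedy coloring); districts of one
   color are never adjacent, so their ICAR full conditionals are mutually
   independent given the rest and each color class is proposed and accepted
   in one vectorised step. Afterwards the field is recentred to sum to zero
   (the intercept re-absorbs the level over subsequent iterations).
3. `V`, `X_t`: element-wise vectorised random walks (their full
   conditionals are independent across elements).
4. `ε`: element-wise random walk at observed cells; at unobserved cells the
   full conditional is exactly the prior, so a fresh prior draw is taken
   (a Gibbs step — faster mixing for interpolated years).
5. Translation moves. The posterior of a BYM-type model has long ridges:
   only `α + mean(V) + mean(X) + …` and `β_k·x + (absorbable surfaces)` are
   well identified. Dedicated joint moves shift one parameter and
   compensate with the random-effect surfaces so the linear predictor is
   (near-)invariant and only prior ratios enter the acceptance probability:
   `α ↔ level(X_t)`, `α ↔ level(V)`, `U_i ↔ V_i` per color class, and for
   each `β_k` three variants that push the covariate's district profile
   into `U` (or `V`), its year profile into `X_t` and the non-separable
   remainder into `ε`. These moves cut the R-hat of the fixed effects from
   ~1.1–1.3 to ~1.01–1.08 at identical iteration counts.
6. Precisions: conjugate gamma Gibbs draws. For `τ_u` the shape uses the
   ICAR rank (non-isolated districts minus connected components) and the
   rate uses the pairwise-difference sum over edges.

Random-walk proposal scales adapt during burn-in only (Robbins–Monro on the
log scale towards 0.44 acceptance, step `t^-0.6`, clamped) and are frozen
afterwards so detailed balance holds for the retained draws. Post-burn-in
acceptance rates are logged; rates outside [0.05, 0.95] trigger a warning.
Initialisation: `α` at the moment estimate `log(ΣY/ΣE)`, everything else at
zero, precisions at 1.

## Posterior summaries

District RR summaries are posterior means with 2.5th/97.5th empirical
percentiles (linear interpolation between order statistics — numpy's
default rule, declared so the sort-based oracle in the tests is exact).
The national RR per year is the expected-count-weighted mean of district
RRs within each draw, `Σ_i E(i,t)λ(i,t)/Σ_i E(i,t)` — the plug-in analogue
of total observed over total expected (population weighting is available by
flag). Exceedance probabilities compare district and national values
draw-by-draw (same iteration) with strict inequality, so a district
identical to the national trajectory gets probability 0.

## Projection

For each district and each posterior draw, ordinary least squares of that
draw's RR against calendar year over the fit years (all years with a
posterior RR, including model-interpolated missing years), evaluated at the
requested future years. Projection is on the RR scale, matching the linear
projection-model form `R = b0 + b1·X`; negative extrapolations are floored
at 1e-6 and the floored-cell count is logged. The year covariate is centred
at the fit-window midpoint for conditioning; the stored intercept is
re-expressed at year zero. Summaries over draws use the same percentile
rule as above, which propagates the full posterior uncertainty into the
projections.

## Cross-validation and diagnostics

A fraction (default 10%) of the *observed* district-year cells is withheld
uniformly at random; the model is refitted on the rest and the posterior RR
at each held-out cell is compared with the held-out SMR `Y/E` (the model's
estimand is a relative risk, so the SMR is the observed value on the same
scale — a declared design choice). Reported per year: median relative
error, median absolute relative error, median error, median absolute error,
and the percentage of held-out SMRs inside the predicted 95% credible
interval. Cells with `Y = 0` have no defined relative error and are
excluded from the relative-error medians only (count reported); they remain
in the absolute-error and coverage summaries.

The rank test is a per-draw Wilcoxon signed-rank analogue and is this
package's declared contract: for each posterior draw, the differences
(predicted − observed) over held-out cells are ranked by magnitude (average
ranks on ties, zero differences contributing zero) and the mean signed rank
is the draw's statistic; the 95% interval of the statistic across draws and
whether it contains zero are reported.

R-hat is the split-chain potential scale reduction factor: each chain is
halved and `sqrt((W(n−1)/n + B/n)/W)` is computed over the half-chains —
stricter than the unsplit statistic because within-chain trends surface as
between-half disagreement (this also makes the statistic sensitive to draw
order, which is intended). Zero within-chain variance reports 1 with a
warning. DIC is `Dbar + pD` with `pD = Dbar − D(θ̄)`; since the linear
predictor is linear in all parameters, `D(θ̄)` is evaluated at the
posterior mean of `log λ`.

## Synthetic-data generator

The generator draws panels from the generative form of the model itself so
that every pipeline stage is testable without registry downloads. Scenario
shape mirrors a national registry panel: districts on a rook-adjacency
lattice (the `paper-scale` preset uses 316 districts over 2000–2010), one
fully missing year (2006), optional thinning of the first year (sparse
early registration), and a national risk level that can rise severalfold
across the window via a deterministic drift in `X_t` (the `paper-scale`
preset rises ~3x). Covariates: schooling with a north–south gradient plus
district noise and a small annual increase; urbanisation correlated with a
wealth index; registry completeness improving over time. Age structure: a
gamma-shaped female pyramid over 5-year bins from 30 to 85+ (the modelled
population is women over 30) with reference rates increasing with age;
district populations are log-normally dispersed around the scenario scale.

`U` is sampled by coloring-blocked Gibbs sweeps of the ICAR conditional
with recentring (300 sweeps by default) — reusing the model's own
conditional works on any graph, including ones with islands, where an
eigen-decomposition approach would need special-casing.

For inequality studies the generator can calibrate `β_yos` so that the
expected-count-weighted top/bottom-quintile ratio of `exp(β·YOS)` equals a
target (root-finding on the realised covariate values) — the generative
quintile risk ratio is then the target exactly, and the measured RII
estimates it. The RII scenario uses 120 districts with a weak spatial
gradient and dominant district-level schooling noise so that quintile
membership is nearly independent of the spatial field; with spatially
banded quintiles the correlated field noise would not average out within
quintiles and the ratio estimator would be inflated. The Monte-Carlo
summary over replicates is the geometric mean — the natural location
summary for a ratio-valued statistic.

What the generator does not emulate: real geography (adjacency is a
lattice), registry artefacts such as duplicate reporting or
pathology-vs-population case mix, covariate measurement error, and
migration. Passing tests therefore demonstrate correctness of the machinery
and calibration under the model's own assumptions, not robustness to their
violation on real registry data.

## Test problem sizes

The test suite and acceptance script run scaled-down scenarios chosen to
keep full runs comfortable on a single CPU while leaving the protocol
intact: parameter recovery uses 24 districts x 11 years with 2 chains x
6,000 iterations (1,000 burn-in); cross-validation calibration pools ~200
held-out cells over five 40-district fits (2 chains x 2,500); the conjugate
limit uses 10,000 retained draws; the RII check uses 50 replicates of the
120-district scenario. The full-size default (2 chains x 15,000, 316
districts) is exercised structurally via the `paper-scale` preset.

## Known limitations

* The ICAR recentring step without intercept compensation is the standard
  disease-mapping practice but is a slight approximation to exact detailed
  balance on the unconstrained space; the conjugate-limit and
  parameter-recovery checks bound its practical effect.
* Projection is linear on the RR scale by design fidelity; it can cross
  zero (floored) and ignores covariate futures.
* The exceedance probability uses strict inequality; ties (measure-zero in
  practice) count as non-exceeding.
* DIC's `pD` can be unstable under strong non-normality of the posterior;
  it is reported with its components so users can judge.
* The regression-based RII variant (`regression_rii`) is provided for
  comparability, but the headline RII is the extreme-quintile ratio.
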