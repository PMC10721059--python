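# Methods

## The estimation problem

Let `D_i` be individual `i`'s true dose (Gy) and `Y_i` a disease outcome.
The two risk models are

- linear ERR Poisson: `Y_i ~ Poisson(PY_i · λ0_i · (1 + β D_i e^{η′M_i}))`
  with log-linear baseline `λ0_i = exp(α0 + α′C_i)` and person-years offset
  `PY_i`;
- linear EOR logistic: `odds_i = exp(α0 + α′C_i)(1 + β D_i e^{η′M_i})`.

`β` (ERR or EOR per Gy) is the target. The linear dose term forces
`1 + β D_i e^{η′M_i} > 0`; the optimizer box-constrains `β` to
`(−1/max_i(D_i e^{η′M_i}) + 10⁻⁸, ∞)`, the standard convention for
linear-ERR software. Log-likelihoods keep their constants (`log Y_i!`), so
AIC values are absolute.

`D_i` is unobserved. The data carry `K` reconstructed cohort dose vectors
`X_1..X_K`, one per joint draw of the dosimetry system's shared and
unshared error components. All estimators in this package consume that
ensemble directly.

## SUMA dose simulator

`X_ik = ε_SM,k · ε_UM,ik · Z_i + ε_SA,k + ε_UA,ik`, with multiplicative
errors lognormal with mean exactly 1 (`μ = −σ²/2`, `σ = √var`) and
additive errors normal with mean 0. "Shared" draws take one value per
realization `k`; "unshared" draws are independent per individual. Scenario
presets 1–4 set log-scale variances (0.318/0.223, 0.632/0.223, 0.632/0.446,
0.954/0.223 for shared/unshared), whose geometric standard deviations
`exp(σ)` are 1.8/1.6, 2.2/1.6, 2.2/2.0, 2.7/1.6. The variances are
interpreted on the log scale because that is the only reading that
reproduces the tabulated GSDs. Additive components are implemented but
default to zero; the simulation study exercises the multiplicative terms
only.

Because the multiplicative errors have mean one, the ensemble is centered
on the baseline vector `Z` — a Berkson-type structure in which `Z` is an
unbiased surrogate for the true dose.

The baseline doses `Z_i` are lognormal with median 0.1 Gy and GSD 2.0 by
default (configurable). No external reference pins this distribution, so it
is the package's own choice: a right-skewed, sub-Gy scale typical of
reconstructed environmental thyroid doses, and one at which the null-model
(β = 0) slope uncertainty of the fitted ERR model is of order 0.05–0.08
per Gy at N = 1,000.

Simulated cohorts: age ~ U(20, 50), gender ~ Bernoulli(0.5), person-years ~
Exponential(rate 0.5); one row is one stratum. Simulated Poisson outcomes
use `λ_i = exp(1 + 1.5·gender_i + 2·log(age_i/40)) · (1 + β·dose_i)` and
`Y_i ~ Poisson(λ_i · PY_i)`. Note this generating model is *count-rich*
(several events per stratum on average), so simulated studies carry far
more outcome information than a typical rare-disease cohort; consequences
are discussed under Limitations.

## FMA

Stage 1 fits the same model once per analysis realization. All K fits share
the cohort, so they are solved jointly by a Newton–Raphson iteration
vectorized over a (K, p) parameter block: per iteration, the gradient and
observed information of every active column are assembled with dense matrix
products, a batched linear solve gives the Newton directions, and a
per-column backtracking line search enforces monotone ascent and the
positivity constraint. A column is frozen the moment it converges (relative
log-likelihood change < 10⁻⁹ and gradient max-norm < 10⁻⁴), which makes
each column's result independent of how columns are batched (up to ~1 ulp
of floating-point lane noise). Initialization: null-model α's from a
standard Poisson GLM with β = 0; columns that stall fall back to a scalar
optimizer with a moment-based β start and three deterministic jitters.
`var(β̂_k)` is the β-diagonal of the inverse observed information. An
all-zero dose column leaves β unidentified: it is reported as β̂ = 0 with
infinite variance and receives zero averaging weight.

Stage 2 forms Akaike weights `FW_k ∝ exp(−½(AIC_k − min AIC))` (max-shifted
for overflow safety; non-converged or unidentified fits get weight 0),
allocates `n_k` of `M` draws by largest-remainder rounding (ties broken by
index), samples `n_k` values from `N(β̂_k, var(β̂_k))`, and reports the
pooled mean and the 2.5th/97.5th empirical percentiles (linear
interpolation). Because draws are allocated proportionally to the weights,
the plain pooled mean already is the weight-proportional estimator; no
second weighting is applied. Default `M` = 100,000 (20,000 in the
reduced-scale studies).

On the sign of the weight exponent: a goodness-of-fit weight must *decrease*
in AIC; `exp(−½ΔAIC)` is the standard Akaike weight and the form used here.

## CIM

CIM fits the ERR Poisson model once on the per-individual mean dose
`Z̄_i = mean_k X_ik` over the analysis realizations and corrects the Wald
variance:

```
Var(Θ̂) = I_Z⁻¹ + β̂² · I_Z⁻¹ M Cov(X|Z) M′ I_Z⁻¹
```

`Cov(X|Z)` is the empirical covariance across realizations with denominator
K − 1 (row-mean centered). `M = Q G` is minus the sensitivity of the score
to the dose vector: a Taylor expansion of the score of the Poisson ERR
likelihood gives `∂S/∂X_i = −β · PY_i · exp(α′W_i) · q_i` with
`q_i = (1, C_i, Z_i/(1+β̂Z_i))′`, so `G = diag(PY_i · exp(α′W_i))` — the
person-years factor belongs in `G` whenever the likelihood carries a
person-years offset (with PY ≡ 1 the familiar `diag(exp(α′W))` form is
recovered). The `p×p` product is computed as `(p×N)(N×N)(N×p)`; nothing
larger than N×p is materialized beyond the covariance itself. The
correction is a positive-semidefinite quadratic form scaled by `β̂²`: the
corrected variance can never fall below the naive one, it vanishes exactly
at `β̂ = 0`, and with identical realizations it vanishes identically.

Shared errors give `Cov(X|Z) ≈ Var(ε_SM)·ZZ′` (rank one); unshared errors
contribute a diagonal (per-individual Berkson) term that does *not* vanish
with K and is intentionally absorbed. CIM has no published form for binary
outcomes; requesting the logistic family raises an explicit error.

## BMA

The dose index `γ` is a categorical parameter selecting the likelihood's
dose column. A Dirichlet(1,..,1) hyperprior on the selection probabilities
marginalizes to a uniform `p(γ) = 1/K`, so the simplex is never sampled.
Priors: N(0, 1000) on baseline parameters; for the slope either a
truncated-at-zero N(0, 1000) (default; it encodes the positivity constraint
of the linear excess term, so every posterior slope draw is ≥ 0) or an
exponential. Sampling is blocked Metropolis–Hastings: scalar random-walk
updates for each regression parameter and an independent *uniform* proposal
over {1..K} for `γ` — a global move chosen because the posterior in `γ` is
typically multimodal and local moves trap. Proposal scales adapt during
burn-in toward 20–45% acceptance (factor-1.25 adjustments every 200
iterations), then freeze. Defaults: 4 chains × 50,000 iterations, 20,000
burn-in, thinning 5, pooled post-burn-in draws; all configurable, and far
smaller settings suffice at small N and K. Outputs include per-block
acceptance rates (a near-zero rate triggers a warning naming the scale to
shrink), Bayesian weights `BW_k` (selection frequencies of `γ`), and the
95% HPD interval — the shortest window containing ⌈0.95·n⌉ sorted draws.

## Study harness and operating characteristics

One test: draw a cohort and baseline `Z`, generate K realizations,
designate column `t mod K` as true (a rotating, reproducible rule), draw
outcomes from it, exclude it, run each method on the remaining K−1 columns.
Across tests: CR/LER/RER (% of tests with the truth inside the interval,
above its upper limit, below its lower limit; they sum to 100 before
rounding), mean interval length (LCI), mean absolute bias (AB), mean
absolute relative bias (ARB = |β̂−β|/β), and mean relative upper limit
(RUL = upper limit / β). When β = 0, ARB and RUL are undefined and the
harness substitutes AB and the plain mean upper limit, flagged rather than
raised. Every mean carries its 2.5/97.5 empirical percentiles across tests.
The RUL denominator is the *true* β when known (the simulation setting);
dividing by β̂ instead makes the CIM ratio nearly deterministic because the
corrected SE is proportional to β̂.

Cohort covariates and `Z` are redrawn per test; every stochastic stage
draws from an independent, labeled substream of the master seed, so any
stage can be reproduced in isolation and aggregates are independent of test
execution order.

Reduced-scale defaults — 200 tests, K = 500, N = 1,000, M = 20,000 — are
the package's own choice of problem size: a coverage estimate from 200
tests has Monte-Carlo standard error ≈ 1.5 percentage points, adequate for
method comparison, and a full four-scenario comparison runs in minutes on
one CPU. Full scale (5,000 tests × 4,999 realizations) is reachable through
the same config.

## Numerical choices

- Newton convergence: relative log-likelihood change < 10⁻⁹ *and* gradient
  max-norm < 10⁻⁴; at most 200 iterations, 50 halvings per line search.
- Covariances by explicit inversion of the p×p observed information
  (p ≤ ~6); condition numbers above 10¹² are treated as singular.
- Largest-remainder draw allocation breaks ties toward lower index;
  percentile intervals use linear interpolation — both so results are
  bit-reproducible given a seed.
- Degenerate inputs: all-zero dose → unidentified slope, zero weight;
  empty weight set → explicit "no informative realizations" error; K < 2 →
  covariance undefined error.

## Limitations

- **The error model is idealized.** SUMA's unit-mean multiplicative errors
  make the realization ensemble exactly centered on `Z` (pure Berkson
  structure). Real 2DMC ensembles make no such promise — their mean dose
  can be biased — so passing simulation checks here says nothing about
  bias from a miscentered ensemble.
- **Shared dosimetry error is not identifiable from outcome data.** Two
  realizations differing only by a shared scale fit the outcomes equally
  well (the slope rescales to compensate). AIC weighting therefore
  discriminates realizations only through their *unshared* error patterns,
  and the mean-dose fit tracks the true vector's shared scale one-for-one.
  In count-rich regimes (like the default generating model) the Akaike
  weights concentrate on a handful of realizations and the FMA interval can
  be substantially narrower than the spread of the estimator across tests —
  i.e., FMA under-covers when shared uncertainty dominates and the outcome
  data are highly informative. The replicated studies in the acceptance
  script quantify this behaviour rather than assume it away.
- **Per-realization fits are attenuated.** Relative to the truth, an
  analysis realization's unshared errors act like classical measurement
  error, biasing each β̂_k (and hence the FMA average) downward; left-tail
  interval errors dominate right-tail ones.
- Cox proportional-hazards ERR models, additive-rate (EAR) variants,
  quadratic dose terms, and CIM for binary outcomes are out of scope.
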