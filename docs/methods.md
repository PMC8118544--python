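# Methods

## Model

The package implements a field-defect → initiation → clonal expansion →
transformation → lag model of ESCC incidence. One subject's history:

* **Field-defect onset.** A single stochastic event with age-, period- and
  cohort-modulated rate ν_FD(s; B) (see README for the closed form). The
  onset density f_FD(s) = ν_FD(s)·exp(−∫₀ˢ ν_FD) is *improper* whenever
  ν_FD vanishes or decays — not everyone acquires the defect — and is
  never renormalized.
* **Two-stage clonal expansion.** After onset, dysplastic clones initiate
  at rate μ₁ per year per field; each clone is a linear birth–death
  process (division α, death β) whose cells transform at rate μ₂,
  producing one malignant and one dysplastic daughter (the dysplastic
  count is unchanged by transformation). The exact TSCE hazard/survival
  (h₂, S₂) follow from the roots p ≤ 0 ≤ q of the characteristic
  quadratic.
* **Lag.** Clinical detection follows the first malignant cell after a
  fixed 5-year lag, applied as a hard shift h_clinical(a) = h(a − lag).
  The lag shift is applied to the whole hazard argument, including the
  no-prior-cancer conditioning term in the convolution denominator; the
  model family does not distinguish the alternatives at the data's
  resolution, and the hard shift keeps h ≡ 0 below the lag exactly.

Free parameters in the full model (12): ν₀, μ₁, μ₂, g₀, g₁, g₂, b₁, b₂,
w₁, w₂, y₀, s₀. Fixed: α = 17.4/yr (esophageal stem-cell division rate;
non-identifiable from incidence), lag = 5 yr, B₀ = y₀ (tied reference
years), birth cohorts ≤ 1960. β is always derived as α − g − μ₂ and must
stay positive over the cohort range; violations surface as −inf
log-likelihood, never as silent clipping.

### Regularized trend forms — design choices

The cohort factor exp[b₁(B−B₀)²(1+b₂(B−B₀))] is adopted verbatim; the
period factor uses the same algebraic shape in (y−y₀), which matches the
stated units of w₁ [1/yr²] and w₂ [1/yr], gives value 1 and zero slope at
y₀ (a smooth approach to the background rate), and is symmetric with the
cohort term. The signed (y−y₀) convention makes past period factors
exceed 1, as required to reproduce historically higher incidence.

The log(s/s₀) attenuation multiplies the whole rate (clipped at 0 below
s₀, no saturation cap; a `cap_attenuation` flag caps it at 1 for
sensitivity analysis). Once *both* y ≥ y₀ and B ≥ y₀, ν_FD = ν₀ exactly,
with no attenuation — the regularization stipulates a constant background
rate there. For y ≥ y₀ but B < y₀, only the period factor is pinned to 1;
cohort factor and attenuation still apply, so a cohort crossing y₀ during
life sees a kink in ν_FD. That discontinuity of slope is accepted.

Calendar convention: y = B + s in continuous years. Registry strata are
evaluated at midpoints (age + 0.5, hence cohort B = year − age).

### Numerics

* **Roots.** The discriminant (α+β+μ₂)² − 4αβ is computed as
  (α−β+μ₂)² + 4βμ₂ (no cancellation); the small root comes from the
  product identity q = −αμ₂/p. The identities p+q and pq then hold to
  1e−10 at the scale of the roots.
* **Overflow.** h₂ and log S₂ are evaluated after factoring out e^{−pu},
  so only the bounded e^{(p−q)u} is exponentiated; the model is usable at
  arbitrarily old ages. Trend exponents are summed before a single
  exponentiation, so an enormous period factor times a vanishing cohort
  factor stays finite; genuinely overflowing proposals map to −inf
  log-likelihood.
* **Degenerate roots** (p = q, only when μ₂ = 0 and α = β) raise a
  documented error; the region is outside the biological domain.
* **Convolution quadrature.** The scalar reference (`convolved_hazard`)
  uses adaptive Gauss-Kronrod (abs tol 1e−12, rel tol 1e−8) with the
  integration range split at s₀ and at the y₀ crossing. The likelihood
  path (`cohort_hazard_grid`) evaluates all strata of a table at once:
  per cohort, ν_FD, f_FD, h₂, S₂ are tabulated on a fixed grid (default
  step 0.25 yr; the heavy recovery studies use 0.5 yr) and the numerator
  and denominator integrals become trapezoid convolutions computed by
  FFT across all cohorts simultaneously. Agreement with the adaptive
  reference is O(step²), ~1e−3 relative at 0.25 yr; synthetic tables are
  generated with the same evaluator, so recovery studies are exactly
  on-model.
* **Saturated likelihood** uses 0·log 0 = 0; log(cases!) via log-gamma.
  Zero person-year strata are dropped with a warning; zero expected
  counts with observed cases give −inf log-likelihood.

## Inference

Free parameters are optimized/sampled on a box-normalized internal scale:
each parameter is mapped to [0, 1] through its prior box, on log scale
for strictly positive rates (ν₀, μ₁, μ₂, g₀). This equalizes gradient
magnitudes across parameters whose natural scales span ten orders of
magnitude. Priors are uniform *on this internal scale* — log-uniform in
natural units for the rates — which is the deliberate resolution of the
scale problem those rates pose; summaries are reported in natural units.

* **MLE** (`fit_mle`): bounded L-BFGS-B with central finite-difference
  gradients (relative step 1e−6); multi-start with jittered initials.
  The 12-parameter surface is genuinely multimodal (secondary optima
  where trend parameters trade off), so recovery studies start from
  mildly jittered truth with restarts, and a fit is only trusted when its
  log-likelihood reaches the generating value's.
* **Random-walk MCMC** (`run_mcmc`): multivariate Metropolis-Hastings.
  During burn-in (default 25% of the chain) the proposal covariance is
  re-estimated from the chain history and a global scale factor is tuned
  toward the 0.234 acceptance optimum; both are frozen afterwards, so the
  retained draws come from a fixed reversible kernel.
* **Ensemble MCMC** (`run_ensemble_mcmc`, emcee): the posterior exhibits
  curved ridges (w₁–w₂, μ₁–μ₂–g₀ trade-offs) that a random walk traverses
  too slowly at reduced chain lengths. The affine-invariant stretch move
  handles them far better per likelihood evaluation. Walkers start from
  an overdispersed Gaussian shaped by the inverse observed information at
  the MLE (`laplace_covariance`). This sampler is used for the posterior
  coverage study.
* **Promotion-trend tests.** The published parameterization
  g₀·exp[g₁X(1+g₂X)] leaves g₂ unidentified at g₁ = 0, so
  likelihood-ratio tests of the trend are fitted in the regular
  coefficients (gl, gq) = (g₁, g₁g₂) of the linear-quadratic
  log-promotion exponent — the same model family almost everywhere —
  giving a regular 2-df χ² null.

## Synthetic data

`synthetic.make_py_schedule` emulates the SEER9 tabulation shape:
diagnosis years 1975–2016, single-year ages 0–84 (2079 strata after the
cohort ≤ 1960 exclusion), smooth person-year schedules with a mild
old-age decline and optional cohort scaling. The default per-stratum
person-years (2e4) put population totals at the order of magnitude of a
single SEER9 sex-by-race stratum (~1e8 person-years); they are
order-of-magnitude stand-ins, not demographic projections. Case counts
are independent Poisson draws with mean h × PY.

What the generator does *not* emulate: registry coverage changes,
reporting delay, race/ethnicity coding shifts, overdispersion, or any
non-model heterogeneity. Passing recovery tests therefore demonstrate
correctness of the estimation machinery on on-model data, not robustness
of the scientific conclusions to registry artifacts.

## Stochastic oracle

`oracle.simulate_cohort` realizes the model exactly, per subject:
field-defect onset by thinning against the analytic ν_FD (piecewise-
constant yearly majorant × 1.05), clone initiations as a Poisson process,
and exact Gillespie dynamics per clone with integer cell counts
(numba-compiled). Clones initiated after the current earliest
transformation are pruned — they cannot change the first transformation
time. Per-subject RNG streams derive from the root seed by a counter
scheme, so results are independent of execution order. A configurable
clone-size cap (default 1e7) aborts runaway supercritical clones with a
warning; validation regimes use inflated μ₂ / deflated α so the cap is
never reached.

`empirical_hazard` bins events and person-time at risk and attaches exact
(Garwood) Poisson intervals. Comparisons against the analytic curve use
the survival-weighted bin average of h (`analytic_bin_hazard`), which is
the quantity an occurrence/exposure rate estimates; comparing bin rates
to midpoint hazards misstates curved bins.

Oracle validation regimes (three parameter sets in the acceptance suite)
use onset rates ~10³ times realistic values, α of order 1–3/yr and μ₂ of
order 0.01–0.03/yr so that 1e5 subjects yield tens of thousands of events
in seconds while clones stay small. These rates are validation
instruments: they exercise exactly the same code paths as realistic
values, at measurable event counts.

## Study sizes used by the heavier tests

Chosen as the package's own scaled-down designs: MLE recovery on a
1000× person-year table (sampling error on ν₀, g₀ well below the 10%
acceptance band); posterior coverage on a 10× table with 32 walkers ×
3000 steps (~96k retained draws); LR null calibration with 1000
replicates of a 400-stratum constant-onset table at 2e5 person-years per
stratum, with all nuisance parameters held at their generating values
(a simple null, so the 2-df χ² reference is exact up to asymptotics).

## Known limitations

* The exact functional form of the period regularization is a design
  choice (see above); with the published black-male medians the
  cohort-factor exponent is strongly negative for pre-1944 cohorts, so
  computed early-cohort field-defect prevalences are far below the
  published narrative values (the white-male/female values land close).
  Quantities derived from early-cohort trends should be read as
  model-form-dependent.
* The grid likelihood is O(step²) accurate; step 0.25 yr is adequate for
  fitting but not for 1e−8-level reference values — use the quadrature
  surface for those.
* Random-walk MCMC at short chain lengths under-explores the trend
  ridges; use the ensemble sampler for credible intervals.
* No overdispersion: the likelihood is strictly Poisson.
* The three-stage clonal expansion variant and tumor-size-dependent
  detection are out of scope.
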