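# Methods

`ppsdm` implements a spatiotemporal species distribution model of the
predictive-process family for geostatistical survey data, a synthetic
survey generator matched to its assumptions, and the three decision-point
sensitivity experiments built on top (model structure, spatial extent of
the data, prediction resolution).  This note records the model, the
numerical choices, and what the synthetic experiments can and cannot show.

## The model

Catch rate (CPUE, kg/km²) of haul *i* in year *t* at location *s* follows
a Tweedie distribution with log link:

    y_i ~ Tweedie(mu_i, p, phi),   log mu_i = x_i'b + omega(s_i) + eps_t(s_i)

* `x_i'b` — fixed effects: one indicator per year (no global intercept, so
  year effects stay identified against the zero-mean field) and, when the
  model includes depth, standardized depth and its square.  The quadratic
  gives the dome-shaped habitat response typical of demersal fish.
* `omega` — a time-constant Gaussian field with Matérn covariance
  (smoothness ν = 1), the persistent spatial pattern.
* `eps_t` — optional per-year Gaussian fields of the same Matérn family:
  absent, independent across years (IID), or first-order autoregressive
  (AR(1)) with coefficient φ and innovations scaled by √(1−φ²) so the
  marginal variance is the same every year.
* Tweedie power 1 < p < 2 mixes a point mass at zero (empty hauls) with
  continuous positive catches; variance is φ·μ^p.

The Matérn range is parametrized so correlation ≈ 0.1 at distance
`range_km` (decay rate √(8ν)/range), the convention used by the common
SPDE-based software, making reported ranges comparable.

### Dimension reduction: the predictive process

The fields are represented by their values `u` at m knots (k-means
centres of the observation locations, canonical-order, fixed seed) and
projected elsewhere by the conditional expectation
`A = C(targets, knots) C(knots, knots)^-1` (kriging weights).  This is a
covariance-based Gaussian predictive process: same modeling intent as the
triangulated-mesh SPDE approach — a low-dimensional field at knots,
interpolated to data and grid — with a far smaller engineering surface.
It is a deliberate design deviation: no mesh is built, and the knot count
(default 80 for fitting; analyses at desk scale use 30–60) plays the role
of mesh resolution.  Too few knots oversmooth the field; sensitivity to
knot count is part of the test suite rather than a fitted quantity.

The projection omits the conditional (residual) variance of the field
between knots: predictions are the smoothed field, as in standard
predictive-process practice.  The synthetic generator, by contrast, *adds*
independent residuals with the exact conditional variance when drawing
true fields, so simulated fields have the full Matérn marginal variance.

### Estimation

Maximum likelihood by the standard nested (Laplace) scheme:

* **Inner problem** — for fixed (b, θ), Newton iterations maximize the
  penalized log-likelihood Σℓ(y_i; η_i) − ½u'Qu over the knot effects,
  with analytic first/second Tweedie derivatives in η (the μ-dependent
  part of the log-density is closed-form).  Step-halving guards
  non-increase; convergence at max|grad| < 1e−8 or 50 iterations.
  The negated Hessian Q − J'WJ is assembled blockwise by year.
* **Marginal likelihood** — Laplace: ℓ_joint at the mode − ½log|Σ|
  − ½log|Q − J'WJ| (Gaussian-integral constants cancel).  Exact when the
  response is Gaussian — the test suite exploits this with a
  Gaussian-response hook checked against the closed-form marginal.
* **Outer problem** — L-BFGS-B over (b, θ) on unconstrained scales (logs
  for positive parameters, atanh for φ, logit to (1,2) for p) with
  forward-difference gradients (relative step 1e−5) and warm-started inner
  modes.  Two starting points by default (the second perturbs θ); best NLL
  wins.  Structures that depend only on θ are cached across the
  fixed-effect components of the gradient.
* **Standard errors** — central finite-difference Hessian at the optimum;
  delta method maps transformed-scale SEs to natural scale.  A non-PD
  Hessian flags SEs as missing rather than fabricating them.
* The Tweedie series normalizer log a(y; p, φ) is independent of μ and is
  cached per (y, p, φ), so inner iterations only pay for the closed-form
  exponential-family part.

ω and ε share the Matérn range by default (toggle `share_range=False`);
with shared range they also share kriging weights.  The AR(1) joint
precision uses the Kronecker structure (tridiagonal temporal precision ⊗
spatial precision), and log-determinants use the same factorization.

### Tweedie density numerics

For y > 0 the density is the index series in the canonical (θ, κ)
parametrization, summed over a common j-grid extended until every
observation's trailing term is 1e−12 below its own peak (the summand is
unimodal in j).  If the dominating index exceeds 20,000 terms — far
outside the regimes this package targets — a saddlepoint approximation is
used and flagged.  P(y = 0) = exp(−μ^(2−p)/(φ(2−p))) is exact.

### Derived indices and uncertainty

Annual biomass is Σ_g area_g·density_g; COG is the density-weighted mean
Eastings/Northings.  Uncertainty is simulation-based: fixed effects drawn
from N(b̂, Ĉov) and random effects from N(mode, (Q − J'WJ)^-1) jointly,
the statistic recomputed per draw (default 500).  Biomass intervals are
formed on the log scale (positivity, asymmetry); COG intervals on the
natural scale.  A `relative_biomass` mode standardizes each draw's series
to its own maximum before summarizing — the scale on which relative-index
figures are drawn, and one on which uncertainty common to all years
(e.g. the time-constant field's level) cancels.  Cross-covariance between b̂ and the modes is neglected —
the usual plug-in Gaussian approximation.  Draw-based SEs of biomass are
heavy-tailed when the field has prior-level uncertainty somewhere on the
grid; the intervals (log-scale) are the more stable summary.

### Validation

Cross-validation folds are contiguous latitude bands at the pooled 1/k…
(k−1)/k Northings quantiles (ties to the lower band), respecting spatial
autocorrelation.  Each fold's held-out records are scored by their Tweedie
log-density at means predicted from the training fit (spatiotemporal
effects of the matching year projected from trained modes, not
re-estimated); the report is the raw sum over observations and folds.
Randomized-quantile (PIT) residuals simulate replicate datasets at the
conditional means and rank each observation among its replicates, ties —
including the zero atom — broken uniformly; uniformity is summarized by a
Kolmogorov–Smirnov distance.

## The synthetic survey generator

The generator emulates an annual stratified-random bottom-trawl survey on
a long narrow shelf: a rectangular lattice (default 36 × 270 cells of
2.8 × 3.7 km ≈ 100.8 × 999 km), depth from a logistic cross-shore
shelf-break profile spanning ~60–1,270 m with an optional smooth
along-shore meander, stations allocated equally over 5 latitude × 3
depth-tercile strata (empty strata reallocate with a warning), uniform
within stratum, never in protected polygons.  True log-density is the
model's own linear predictor (quadratic depth dome peaking seaward of the
break, plus ω and optional ε); observation noise is Tweedie.

Default parameters are the study conditions: 16 years × 400 stations,
σ_ω = 0.8, Matérn range 40 km, σ_ε = 0.4, φ = 0.3, p = 1.5, dispersion
4.0, intercept 2.2 — the intercept calibrated once so occurrence lands
near 0.65, the rate the reference survey reports; φ and the range sit
inside the reported 0.22–0.41 and 22.83–67.00 km bands.  An optional
linear along-shore trend (`b_north`, default 0) supports gradient-bearing
scenarios.

Field draws use the same knot machinery as the estimator (150 simulation
knots by default) plus independent per-cell residuals at the exact
conditional variance, so marginal variances are exact and cost stays
O(knots²·cells).  Between-cell correlation at lags shorter than the knot
spacing is slightly underrepresented; the Monte-Carlo covariance test
bounds this against the closed-form Matérn.

What the generator does *not* emulate: vessel/gear catchability, seasonal
timing, real bathymetry, haul-level area swept variation, and
measurement error in depth.  Passing tests therefore demonstrate the
method's internal correctness and the qualitative decision-point
phenomena, not performance on the real survey.

## The three experiments

* **Structure** — four candidate models (depth in/out × spatiotemporal
  none/IID/AR(1)) ranked by 5-fold latitude-blocked CV log-density; best
  and worst refit on all data and compared on biomass/COG.  On data
  generated under the spatial-only depth model, that model should win the
  ranking; with no depth signal, models with and without depth should be
  indistinguishable.
* **Extent** — symmetric latitude-quantile filtering (total fractions up
  to 20%, split evenly north/south, boundary ties retained), refit with
  the knot layout *fixed on the full survey* (the analog of keeping the
  mesh fixed), prediction to the full grid.  Where data were removed the
  field's posterior reverts toward its prior, so COG and biomass
  uncertainty grow with the filtered fraction.  The acceptance scenario
  carries its density gradient through bathymetry (the shelf break
  migrates offshore toward the north, truncating deep habitat there)
  rather than a linear log-density trend: a domain-wide trend is absorbed
  by ω and shifts its variance estimate between refits, confounding the
  precision comparison that is the point of the experiment.
* **Resolution** — one fit predicted to the native grid and to 2–4×
  block-coarsened grids (centroid = member mean, depth = area-weighted
  mean, area = sum; a coarse cell is masked only if all members are;
  incomplete edge blocks dropped).  Per-block log-ratios of aggregated
  fine density to the coarse prediction concentrate where depth varies
  within blocks — blocks straddling the ~200 m shelf break — because
  averaging depth across the drop-off misplaces the quadratic response.
  Factor-1 coarsening is an exact identity; with depth constant within
  every block and no field curvature the log-ratios vanish.

Every experiment is reproducible from (inputs, seed): all randomness
flows through explicitly seeded generators.

## Problem sizes

Desk-scale defaults used by the analyses and tests: fitting knot counts
30–60 (80 is the package default), surveys of 1,000–2,500 hauls, grids of
~1,500–9,700 cells, 150–500 uncertainty draws, replicate batteries of
10–20 seeds.  These sizes keep a full analysis on one CPU in minutes
while leaving the phenomena of interest comfortably detectable.

## Known limitations

* The predictive process omits between-knot conditional variance in
  predictions (standard practice, but densities between knots are
  oversmoothed when knots are sparse).
* Finite-difference outer derivatives: gradients cost (dim+1) likelihood
  evaluations; with ~20 outer parameters and spatiotemporal fields a fit
  is seconds-to-a-minute, not milliseconds.
* The Laplace approximation is unverified for Tweedie responses beyond
  the consistency checks in the suite (exactness holds only for the
  Gaussian hook); no importance-sampling correction is provided.
* ω and a systematic spatial trend in the truth are confounded at the
  scale of the domain; variance parameters then differ between refits on
  different spatial subsets (this is a property of the model class, and
  it is why the extent experiment uses a habitat-borne gradient).
* No bias correction is applied to the derived indices (out of scope).
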