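# Methods

This note documents the models behind `tnzsize`, the defaults of the
synthetic-data generator, and the numerical and design choices made where the
problem left the design open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The generative model (`synthetic`)

The generator emulates a two-scale rodent monitoring study: a spatial
transect of `n_sites` sites (default 9) sampled in the last two configured
years, and a temporal series across all configured years (default
2016–2023).

**Sites and climate.**  Longitude, altitude and latitude are uniform in
their configured ranges (defaults span ~3° E, 0.30–1.45 km, a subtropical
mountain setting).  The annual mean daily-minimum temperature of site *s* in
year *t* is

    AnnMinTemp(s, t) = a + b_lon·lon_s + b_alt·alt_s + b_yr·(t − t0) + ε_s,

with defaults a = −79.8 °C, b_lon = 0.89 °C °E⁻¹, b_alt = −2.32 °C km⁻¹,
b_yr = 0.26 °C yr⁻¹ and site noise ε_s ~ N(0, 0.3²).  The slope magnitudes
mirror what regional studies of this kind report, and they are the recovery
targets of the trend-model tests.  Daily minima are a single annual sinusoid
(amplitude 8 °C, coldest mid-January) plus N(0, 2²) day-to-day noise,
re-centred exactly onto the target annual mean — downstream analyses consume
only the annual mean, so richer weather structure would add nothing
testable.  Interannual variability beyond the linear trend is deliberately
absent; the year-trend fits on synthetic data are therefore exact.

**Individuals.**  Each site-year contributes `n_per_site_year` records.
Sex is Bernoulli(½); stage is drawn from a five-class distribution
(juvenile 0.08, sub-adult 0.27, adult I 0.30, adult II 0.25, old 0.10) so the
exclusion filters always have work to do.  Body length is gamma with shape
300 (CV ≈ 5.8 %) and mean

    μ_len = 88 + 0.99·AnnMinTemp + 2·[male] + stage offset + u_site + v_year,

u_site ~ N(0, 0.8²), v_year ~ N(0, 0.4²) (mm).  An optional
`length_tnzb_slope` adds a true TNZ-breadth → length effect for SEM power
experiments (default 0: the world of "pathway 1").  Body mass follows the
analogous model (intercept 14 g, slope 0.44 g °C⁻¹, shape 300) but each draw
is rejected into the assigned stage's mass band, so stage classification
round-trips exactly.  The truncation slightly attenuates the realised
mass–temperature slope relative to the nominal 0.44; quantitative
slope-recovery tests therefore use body length.  Pregnancy flags females
(non-juvenile) with probability 0.15.

**TNZ and respirometry.**  Site TNZ limits are linear in the site's spatial
AnnMinTemp: LLT = 27.6 + 0.15·T, ULT = 33.9 − 0.19·T (so breadth narrows by
0.34 °C per +1 °C), plus independent N(0, 0.15²) site-level deviations
(`tnz_site_sd`) representing real population heterogeneity — without it the
breadth would be an exact linear function of temperature and every
conditional-independence test downstream would be degenerate.  Mass-specific
RMR follows the piecewise-linear Scholander form: slope −0.12 below the LLT,
flat at BMR = 1.8 mL O₂ g⁻¹ h⁻¹ inside the zone, slope +0.20 above the ULT.
These give ≈ 2.6 × BMR at 5 °C and a warm limb steeper than the cold one,
both physiologically plausible for a ~30 g murid.  Each of `n_rmr_animals`
(default 6) animals per site is measured for 10 one-minute readings at each
chamber temperature on the schedule {37.5, 35, 32.5, 30, 27.5, 25, 20, 15,
10, 5} °C, with N(0, (0.05·mass)²) reading noise.  Ten minutes gives the
5-minute minimum-window search room to act; trace length is configurable.

**Reproducibility.**  All draws come from labelled child streams
(`SeedSequence(seed, spawn_key=crc32(label))`) of one root seed, so an
identical configuration yields bitwise-identical outputs and adding a new
stage never perturbs existing draws.

## 2. TNZ estimation (`metabolic`)

Temperature-specific RMR is the minimum over all contiguous 5-minute windows
of the window mean ("minimal consumption over at least 5 minutes" — the
minimum over longer windows can never be smaller, so 5 is the operative
length).  Points are pooled across a site's animals and one curve is fitted
per population: populations, not individuals, carry one LLT/ULT in this
design, and pooling is far more stable at ~6 animals per site.

The curve is a degree-4 polynomial by default (configurable 2–6): a
quadratic cannot represent a flat-bottomed zone with asymmetric limbs, and
degrees above 4 buy no recovery accuracy on a 10-temperature schedule while
amplifying derivative wiggle.  Fitting is linear least squares solved by
gradient descent: the temperature axis is centred and scaled to unit
variance, the monomial columns are norm-scaled, and heavy-ball iterations
use the optimal step/momentum from the extreme eigenvalues of the normal
matrix.  Convergence is declared when the gradient's infinity norm falls
below `tol` (default 1e-12); coefficients are composed back to the °C scale.
The acceptance suite checks agreement with the closed-form solution to
≤ 1e-6 in fitted values.

Limits come from the fitted derivative: `t_min` is the interior argmin
(grid scan seeded, refined by polynomial root finding, well below the
10⁻⁴ °C target); LLT/ULT are the nearest derivative crossings of ∓δ below/
above `t_min`.  The threshold default is δ = 0.03 mL O₂ g⁻¹ h⁻¹ °C⁻¹,
chosen once so that noiseless recovery of known limits succeeds on the
default measurement schedule (with δ = 0.02 the smoothed quartic's warm limb
crosses too close to the minimum and the ULT lands > 1 °C low).  If a limb
never reaches ±δ inside the fitted domain the estimate is clipped to the
domain edge and flagged (`boundary_clipped`).

**Known limitation — breadth attenuation.**  The polynomial smooths the
piecewise-linear kinks over roughly the inter-point spacing, so estimated
limits track the true limits with slopes well below 1 (about 0.3 for LLT and
0.5 for ULT on the default schedule) and the estimated *breadth* contrast
between populations is compressed much further.  Mean limits are recovered
to ≲ 0.4 °C, but a cross-population TNZ_b gradient passes through the
estimator strongly attenuated.  Quantitative recovery tests of the
TNZ-effect models therefore feed the models ground-truth site TNZ values;
what passing tests show about real data is that the *models* are correct,
not that this curve-plus-threshold estimator preserves breadth gradients.

## 3. Climate aggregation and linear models (`climate`)

AnnMinTemp is the calendar-year (Jan–Dec) mean of daily minima, guarded by a
completeness threshold of 300 days per site-year (configurable) so that a
patchy year cannot silently bias the mean.  The spatial site value is the
mean of the two configured spatial years.  Trend and effect models are
ordinary least squares with the textbook slope t test; effect-model slopes
are emitted on both the natural (per °C) and standardised-predictor scales,
since either convention may be wanted when comparing against field reports.

## 4. Gamma identity-link GLMM (`body_size`)

Body sizes are positive and right-skewed; the gamma family with an identity
link keeps coefficients on interpretable mm/g scales.  Stage bands are
[0,16) juvenile, [16,23] sub-adult, (23,29] adult I, (29,37] adult II,
(37,∞) old; the published adult-I band nominally starts at 16 g, overlapping
sub-adult — the overlap is treated as a typographical slip and (16,23] is
assigned to sub-adult by default, with `ambiguous_band="adult I"` honouring
the literal reading.  Juvenile, old and pregnant records are excluded before
modelling, with per-reason counts logged.

Estimation: the joint penalised log-likelihood in (β, b) is maximised by
Fisher-scoring Newton steps with a monotone, positivity-preserving line
search (identity-link means must stay positive; step halving enforces both).
The marginal likelihood is the Laplace approximation at the joint mode
(validated against adaptive quadrature during development).  The two
variance-type parameters (gamma shape ν, random-intercept SD σ) maximise by
default the criterion with the *fixed effects integrated out as well*
(joint Laplace over β and b — the REML analogue, as in glmmTMB's REML
option): with only ~9 groups, plain ML biases σ down and the slope's
±2 SE interval under-covers; `method="ml"` restores ordinary Laplace ML.
`force_zero_variance=True` profiles σ at exactly 0, reproducing the plain
gamma GLM — the equivalence to the statsmodels IRLS fit is an acceptance
check.  Fixed-effect covariance is the β-block of the inverse joint
information at the mode.

Internally the response is divided by its mean and non-constant design
columns are standardised, so all optimiser parameters are O(1); estimates
and SEs are mapped back exactly (the gamma shape is scale-invariant).  Wald
p-values use a between-within t reference in the style of nlme: a
coefficient whose column is constant within every group is judged against
t with (G − q) df, where q counts the group-constant columns; other
coefficients effectively against a normal.  With few groups this is the
difference between a usable and a misleading test of a site-level predictor.

Dummy coding: sex reference female, stage reference sub-adult — the choice
only moves the intercept.  Predictors are standardised before fitting and
slopes are reported on both scales (an exact reparameterisation under the
identity link).

## 5. Piecewise SEM (`sem`)

The causal graph contains AnnMinTemp, TNZ_b and body length, plus the
exogenous sex and stage effects on length that the length component model
carries.  Pathway 1 has only AnnMinTemp → {length, TNZ_b}; pathway 2 adds
TNZ_b → length; pathway 3 instead a TNZ_b ↔ length correlated error.

* **Basis set.**  One claim per non-adjacent pair (edges and correlated
  errors make pairs adjacent; pairs of two parentless variables are not
  modelled), conditioned on the union of the pair's parents — Shipley's
  construction.  Every emitted claim is verified against a brute-force
  d-separation oracle over all DAGs on ≤ 5 ordered nodes in the acceptance
  suite.  With the sex/stage covariates in the graph, pathway 1 yields three
  claims (df = 6) and pathways 2–3 two each (df = 4); because those two
  claims live entirely in the TNZ_b component model, pathways 2 and 3 share
  the same Fisher's C — the structure that makes the pathway comparison
  informative.
* **Claim testing.**  A claim is tested by adding the putatively independent
  variable to the component model of the claim's "response" (the pair member
  with the larger parent set): individual-level variables into the length
  GLMM (Wald t), site-level claims into the site-level TNZ_b OLS.  Sex and
  stage aggregate to site shares there; the multi-column stage claim uses a
  nested-model F test so each claim contributes a single p-value.
* **Fisher's C and AIC.**  C = −2 Σ ln p ~ χ²(2k) under the graph;
  AIC = C + 2K with K the total parameter count of the component models
  (coefficients, gamma shape, random-intercept variance, OLS residual
  variance).  The pathway-3 residual correlation is a post-hoc statistic
  computed from site-mean marginal length residuals against the TNZ model
  residuals (Pearson r, t test with G − 2 df) and is *not* counted in K —
  this matches the published information-criterion arithmetic for such
  systems and the behaviour of the piecewiseSEM package.
* **Standardised estimates** are slope · SD(x)/SD(y) on the observation
  scale of the component model (site scale for the TNZ_b model).

## 6. Calibration experiments and problem sizes

The suite's stochastic claims run at sizes chosen to make the reference
distributions meaningful while staying desk-scale:

* TNZ recovery: 200 population estimates at reading noise SD 0.05.
* GLMM slope coverage: 100 replicates of ~2000 generated records over
  9 sites (the study's spatial geometry); coverage of the true slope by
  ±2 SE.
* Wald type-I error: 500 null replicates over 40 sites.  With 9 sites a
  site-level slope has ~7 denominator df and no z-type test can sit at
  5 % ± 2 %; 40 groups is the smallest geometry where the t reference is
  honest.
* Fisher's C type-I error: 500 replicates over 80 sites.  At 40 sites the C
  test still rejects ~7 % because the Laplace/REML Wald SE of a group-level
  predictor ignores variance-parameter uncertainty (a ~1/G effect); at 80
  sites a distributional check (claim p-values uniform by KS, mutually
  uncorrelated; C matching the χ²₆ mean and variance) shows the reference
  distribution applies.  This small-group anti-conservatism is a known
  property of Wald tests in mixed models, inherited by piecewise SEM.

## 7. Degenerate inputs and error policy

Non-positive responses, constant predictors to be standardised, fewer than
two random-effect groups, traces shorter than the extraction window,
monotone fitted RMR curves (no interior minimum), cyclic pathway graphs and
zero claim p-values all raise typed errors (`tnzsize.errors`).  Sites with
too few distinct chamber temperatures are skipped with a logged reason
rather than failing a whole run; non-converged fits are returned flagged,
never silently.
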