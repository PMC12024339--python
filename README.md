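# tnzsize

Ecophysiological analysis of how rodent body size tracks ambient temperature,
and how the response is shaped by each population's **thermoneutral zone**
(TNZ) — the ambient-temperature range in which an endotherm spends no extra
energy on thermoregulation.

Classical Bergmann reasoning predicts larger bodies in colder climates, but
many rodent populations do the opposite: they grow larger where (and when) it
is warmer, and populations with narrow TNZs respond differently from
populations with broad ones.  `tnzsize` implements the full analysis chain
needed to study this at the population level, plus a synthetic-data generator
with known ground truth so every stage can be validated by parameter
recovery:

1. **Respirometry → TNZ** (`tnzsize.metabolic`).  Minute-resolution oxygen
   consumption traces are reduced to temperature-specific resting metabolic
   rate (the minimal 5-minute window mean), converted to mass-specific units
   (mL O₂ g⁻¹ h⁻¹), and pooled per population.  A degree-*d* polynomial
   RMR(T) is fitted by gradient descent (heavy-ball iterations on a
   standardised temperature axis; the result matches closed-form least
   squares to numerical precision).  The lower and upper limit temperatures
   are the derivative-threshold crossings around the curve minimum:
   LLT = max{T < T_min : RMR′(T) = −δ}, ULT = min{T > T_min : RMR′(T) = +δ},
   and TNZ breadth is TNZ_b = ULT − LLT.
2. **Climate** (`tnzsize.climate`).  AnnMinTemp — the annual mean of daily
   minimum temperature per site and year — plus OLS trend models
   (AnnMinTemp ~ latitude/longitude/altitude/year) and effect models
   (ULT/LLT/TNZ_b ~ AnnMinTemp), reported on natural and standardised scales.
3. **Body size** (`tnzsize.body_size`).  Stage classification from body-mass
   bands, exclusion filters (juvenile, old, pregnant), and gamma GLMMs with
   an *identity* link:

       y_i ~ Gamma(shape ν, mean μ_i),   μ_i = α + β·x_i + Sex_i + Stage_i + u_g(i),
       u_g ~ N(0, σ²)

   fitted by a Laplace approximation (REML-flavoured variance estimation;
   `GammaGLMM` is a scikit-learn style estimator).  Slopes keep their
   field units (mm or g per °C).
4. **Piecewise SEM** (`tnzsize.sem`).  Three causal pathways linking
   AnnMinTemp, TNZ_b and body length are fitted piecewise, their d-separation
   claims tested, and the models compared by Fisher's C = −2 Σ ln p
   (χ² with 2k df) and AIC = C + 2K.

A thin `tnzsize` command line (`simulate`, `tnz`, `trends`, `size-models`,
`sem`, `all`, `report`) chains the stages over CSV files with provenance
stamping and a run manifest.

## Worked example

```python
import tnzsize as tz

cfg = tz.RunConfig(synthetic=tz.SyntheticConfig(n_per_site_year=8,
                                                n_rmr_animals=4, seed=1))
tz.run_all(cfg, "demo_out")
print(tz.report("demo_out"))
```

The TNZ table gives one estimate per population (true limits here vary
around LLT ≈ 29.2, ULT ≈ 31.5 °C):

```
== tnz (tnz_estimates.csv, 9 rows) ==
site  llt_C  ult_C  tnz_b_C   bmr  t_min_C  converged  boundary_clipped  n_animals
 S01  29.32   31.2    1.885 1.932    30.33       True             False          4
 S02  29.14  31.12    1.975 1.914     30.2       True             False          4
 ...
```

`llt_C`/`ult_C` are the derivative-threshold limits, `bmr` the curve minimum
(basal metabolic rate, mL O₂ g⁻¹ h⁻¹).  The body-size battery recovers the
generating temperature–length slope (0.99 mm °C⁻¹ here) within its
uncertainty, on both temporal and spatial gradients:

```
 dataset response    predictor   slope      se         p
temporal   length ann_min_temp   1.453  0.2771 2.494e-07
 spatial   length ann_min_temp   1.607  0.6824   0.05074
```

and the SEM stage ranks the three pathways by AIC = Fisher's C + 2K:

```
 pathway  fisher_c  df     c_p  K   aic  rank
pathway3     11.96   4 0.01765 10 31.96     1
pathway1     12.25   6 0.05662 10 32.25     2
pathway2     11.96   4 0.01765 11 33.96     3
```

(`pathway1`: only direct AnnMinTemp effects on length and TNZ_b;
`pathway2`: adds TNZ_b → length; `pathway3`: adds a TNZ_b ↔ length residual
correlation instead.)

## Layout

```
src/tnzsize/
  config.py      # SyntheticConfig / RunConfig, labelled child RNG streams
  synthetic.py   # sites, daily climate, capture records, RMR traces + truth
  metabolic.py   # min-window RMR, gradient-descent curve fit, TNZ limits
  climate.py     # AnnMinTemp aggregation, trend and effect linear models
  body_size.py   # stage filters, GammaGLMM, model battery
  sem.py         # pathways, d-separation basis, Fisher's C, AIC ranking
  pipeline.py    # stage orchestration, provenance, report
  cli.py         # click command line
docs/methods.md  # modelling assumptions, defaults, numerical choices
```
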