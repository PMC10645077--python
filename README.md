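# paleodyn

Radiocarbon summed-probability palaeodemography and competition–cooperation
population-dynamics modelling.

`paleodyn` is for archaeologists and quantitative ecologists who want to go
from a radiocarbon date list to a tested population-dynamic inference: it
builds summed probability distributions (SPDs) of calibrated ¹⁴C dates as a
relative population proxy, couples them with palaeo-proxy covariates
(hydroclimate, warfare, social upscaling), fits a family of Ricker-type
growth models to generation-scale growth rates, ranks the candidates by AICc
with Akaike weights, and validates each fit by simulating the whole
trajectory from its first observed value.

## The model

With `x_t` the population proxy at generation `t` (25 yr), `X_t = ln x_t` and
`R_t = X_{t+1} − X_t`, the full model is

```
R_t = R_m − (c + α₀·z_t + α₁·z′_t)·e^{X_t} − (w + β₀·z″_t + β₁·z′_t)·e^{−X_t}
```

* `R_m` — logarithmic maximum reproductive rate (intercept of the R–X curve);
* `c` — intensity of intra-population competition (Ricker density dependence);
* `w` — intensity of cooperation: an Allee-like penalty `w·e^{−X}` measuring
  the numbers needed to overcome environmental hazards;
* `z, z′, z″` — hydroclimate (lithic %), warfare and social-upscaling
  (palaeopollution) covariates; `α` and `β` couple them to `c` and `w`.

Candidate structures A (endogenous only), B (+ hydroclimate and warfare on
`c`), C (+ social upscaling on `w`) and D (+ warfare on `w`) are nested; the
model is linear in its parameters given the data, so fits are exact
least-squares solutions, compared by AICc (`K = n_params + 1`), Akaike
weights and per-predictor relative importance. Trajectory validation scores
`σ² = 1 − SSE/SST` (coefficient of prediction) on total simulated paths.

## Worked example

Fit all four candidates to a synthetic generation table with known truth
(`R_m=0.9, c=0.035, w=1.2, α₀=0.08, α₁=0.05, β₀=1.2, β₁=−4.2`, growth noise
sd 0.073):

```python
from paleodyn.synthetic import simulate_generation_table
from paleodyn.models import fit_all_models

table = simulate_generation_table(seed=1, noise_sd=0.073)
comp = fit_all_models(table, score_trajectories=True)
print(comp.summary())
```

```
model     R_m         c       w    alpha0    alpha1    beta0    beta1      rss     AICc   dAICc         w_i    sigma2
    D  0.8117 0.0281422 1.51446 0.0763924 0.0588831 0.748268 -5.03659 0.202052 -129.318       0    0.999971  0.965905
    C 1.66653 0.0858939 3.20553  0.070626 0.0197574  1.38337        0 0.317897  -107.61 21.7076 1.93304e-05  0.952288
    B 1.58941 0.0859395 3.47887 0.0651014 0.0201844        0        0 0.342335 -106.259 23.0595 9.83307e-06  0.950385
    A 1.65392  0.117393 4.62915         0         0        0        0  1.95722 -17.0811 112.237 4.24659e-25 0.0661357

relative importance: lithic=1.000, warfare=1.000, pollution=1.000
```

The generating model D is selected with weight ≈ 1, its parameters are
recovered near their true values, and iterating the fitted model from the
first observation alone reproduces the trajectory with σ² = 0.97 (1 would be
a perfect prediction, 0 no better than the observed mean).

The same analysis runs from the shell on CSV inputs:

```
paleodyn synth --out bundle --seed 1          # synthetic input bundle
paleodyn run --dates bundle/dates.csv --curve bundle/curve.14c \
    --lithic bundle/lithic.csv --warfare bundle/warfare.csv \
    --pollution bundle/pollution.csv --out report
```

which writes both SPD normalisation variants, the generation tables, an
eight-row fit table (A1–D1 unnormalised, A2–D2 normalised) and a JSON report.
Real inputs use the same formats: P3K14C-compatible date CSVs
(`LabID,Age,Error,SiteID,Material`), standard `.14c` calibration curves
(e.g. SHCal20), annual proxy CSVs (`year_ad,value`) and period-score CSVs
(`period_start,period_end,score`); pass a covariate flag twice to min–max
merge two source series.

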