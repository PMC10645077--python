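# Methods

## Pipeline overview

The analysis runs in five stages:

1. **Calibration.** Each radiocarbon determination `a ± σ` is calibrated on an
   annual calendar grid: the probability mass at calendar year θ is the
   Gaussian ordinate `N(a; μ(θ), sqrt(σ² + σ_curve(θ)²))` with `(μ, σ_curve)`
   linearly interpolated from the calibration-curve knots. Support is trimmed
   where the cumulative mass per tail falls below 1e-5 (before any
   rescaling); a *normalised* density is then rescaled to unit mass, an
   *unnormalised* one keeps the raw ordinates. Internally everything runs in
   cal BP (= 1950 − AD); all I/O is in years AD.
2. **Binning and SPD.** Within each site, dates are clustered on their
   uncalibrated ages by complete-linkage hierarchical clustering, tree cut at
   50 yr (the convention of rcarbon's `binPrep`); each bin contributes the
   arithmetic mean of its members' calibrated densities, bins are summed, and
   a 100-yr centred rolling mean is applied. The sum is evaluated on a grid
   padded by the rolling half-width beyond the analysis window (AD 100–1450
   by default) and truncated back afterwards, so smoothing never manufactures
   mass inside the window; at hard grid ends the window shrinks symmetrically.
   Both normalisation variants are produced, as a robustness pair against
   calibration-slope artefacts.
3. **Covariates.** The warfare index starts from period-level trauma scores:
   each score sits at its period midpoint and is linearly interpolated to an
   annual grid (held constant beyond the outermost midpoints). Paired source
   series (two enrichment-factor records, two trauma records) are min–max
   normalised to [0, 1] and averaged on the union of their grids. Every
   covariate is then smoothed by a cubic smoothing spline — `spar` 0.65
   (lithic), 0.45 (palaeopollution), 0.70 (warfare) — reflecting each
   record's native resolution.
4. **Generation table.** The SPD and the smoothed covariates are point-sampled
   every 25 years (one human generation): `x_t`, `X_t = ln x_t`,
   `R_t = X_{t+1} − X_t`, and covariates "in t", i.e. at the start of the
   interval that `R_t` spans. The default window gives 55 rows and 54 growth
   rates. The SPD itself receives only the rolling mean, not a spline
   (configurable).
5. **Fitting, selection, validation.** See below.

## The growth model and its fitting

`R_t = R_m − (c + α₀z + α₁z′)·e^X − (w + β₀z″ + β₁z′)·e^{−X}` combines Ricker
competition (`c·e^X`: per-capita growth falls as numbers rise against fixed
resources) with an Allee-like cooperation term (`w·e^{−X}`: hazards that
require numbers to overcome penalise small populations). The four candidates
are nested: A endogenous, B adds hydroclimate and warfare on `c`, C adds
social upscaling on `w`, D adds warfare on `w`.

The predictor is linear in `(R_m, c, α₀, α₁, w, β₀, β₁)` given the data, so
the least-squares problem is solved exactly by OLS on the regressor set
`{1, e^X, z·e^X, z′·e^X, e^{−X}, z″·e^{−X}, z′·e^{−X}}` (restricted per
candidate). An iterative nonlinear-least-squares mode (`method="nls"`)
reaches the same optimum and exists only for parity with `nls`-style
workflows; the linear solve has no starting-value or convergence ambiguity.
Rank-deficient designs raise a collinearity error naming the offending terms.

AICc uses the full Gaussian log-likelihood with the residual variance counted
as a parameter (`K = n_params + 1`):

```
AICc = n·[ln(2π·RSS/n) + 1] + 2K + 2K(K+1)/(n − K − 1)
```

Constants cancel in ΔAICc and weights; they matter only for comparing
absolute AICc values across software. Akaike weights are computed within a
comparison set of fits to the *same* table (the two normalisation variants
are never pooled); ties rank by fewer parameters, then name. Relative
importance of a predictor is the sum of weights over models containing it.

Validation iterates the fitted map from the first observed value only —
`X̂_{t+1} = X̂_t + R(θ̂, X̂_t, covariates_t)` — and scores
`σ² = 1 − Σ(X̂−X)²/Σ(X̄−X)²`. σ² is computed on the log scale by default
because fitting is on log-transformed series; a raw-scale option exists. A
trajectory whose |X̂| exceeds 40 is reported as a divergence (collapse or
runaway) with its step index.

## Synthetic study conditions

The generators provide known-truth inputs for every stage:

* **Covariates** are annual Gaussian random walks, spline-smoothed
  (smoothness 0.75 lithic, 0.70 conflict, 0.60 pollution — multi-century
  swings, like centennial hydroclimate anomalies) and min–max normalised.
* **Truth trajectories** iterate the full model with Gaussian growth noise
  (default sd 0.01 per generation). Default parameters
  `R_m=0.9, c=0.035, w=1.2, α₀=0.08, α₁=0.05, β₀=1.2, β₁=−4.2`, `x₀=20` were
  fixed once, by a design analysis rather than convenience: the proxy must
  oscillate around the balance point `sqrt(w/c) ≈ 6` with deep (≈5–10×)
  boom-bust phases, else `{1, e^X, e^{−X}}` are nearly collinear and the
  cooperation-side couplings are unidentifiable; the warfare–cooperation
  coupling is strongly negative because that is both the term that separates
  model D from C and the dynamically safe direction (it boosts growth in
  busts rather than deepening them), while `w + β₀` is kept moderate because
  it drives collapse at the adverse-covariate corner. At these values the
  noise-free map showed no divergence over 300 covariate seeds; stochastic
  replicates that do collapse count as failures in every experiment.
  `R_m = 0.9` per 25-yr generation (≈3.7 %/yr ceiling) is at the high end of
  agrarian boom rates; realised growth stays well below it.
* **Radiocarbon dates** sample calendar years with probability proportional
  to the (annually interpolated) truth population — the "ages as data"
  premise run forward — map them through a toy calibration curve (identity
  plus a sinusoidal wiggle, so calibrated densities are realistically
  multimodal) and perturb by lab error (default 30 ¹⁴C yr, 400 dates across
  200 sites, matching the ~2 dates/site density of regional compilations).
  Truth and dates extend 150 yr beyond the analysis window: sampling only
  inside the window depresses the SPD near its edges by up to half.
* The generation-scale residual noise sd 0.073 used in the model-selection
  experiment is the residual scale implied by the best reported fit of this
  kind (inverting the AICc formula at n = 54, K = 8).

What the generators deliberately do not emulate: taphonomic loss, spatially
structured site placement, research-intensity bias in date submission, and
marine/mixed-curve calibration. Passing tests therefore demonstrate the
statistical machinery, not robustness to those real-data pathologies.

## What the radiocarbon loop can and cannot recover

Direct fits to truth generation tables recover all seven parameters with
Monte-Carlo relative bias under 5 % (noise 0.01, n = 54) and select the
generating model in ≈90 % of replicates at noise 0.073. The full radiocarbon
loop (truth → 400 dates → SPD → fit) is different in kind: at realistic date
densities the SPD carries log-scale sampling noise of ~0.2–0.3, comparable to
the largest dynamically safe trajectory amplitude, and the calibration smear
plus the 100-yr rolling mean average in *x*-space, which preferentially fills
the population busts — exactly where the cooperation-side (`e^{−X}`) signal
lives. Consequently end-to-end recovery of the generating structure's rank
and of all parameter signs is not reliably achievable (top-rank rate ≈30 %,
joint sign recovery <10 %, improving only weakly even at ten times the date
density), and fitted endogenous baselines on SPD-reconstructed series can
take theory-inverted signs. The acceptance suite reports these rates as
measured; analyses of real SPD series should read fitted `c` and `w` on the
reconstructed scale, not as estimates of latent demographic parameters.

## Numerical choices

* **Spline `spar` mapping.** The smoother minimises
  `Σ(y−f)² + λ∫f″²` over natural cubic splines with knots at all points, on
  an abscissa rescaled to [0, 1], with `λ = r·256^(3·spar−1)` and `r` the
  design/penalty trace ratio. In the value basis used here the design trace
  is `n` and the penalty trace is `tr(K)` of the Green–Silverman matrix;
  standard statistical software computes `r` from a B-spline basis instead,
  so identical `spar` values are comparable but not bit-identical across
  implementations. The production solve is `scipy`'s O(n) banded smoothing
  spline; a dense `(I+λK)⁻¹y` solve serves as the independent cross-check.
* **Tie-breaks and determinism.** Bins sort by site then cluster label;
  selection ties break by parameter count then model name; all random
  generation flows through explicit seeds (sub-seeds spawned per stage), so
  pipeline reruns are bitwise reproducible.
* **Degenerate inputs.** Constant series cannot be min–max normalised;
  constant observations have no defined σ²; AICc requires `n > K + 1`;
  non-positive SPD samples name the offending year; dates outside curve
  coverage raise a coverage error rather than returning zero mass.
* **Edge behaviour.** Calibrated-density tails are trimmed at 1e-5 cumulative
  mass per side before normalisation, bounding each date's support; the
  rolling mean pads beyond the window before truncation (mass can be lost at
  the window edge, never created).

## Known limitations

* The growth model treats covariate couplings as linear in the covariates and
  ignores age structure, migration and spatial heterogeneity.
* σ² on total simulated trajectories is sensitive to early errors compounding
  along the path; it is a stringent, not a forgiving, score.
* Absolute AICc values depend on the likelihood-constant convention; only
  differences and weights are convention-free.
* The warfare record enters as period-level scores interpolated to annual
  scale; sub-period timing of conflict is unknowable from such data.
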