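# Methods

This note documents the statistical models implemented in `featureshy`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Occurrence model

Nearest distances from locations to a feature class are reduced to cumulative
counts `y_i` (locations within bin edge `i`) out of `n` total locations, with
bin widths of 10–100 m (default 10 m). Each bin's occurrence probability has
a binomial likelihood with a flat Beta(1, 1) prior, so the posterior is
Beta(y_i + 1, n − y_i + 1) and is sampled directly. A logit-scale
random-walk Metropolis sampler (`binomial_posterior_mcmc`, thinned to ~1e4
retained draws from under 1e5 iterations) provides an independent route and
is checked against the conjugate form in the tests (KS < 0.02).

Bins are modelled independently even though cumulative counts are dependent
across bins. This is a deliberate simplification inherited from the method
being implemented; its practical consequence is that per-bin uncertainty is
correct marginally but joint statements across bins are approximate.

Animal and random curves share identical bin edges (required by the
difference step); the default upper edge is the maximum distance observed in
either sample.

## Threshold algorithm

With paired posterior draws, Δ_k = π_R,k − π_G,k per bin, q_k = P(Δ_k > 0),
and p_k = 1 − 2|q_k − ½| (maximal when the difference posterior straddles
zero evenly; zero when it is decisively one-sided).

**Crossover.** The crossover is where formerly separated curves converge.
Separation in a bin is declared when every paired draw is positive (q_k = 1
at the Monte Carlo resolution, hence p_k = 0); this deliberately strong
criterion keeps the false-detection rate under the null far below the per-bin
HDI error rate, which matters because the ~50 bins are strongly dependent.
After the first separated bin, the primary crossover is the first descending
sign change of the posterior-median difference. If per-bin HDIs begin to
overlap zero at a shorter distance than the median crossing, that shorter
bin is used instead — the conservative rule, which by construction never
returns a longer distance than the unambiguous rule. With no separated bin
anywhere the threshold is reported as undetected.

**Posterior of T.** Over bins within ±500 m of the crossover (window
truncated at the data and renormalised), T is distributed over bin centres
with mass ∝ p_k, plus uniform within-bin jitter; the point summary is the
median with a 95% HDI, and the weighted mean Σ d_k p_k / Σ p_k is also
reported. The construction of T's posterior from the p_k weights is a
documented design choice: it reproduces the weighted-average point estimate
and yields median/HDI summaries. A threshold is flagged *not detected* when
no crossover is found, when all window weights vanish, or when the lower HDI
bound of T comes within one bin width of zero ("overlaps or closely
approaches 0"; the tolerance is configurable).

**Hypothesis classification.** No detected thresholds supports proportional
use (H1). With detections, pairwise overlap of the T credible intervals
separates egalitarian (H2: all overlap) from selective avoidance (H3: some
pair disjoint, or some features detected and others not). The
"rather be elsewhere" prediction (H4) is assessed with the colocation model
below.

### When the threshold is identified

For any purely distance-thinned point process (hard or smooth suppression of
an otherwise uniform field) the true cumulative curves satisfy
π_R(d) − π_G(d) = F_R(T)·(1 − π_G(d)) ≥ 0: the curves converge only where
the landscape's distance-to-feature distribution saturates. The convergence
distance therefore identifies the true threshold only when availability
saturates shortly beyond it — dense-feature regimes such as section-line
fencing, where nearly every point lies within a few hundred meters of a
fence. The reference synthetic landscape is designed in exactly that regime
(grid spacing 1100 m, so saturation at 550 m, with a hard 500 m threshold);
there the estimator lands within ±50 m of truth. In sparse-feature regimes
the method reports where the curves become statistically indistinguishable,
which can be far beyond the behavioural threshold; treat estimates for
features whose availability distances extend well past the apparent
threshold as upper bounds. This is a property of the method itself, not of
the implementation.

## Synthetic landscapes

`LandscapeConfig` describes a rectangular study area (reference: 5 × 5 km)
with point features (wells, outbuildings, residences), random-chord polyline
features (roads, powerlines), and regular grid polylines (section-line
fences; two orthogonal families with random phase, continuing one spacing
beyond the study window so boundary strips are not artificially unfenced).
Defaults mirror the reference study conditions: 250 animal locations, 2000
random availability points, hard 500 m fence threshold.

Avoidance is operationalised as suppression of a homogeneous point process:
candidates drawn uniformly are accepted with weight equal to the product over
feature classes of a suppression function of nearest distance — a step
function (hard) or a logistic curve 1/(1 + exp(−(d − T)/s)) with softness
default s = 25 m, smooth enough for the crossover to be detectable at 10 m
bins. Rejection sampling is capped at 1e7 attempts with a clear error when
thresholds cover the extent.

What the generator does **not** emulate: home-range clustering and temporal
autocorrelation of fixes (fix clouds in the pipeline are isotropic Gaussian
scatters around independent centroids), vegetation or terrain covariates,
realistic road networks, and any behavioural overshoot (real animals
displaced from an exclusion zone may concentrate just beyond it; thinned
uniform sampling spreads them over all remaining habitat). Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to movement autocorrelation or covariate
confounding in field data.

## Triangulation

Azimuths are degrees clockwise from north. The MLE is Lenth's iteratively
reweighted bearing intersection: weighted least squares on signed
perpendicular distances from the candidate point to each bearing line with
weights 1/d_i² (the linearised von Mises score), iterated to step < 1e-8
(relative) with a 100-iteration cap; exceeding the cap or diverging (estimate
beyond ~1000× the station span, e.g. parallel bearings) flags
non-convergence without raising. The fixed point coincides with the
minimiser of the squared angular residual objective to well under the 2 m
oracle tolerance used in the tests.

Robust fallbacks reweight standardised angular residuals (scale = median
absolute residual): Huber with k = 1.345 and Andrews sine with cutoff 1.5π.
They use a damped (step-halving on the angular objective) iteration because
they are invoked exactly on the sets the plain iteration failed, where the
raw update can oscillate through near-station weight blow-ups. `triangulate`
tries MLE, then Andrews, then Huber, and records which estimator produced
the fix; the fallback order is a fixed convention.

## Home ranges and distances

Home ranges are bivariate Gaussian KDEs with the normal-reference plug-in
bandwidth H = n^(−1/3)·Σ̂ (full sample covariance; Silverman's diagonal rule
below n = 10). The outer contour is the boundary of the smallest region
holding the isopleth mass (default 0.95, configurable — the contour level is
a documented choice), extracted from a 256 × 256 grid padded 1.2× beyond the
point bounding box plus three bandwidth standard deviations. The centroid is
the mean of the fixes. Contour mass is accurate to ±0.02 of the isopleth in
the tests. Animals with fewer than five fixes are skipped with a warning.

Nearest distances are planar Euclidean (shapely): point-to-point,
point-to-segment with perpendicular-foot clamping, polygon boundary with
zero on intersection. Empty layers yield +inf sentinels with a warning.

## Between-area comparison

Feature density is compared through random-point distance samples. The
two-group model gives each group a Student-t(ν, μ_g, σ_g) likelihood with
flat priors on means and log scales and ν − 1 ~ Exponential(mean 29) shared
across groups. Sampling is component-wise adaptive random-walk Metropolis
(two chains, 2000-step adaptive burn-in, ≥1e4 retained draws) with a
split-chain Gelman-Rubin check (must be < 1.05, else a ConvergenceError
carries the diagnostics). Reported: posterior of μ₁ − μ₂ with 95% HDI, tail
proportions, and the effect size η = (μ₁ − μ₂)/√((σ₁² + σ₂²)/2) — one of
several possible standardisations; this one follows the two-group Bayesian
estimation convention and is computed per draw and summarised by its median.

Prediction intervals for distances use log d ~ Normal(μ, σ) with flat priors
on (μ, log σ); the conjugate posterior is sampled directly and pushed
through the predictive. Zero distances are offset by 0.5 m (half the 1 m
measurement resolution). The coefficient of variation is sd/mean of the
predictive draws on the meter scale.

## Colocation

For a feature pair, each location contributes observed nearest distances
(A, B) and a latent angle θ ~ Uniform(0, π); the implied between-feature
distance is the law of cosines, and log d ~ Normal(μ, σ) with flat priors
(log σ bounded in [log 1e-3, log 10] to keep the posterior proper). The
sampler is Metropolis-within-Gibbs: reflected random-walk updates of each
θ_j, conjugate Gibbs for (μ, σ). The latent-angle treatment (rather than
computing true angles from coordinates) is the default because the distance
tables do not retain geometry; the per-location latent construction is a
documented choice. The population median distance exp(μ) is carried into
the dispersion ratio d_G/d_R (draws paired independently after shuffling,
since the two fits use disjoint data): clumped if the ratio's 95% HDI lies
below 1, dispersed if above, random otherwise; the construction is symmetric
in the feature order.

Degenerate samples with identical (A, B) everywhere concentrate the
posterior near the upper support A + B (the pushforward density of log d is
singular there); with heterogeneous field-like data the posterior is
well-behaved, and the tests verify agreement with a brute-force grid
marginalisation in both cases.

## Numerical choices and defaults

| quantity | default | notes |
|---|---|---|
| bin width | 10 m | coarsen toward 100 m for small samples |
| threshold window | ±500 m of crossover | truncated and renormalised at the data |
| HDI mass | 0.95 | sliding-window shortest interval, ≥100 draws |
| posterior draws | 1e4 | seeded everywhere; pipeline uses one SeedSequence |
| detection tolerance | 1 bin width | lower T HDI below this ⇒ not detected |
| rejection cap | 1e7 attempts | clear failure when thresholds cover the extent |
| MLE convergence | step < 1e-8, ≤100 iterations | cap defines "failure to converge" |
| robust constants | Huber 1.345, Andrews cutoff 1.5π | classical values |
| KDE grid | 256×256, 1.2× bounding box | contour accuracy vs runtime |

Problem sizes in the test-suite simulations (10–20 seeds per calibration
check, 200 triangulation replicates, 40–50 two-sample simulations, 2000
availability points) match the reference study conditions while keeping each
check to seconds or a few minutes on one CPU.

## Known limitations

- The per-bin independence simplification (above) understates joint
  uncertainty across bins.
- Threshold identification requires the dense-feature regime (see "When the
  threshold is identified"); in sparse regimes estimates drift toward the
  availability saturation distance.
- The detected/undetected flag depends on the Monte-Carlo-decisive
  separation rule; with very few draws (≪1e4) separation becomes easier to
  declare spuriously.
- The latent-angle colocation model ignores the true geometry even when
  coordinates are available, and treats locations as independent.
- No temporal autocorrelation, movement modelling, or covariate adjustment
  anywhere in the pipeline.
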