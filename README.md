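# featureshy

Bayesian estimation of **avoidance-threshold distances** — how far animals
stay from anthropogenic landscape features such as roads, powerlines, oil and
gas wells, fences, outbuildings and railroads — from telemetry-derived
locations and a uniform availability sample. The package is aimed at
movement/habitat ecologists working with VHF-telemetry data on
grassland birds and similar taxa, and includes every stage of such a study:
bearing triangulation, kernel-density home ranges, nearest-distance tables,
per-bin occurrence posteriors, the threshold algorithm itself, between-area
feature-density comparisons, and a colocation ("rather be elsewhere")
analysis. A synthetic-landscape module generates all of these inputs with
known ground truth.

## The model

For a feature class, distances are binned (width 10–100 m) and the cumulative
count of animal locations within bin *i* is modelled binomially with a flat
prior:

    y_i ~ Binomial(n, pi_i),    pi_i ~ Beta(1, 1)

for both animal locations (*G*) and uniform random points (*R*). The
avoidance threshold *T* is where the two cumulative curves converge:

1. form per-bin difference posteriors Δ_k = π_R,k − π_G,k (draws paired by index);
2. let q_k be the fraction of Δ_k draws above zero; the probability that the
   threshold lies in bin *k* is **p_k = 1 − 2|q_k − ½|**;
3. locate the apparent crossover — normally the first descending sign change
   of the posterior-median difference; if the per-bin credible intervals
   overlap zero at a shorter distance, that shorter distance is used so the
   threshold is not overestimated;
4. the posterior of *T* is the p_k-weighted distribution over bin centres
   within ±500 m of the crossover, summarised by its median and 95% highest
   density interval (HDI). A lower HDI bound that overlaps or closely
   approaches zero means the feature is not avoided.

Supporting models: Lenth's iteratively-reweighted maximum-likelihood bearing
intersection with Andrews/Huber robust fallbacks; log-normal prediction
intervals with coefficient of variation; a Student-t two-group comparison
(flat priors, shifted-exponential prior on the normality parameter) with
effect size η = (μ₁−μ₂)/√((σ₁²+σ₂²)/2); and a latent-angle law-of-cosines
model d = √(A² + B² − 2AB·cosθ) whose dispersion ratio d_G/d_R classifies
animal occurrence relative to a feature pair as clumped (<1), random (≈1) or
dispersed (>1).

## Worked example

```python
from featureshy import (AvoidanceThresholdModel, default_landscape_config,
                        generate_features, generate_random_points,
                        simulate_animal_locations)

config = default_landscape_config(seed=5)      # fence grid + wells, hard T = 500 m
layers = generate_features(config)
fence = next(layer for layer in layers if layer.name == "fence")

animals = simulate_animal_locations(layers, config.avoidance_profile,
                                    config.n_animals, config.extent, seed=6)
random_pts = generate_random_points(config.extent, config.n_random, seed=7)

model = AvoidanceThresholdModel(
    fence.distances(animals.x, animals.y),
    fence.distances(random_pts.x, random_pts.y),
    bin_width_m=10.0, feature="fence",
)
results = model.fit(seed=8)
print(results.summary())
```

```
Avoidance threshold model: feature=fence
  n animal locations : 250
  n random points    : 2000
  bin width          : 10 m   window: +-500 m   HDI mass: 0.95
  minimum observed   : 500.0 m
  threshold T median : 545.1 m
  T 95% HDI       : (540.1, 549.6) m
  detected           : yes
```

The simulated birds had a hard 500 m avoidance threshold around fences; the
estimate (545 m, HDI 540–550) sits just above it because the cumulative
curves converge slightly beyond the true exclusion distance, and the closest
simulated bird was recorded at 500.0 m. `results.plot()` draws the two
occurrence curves with HDIs and the threshold window.

The same analysis runs from the shell over CSV/GeoJSON inputs:

```bash
avoidance run --config RUN.json --out results/
avoidance triangulate --bearings BEARINGS.csv --out FIXES.csv
avoidance thresholds --distances DISTANCES.csv --bin 10 --window-m 500 --out THRESH.csv
```

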