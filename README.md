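# climatch

Virtual-ecologist analysis of how habitat suitability model (HSM)
predictions differ between two *versions* of a gridded climate dataset,
as a function of species niche type, grid resolution and projection
scenario.

## The problem

Correlative HSMs (also called SDMs/ENMs) regress species occurrence on
bioclimatic variables and project the fitted relationship across space
and scenarios. The climate surfaces behind those variables get revised:
two versions of the "same" dataset can disagree locally even when their
overall correlation is high, and every published prediction inherits that
disagreement. Because real species confound the question, `climatch`
takes the virtual-ecologist route: it simulates species whose
climate-occurrence relationship is known exactly, fits standard HSMs on
each dataset version, and measures where and how much the predictions
diverge — so the mismatch can be attributed to the data version rather
than to ecology.

Everything runs self-contained on an abstract planar kilometre grid: a
synthetic-climate module generates pairs of highly (but imperfectly)
correlated multivariate climate versions with spatial autocorrelation,
resolution variants and future-scenario perturbations.

## The pipeline

1. **Paired climate versions.** Each variable is a latitudinal gradient
   plus a smoothed-noise anomaly field `f_A`; version B mixes in an
   independent field: `B = gradient + sqrt(1-d) f_A + sqrt(d) f_B`, so the
   per-variable decorrelation `d` controls between-version agreement.
   Predictors are screened by stepwise VIF (threshold 10, consensus over
   version x resolution combinations); versions are compared by pairwise
   Pearson r on stratified random point sets and by focal-window local r.
2. **Virtual species.** Suitability is either a product of response
   curves (sigmoid / Gaussian / threshold-like) or a Gaussian niche in a
   background-sample PCA space; the logistic
   `P = 1 / (1 + exp((HS - beta) / alpha))` converts suitability to
   occurrence probability, Bernoulli draws give presence-absence, and
   virtual sampling (optionally buffered around seed presences, with
   imperfect detection) gives point datasets.
3. **Spatial blocking.** Moran's I correlograms of full-data model
   residuals give the spatial-autocorrelation range; block size = range +
   100 km; square blocks are assigned to two cross-validation folds in a
   checkerboard (plus the complementary assignment).
4. **Fit, gate, ensemble.** GLM, GAM, boosted trees and random forest are
   fitted per fold assignment and evaluated on the spatially independent
   fold (RMSE, rank-based AUC, TSS); models with AUC >= 0.7 and TSS >= 0.4
   are retained and combined per sample into an AUC-weighted ensemble;
   variable importance is permutation-based, standardized to percent.
5. **Projection and mismatch.** Ensembles are projected per context,
   per-cell medians taken across samples, and mismatch quantified as the
   between-version difference of medians, the predicted-simulated
   correlation against the known occurrence probability, and hexagonal
   heatmap summaries.
6. **Factor importance.** A 1000-tree regression forest with block
   permutation importance ranks the experimental factors (species,
   version, resolution, scenario, GCM, timeframe) by their influence on
   the outcomes.

## Worked example

```python
from climatch import (SPECIES_PRESETS, default_generator_config,
                      generate_climate_pair, occurrence_probability,
                      pairwise_between_version_r, realize_presence_absence,
                      sample_presabs, suitability_from_responses)

cfg = default_generator_config(seed=1, n_rows=60, n_cols=60)
pair = generate_climate_pair(cfg)

diag = pairwise_between_version_r(pair.current_a, pair.current_b,
                                  n_points=100, n_sets=5, seed=2)
print(diag.pairwise_r.mean().round(3).to_dict())
# {'bio1': 0.993, 'bio2': 0.917, 'bio4': 0.966, 'bio8': 0.993,
#  'bio15': 0.94, 'bio18': 0.981, 'bio19': 0.988}

preset = SPECIES_PRESETS["alpine"]
hs = suitability_from_responses(pair.current_a, preset.responses)
prob = occurrence_probability(hs, preset.conversion)
pa = realize_presence_absence(prob, seed=3)
print(round(pa.values.mean(), 3))        # 0.129  (extent prevalence)

samples = sample_presabs(pa, "buffered", buffer_km=120, n_points=300,
                         n_samples=3, detection=0.75, seed=4)
print([round(s.prevalence, 3) for s in samples])  # [0.287, 0.24, 0.263]
```

The two versions agree closely on mean-trend variables and least on the
diurnal-range analogue `bio2` (r = 0.92); the cold-adapted species covers
13% of the extent, and buffered sampling roughly doubles its prevalence
inside samples — the situation a field campaign around known occurrences
produces.

The full factorial experiment runs from a config:

```bash
climatch run-all --config experiment.yaml --out runs/exp1 --seed 42
```

or in one call, `run_experiment(ExperimentConfig(), "runs/exp1")` —
2 versions x 3 resolutions x 50 samples x 4 algorithms x 2 fold
assignments = 2400 fits per species at the full design. Each stage writes
CSV/GeoTIFF artifacts plus a JSON manifest and is resumable
(`--resume`).

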