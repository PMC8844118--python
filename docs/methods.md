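# Methods

This note documents the models and procedures implemented in `climatch`,
the parameter choices that matter, and what the synthetic setting can and
cannot show about real climate datasets.

## Synthetic paired climate versions

Each bioclimatic variable on the planar km grid is

    X(s) = base + g * northness(s) + sd * f(s)

with `northness` linear in the row coordinate (+1 at the top row, -1 at
the bottom) and `f` a unit-variance random field built by Gaussian
smoothing of white noise (kernel bandwidth = `spatial_correlation_length`,
default 160 km at 20 km cells). Smoothed white noise was preferred over
spectral synthesis for simplicity and exact seeded reproducibility; the
smoothing kernel makes the field's effective correlation range of the
same order as the bandwidth, which is all the downstream analyses need.

The second dataset version shares the deterministic part and mixes the
anomaly with an independent field,

    f_B = sqrt(1 - d) f_A + sqrt(d) f_indep ,

so the decorrelation parameter `d` in [0, 1] maps monotonically onto the
between-version anomaly correlation (r = sqrt(1-d) on the anomaly
component; higher overall because the gradient is shared). `d = 0` gives
bit-identical versions. The default variable set emulates seven
low-collinearity predictors: mean-trend variables (`bio1`, `bio8`,
`bio18`, `bio19`) get strong gradients and `d = 0.05`, variability-type
variables get weaker gradients and larger `d` (`bio2` 0.40, `bio4`/`bio15`
0.20), reproducing the empirical pattern that dataset versions disagree
most on diurnal/seasonal variability measures and least on annual means.
Under these defaults the stratified-point pairwise correlations come out
at r = 0.92-0.99 with `bio2` lowest — the regime the analysis targets.

Future-scenario stacks add a per-scenario mean shift (the nearer
timeframe realizes half the shift, the farther one all of it) plus a
GCM-tagged smoothed perturbation field shared by both versions (the GCM
represents the climate model, not the dataset version). Coarser
resolutions are block means of the base grid; masked cells are excluded
from block averages. Bilinear resampling interpolates between cell
centres and extends nearest-edge values outside the centre hull, with
masks propagating through any stencil they touch.

All randomness flows from one master seed through named substreams
(CRC-32 of stage tokens into `SeedSequence` spawn keys), so every stage
is independently reproducible and regeneration is bit-identical.

### Predictor screening and version diagnostics

Stepwise VIF: VIF_j = 1/(1 - R²_j) on standardized columns; the max-VIF
variable is dropped until all VIFs <= 10 (exactly collinear columns give
infinite VIF and fall first). A variable enters the consensus set when it
survives in strictly more than half of the version x resolution
combinations. "Regular random sampling" for pairwise r is implemented as
stratified random sampling — one uniform point per cell of a regular
k x k stratum grid with k² ≈ the requested point count — which honours
both the "regular" and the "random" halves of that phrase; the local
version comparison is a focal Pearson r over a 5 x 5 window (truncated at
edges, masked where a window is degenerate). Both the window size and the
point count are explicit configuration, not inferences.

## Virtual species

Response-curve niches multiply univariate responses — increasing /
decreasing sigmoids `1/(1+exp(∓(x-x0)/s))`, Gaussian bells
`exp(-(x-x0)²/2s²)`, and threshold-like logistics (a decreasing sigmoid
with small `s`) — then min-max rescale over unmasked cells; a constant
product is an error naming the degenerate cause rather than a silent
all-zero map. PCA niches standardize the cell climate vectors, fit a PCA
on a seeded random background sample (default 2000 cells), score all
cells on PC1/PC2 and apply a product of Gaussian responses around the
niche centre. A Gaussian product was chosen over a kernel-density
estimate of occurrence because the niche here *defines* the species
rather than describing data; breadth (sd1, sd2) directly controls
generalism.

Suitability converts to occurrence probability by the logistic
`P = 1/(1+exp((HS-β)/α))` with α < 0; P = 0.5 exactly at HS = β, and
smaller |α| makes the transition sharper. The four archetypes use the
conversion parameters α = −0.01, β = 0.4 (generalist), α = −0.05 with
β = 0.6 / 0.7 / 0.8 (alpine / mediterranean / restricted) and detection
probability 0.75 (0.9 for the restricted species, keeping false absences
rare where prevalence is already minimal). The response-curve parameter
values shipped in `presets.py` are editable defaults chosen to realize
the described niche shapes in the synthetic variables' units. Presence-
absence is realized by independent per-cell Bernoulli draws; species are
in equilibrium with climate — no dispersal limitation or disequilibrium
is simulated.

Virtual sampling draws fixed-size point datasets (default 50 samples of
300 points). For low-prevalence species, eligibility is restricted to a
buffer (cell centre within `buffer_km` of any of 500 seeded presence
cells — 120 km for alpine/mediterranean, 60 km for restricted), which
lifts sample prevalence into the range where discrimination metrics are
unbiased. Detection error applies at sampling time only: a sampled
presence is recorded as absence with probability 1 − d; absences are
recorded faithfully. If fewer presence cells exist than requested buffer
seeds, all are used and a warning is emitted.

## Spatial blocking

Residuals (label − predicted suitability) of full-data models (default
GAM + boosted trees) feed Moran's I correlograms over contiguous 100 km
distance classes (max distance: half the point-cloud diagonal; classes
with < 2 pairs are masked). In practice the SAC range is usually read off a
correlogram visually; here that judgement is formalized as the centre of the first class with
I <= 0.05 (configurable), falling back to the maximum distance with a
warning — reproducible and conservative. With several algorithms the
block size is the maximum range + 100 km. Blocks tile the extent from
its origin with no random offset; fold = ((row + col) mod 2) + 1, and the
complementary assignment swaps folds, so the two train/test splits per
sample are "train on fold 1, test on fold 2" under each assignment.
Points inherit folds by half-open containment ([start, start+size)), so
an edge point belongs to the lower-index block.

## Model fitting, gating, ensembles, importance

* **GLM** — binomial GLM with standardized linear + quadratic terms;
  singular designs raise an error naming the collinear variables.
* **GAM** — binomial additive model, per-variable B-spline smooths
  (df 6, degree 3, capped by sample size), penalty weight chosen from a
  small grid {0.1, 1, 10} by AIC (a generalized cross-validation
  analogue). On perfectly separated data, where the penalized IRLS
  likelihood degenerates, the fit falls back to a ridge-penalized
  logistic regression on the same spline basis. GAM defaults are
  documented, not tuned.
* **GBM** — gradient-boosted classification trees (log loss, 100 trees,
  depth 3, learning rate 0.1).
* **RF** — 500-tree random forest; probability = fraction of trees
  voting presence.

Predictions are clipped to [1e-6, 1 − 1e-6] so correlation-based
importance stays defined. Per-fit seeds derive from (master seed,
species, version, resolution, sample, algorithm, assignment).

Evaluation on the spatially independent fold: RMSE; rank-based AUC
(Mann-Whitney form, ties at half weight); TSS maximized over a 0.01-step
threshold grid with ties resolved to the lowest threshold. Models with
AUC >= 0.7 AND TSS >= 0.4 (inclusive) are retained; empty retention is
legal and recorded per sample. Retained models form a per-sample ensemble
with weights proportional to raw AUC (a rank-decay weighting is a noted
alternative, not the default); a single retained model passes through
unchanged. Permutation importance: per variable, 1 − Pearson r between
original and column-permuted predictions, averaged over 5 permutations,
negatives clipped, standardized to percentages summing to 100; constant
prediction vectors fall back to mean absolute difference with a warning.

## Projection and mismatch

Retained ensembles are projected per context; the per-cell median across
samples (even counts: mean of the central pair) summarizes each
version x resolution x scenario combination, and only samples with at
least one retained model enter the median — the per-context sample count
is reported rather than discarded silently. Mismatch measures: the
difference grid (version B − version A, antisymmetric by construction),
the predicted-simulated Pearson r over repeated 10,000-pixel samples
(without replacement within a set), and flat-top hexagonal binning of
the (simulated, predicted) unit plane with cell width 0.04 and grid
origin at (0, 0), plus the least-squares line of predicted on simulated.

## Factor importance

Outcomes (standardized variable importance, predicted-simulated r,
future between-version differences) are regressed on one-hot-encoded
factors by a 1000-tree regression forest with `mtry = max(1, floor(p/3))`
— the regression-forest convention, exposed in config because the
printed source for this default is ambiguous. Factor importance permutes
all dummy columns of a factor as one block (preserving level coherence),
uses the same 1 − r permutation score with n = 5 repeats, and reports
mean ± sd standardized to percent. Factors with a single observed level
are excluded with a warning; a constant response yields an all-zero,
flagged result.

## Problem sizes

The full design (2 versions x 3 resolutions x 50 samples x 4 algorithms
x 2 fold assignments = 2400 fits per species) is the configured default.
The bundled test and acceptance runs use reduced sizes chosen as
desk-scale working points: a 60 x 60 grid with 2 resolutions and 5
samples for the end-to-end smoke experiment (160 fits per species), and
40-50 cell grids with GLM(+GBM) fits, 4 samples and 10 replicate seeds
for the property experiments (driver recovery, mismatch-vs-decorrelation
trend, fidelity direction). These sizes keep every stage exercised — the
conclusions they support are directional, not effect-size estimates of
the full design.

## What the synthetic setting does and does not show

The generator reproduces the *structure* of the real problem — spatially
autocorrelated predictors, two highly correlated dataset versions whose
disagreement concentrates in variability-type variables, species with
contrasting niche breadths, buffered sampling and imperfect detection —
so passing tests show the pipeline's logic and statistics behave
correctly and that the qualitative findings (mismatch grows with driver
decorrelation; models fitted on the generating version track the
simulated truth better; the species factor dominates outcome variation)
are reproduced under known conditions. It does not emulate real
geography: no coastlines or elevation, Gaussian and stationary fields,
no cross-variable physical constraints, no reprojection artefacts, and
no observation-network heterogeneity. Effect sizes measured here do not
transfer to real dataset pairs; directions and machinery do.

## Numerical choices and degenerate inputs

Logistic evaluations use `expit` (no overflow); min-max rescaling of a
constant surface raises rather than divides by zero; local correlation
masks windows with (numerically) zero variance via a relative tolerance;
Moran's I requires nonzero variance and at least one weighted pair;
stepwise VIF treats R² >= 1 − 1e-12 as exact collinearity; fold
assignment tolerates points exactly on the far extent edge; GeoTIFFs are
written as float64 so that write -> read -> recompute cycles in the
resumable pipeline are bit-identical. At float64 precision the logistic
conversion saturates at exactly 0/1 for |HS − β| >> |α|; monotonicity is
strict wherever the output is representable away from the bounds.
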