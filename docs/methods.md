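# Methods

This note documents the models and numerical choices behind `divermap`,
what the synthetic generator does and does not emulate, and the decisions
made where the design was genuinely open.

## The synthetic world

The generator states a world; it is the ground truth every test is scored
against.

**Zones.** Biomes are horizontal bands of the grid and ecoregions vertical
strips within them — rectangular tiles, so zonal membership is exact.  No
attempt is made to mimic real geography, latitudinal gradients, or any
published biome inventory.

**Richness fields.** For each taxon, a Gaussian score field is mapped
through the link `S = round(exp(mu + sigma*G))`, clipped at 1, so
downstream log1p-standardization is meaningful.  Defaults
`mu = 6.0 / 4.5 / 4.0` (plants / AM / ECM; ≈ 400 / 90 / 55 species per
cell) and `sigma = 0.6` give right-skewed richness surfaces of realistic
magnitude.  Spatial autocorrelation comes from Gaussian-filtering white
noise; the config's `autocorr_length` L (cells) sets the filter to
`sigma = L/2`, giving field correlation ≈ exp(−d²/L²); L ≤ 1 means
independent cells.

**Correlation targets.** The per-ecoregion plant–fungal Spearman target
ρ_e is hit exactly on the copula scale: the fungal Gaussian score in zone
*e* is `r·U + sqrt(1−r²)·V` with shared field U, private field V, and
Pearson weight `r = 2·sin(π·ρ_e/6)` — the classical identity linking the
Pearson correlation of a bivariate Gaussian to its Spearman correlation.
Any monotone link preserves Spearman, so the population zonal Spearman
equals ρ_e (integer rounding of richness introduces only tie noise,
< 0.01 at the default links).

**Study replicates and uncertainty.** Each taxon gets two "study" layers,
`true + Normal(0, SD_cell)` with independent noise, where
`SD_cell = noise_cv × (1 + 0.4·M) × true` and M is a smooth field — so the
uncertainty surface is heteroscedastic both absolutely and relatively.
The emitted uncertainty layer reports this same SD in the study's dialect:
`sd` directly, `cv_percent = 100·SD/true`, or
`iqr_ratio_percent = 100·1.349·SD/true` (the IQR of a normal is 1.349
SD).  The default `noise_cv = 0.2` makes the two studies of one taxon
correlate at roughly 0.5–0.7 after masking, matching the cross-study
agreement range reported for the real layers.

**Covariates.** Eleven covariate fields (temperature, precipitation, pH,
SOC, N, P, elevation, AM/ECM host-biomass %, climate-stability index,
human-development %) are independent smoothed Gaussian fields mapped
through strictly monotone transforms to plausible units; percentage layers
go through a logistic and stay in [0, 100].  Optional per-ecoregion
effects `(beta_plant, beta_fungal)` are added to the Gaussian scores
*before* the richness link, so the sign table of environmental responses
is exact ground truth for the sign-concordance analysis.  Optional
per-zone covariate shifts move zone means, which lets tests wire
ecoregion-level ρ to a covariate for driver-recovery checks.

**What a green test does not establish.**  The generator has no spatially
correlated observation error, no sampling-effort bias, no irregular zone
shapes, no missing-data geography (nodata only where tests inject it), and
covariates are mutually independent unless wired otherwise.  Results on
this world validate the *statistical machinery*, not the ecological
conclusions of any real-data analysis.

## Harmonization

Standardization is exact centering/scaling over valid cells; a layer whose
log-values are numerically constant (SD below 1e−12 relative) is rejected
rather than divided by a 1-ulp SD.  The two-layer disagreement CV shifts
both standardized layers by one common constant,
`−(global minimum across both) + 1e−6`, before computing
`(|a−b|/2)/mean`.  The source description of this shift ("the minimum
value across both") would not achieve positivity for negative minima as
written; with exactly two values the rank order of CV values is invariant
to the shift, which is all the 95th-percentile exclusion consumes, and the
shift used is always emitted.  Percentiles are linear-interpolation
(type-7) quantiles; uncertainty masks retain at ≤ threshold (ties kept),
hotspot detection later selects at > threshold (ties dropped) — the
asymmetry is deliberate and mirrors "top percentile excluded" versus
"greater than the upper percentile" semantics.  Nodata propagates through
every cellwise operation.  Mask bundles are assembled per comparison: the
AM analysis and the ECM analysis each intersect six masks (two plant-study,
two fungal-study, two disagreement), so the two comparisons carry
different plant masks.  Percentile thresholds are computed over all valid
cells (whether they were computed before or after land masking in the
source workflow is unstated; this choice is documented here).

## Correlation scan

Sampling is uniform without replacement within each zone, one independent
seed substream per (scale, zone) so results do not depend on zone
iteration order.  Quotas default to 10,000 (global), 10,000 (biome) and
1000 (ecoregion) with a 100-cell ecoregion minimum; all are config.
Spearman uses midranks; constant inputs yield a flagged NaN record, never
a silent zero.  Per-biome one-sample *t*-tests of ecoregion correlations
are two-sided with raw p-values — no multiplicity correction, since the
source workflow reports per-biome significance without stating one.

## Smooth models

All smooth models are Gaussian/identity additive models on B-spline bases
(data-quantile knots, k basis functions per term, cubic for k ≥ 4,
quadratic for k = 3) with a second-derivative penalty, solved in closed
form by penalized least squares.  This replaces an mgcv-style REML fit:
with k = 3 there is about one wiggly degree of freedom per term, so the
penalty is nearly inert and the default is the unpenalized regression
spline (alpha = 0), which is deterministic and exact even on
zero-residual designs (where iteratively reweighted fitters fail).  The
ecoregion-level correlation-driver model (k = 4, a dozen terms, often
under a hundred zones) instead defaults to a mild fixed penalty
(alpha = 1.0) to keep the near-saturated fit stable.  Adequacy is defined
by properties — deviance explained within one point of the linear-model R²
when the truth is linear, a hump fit beating a straight line, a null fit
under 5% — not by equivalence to any particular smoother.  Deviance
explained is clipped to [0, 100]; the nested partition
`100·(dev_red − dev_full)/dev_null` clips negative differences to zero
with a warning, since penalized nesting can be violated numerically.

## Sign-concordance procedure

Within each usable ecoregion (≥ 100 cells, environmental variable with
≥ 10 unique values), all variables are min-max scaled to [0, 1] using the
zone sample's own range, and two OLS models are fitted: plant ~ env +
fungal + host%, fungal ~ env + plant + host%.  The opposite taxon and the
host-biomass covariate strip host–symbiont coupling variation.
Coefficient signs are taken from point estimates after filtering both
coefficients at p < 0.05; the filter removes zones, never flips signs.
The 2×2 table (sign agreement × correlation sign) uses Pearson chi-squared
without Yates continuity correction as the primary statistic — the
corrected value is carried in diagnostics, because which variant the
source workflow used is unstated.  Expected counts below 5 are flagged.
Collinearity sensitivity re-runs the test after dropping zones whose
maximum absolute pairwise covariate correlation exceeds 0.85 and 0.80.
The Shapiro–Wilk screen is diagnostic only (subsampled to 5000), never
blocking.

## Monte-Carlo error adjustment

Dialect conversions: `SD = CV%/100 × mean` and
`SD = ratio%/100 × median × 1.35` (the median layer then stands in for the
mean).  The 1.35 multiplication follows the source procedure verbatim; it
assumes normally distributed replicates and a warning is emitted whenever
this dialect is converted.  Note the generator emits the IQR-ratio dialect
honestly (`100·1.349·SD/median`), so the verbatim back-conversion inflates
that layer's SD by ×1.82 — a faithful reproduction of the stated
procedure, which only tightens the attenuation it measures.
Perturbation is Uniform(−SD, +SD), exactly as specified, not
Gaussian(0, SD).  The original cell sample is held fixed across all
iterations, so the Monte-Carlo spread reflects measurement error only.
Standardization inside the loop uses constants from the full layer, not
the sample.  Perturbed raw values below −1 (where log1p is undefined) are
clamped to −1 + 1e−9 and counted in diagnostics.  Iterations use fresh
seed substreams indexed by (seed, iteration) only, so runs at different SD
scale factors share common random numbers — required for the monotone
attenuation check.

## Hotspots

Hotspots are computed on the individual study layers (not the consensus),
after the comparison's uncertainty masks, then unioned within each taxon
with the 1-vs-2-study agreement level retained.  Overlap percentages are
reported against both denominators, with the fungal hotspot area as the
headline.  Biome-level accounting is provided in both modes: global
thresholds cross-tabulated by biome, and thresholds recomputed within each
biome's own retained cells.

## Pipeline

`run_pipeline` chains the five stages, writing layers as single-band TIFF
(GDAL nodata tag, metadata in the image description) and results as tidy
CSV with the config hash in a header comment.  The hash excludes the
output directory, so two runs of the same analysis are byte-identical
wherever they are written.  The per-zone "raw richness" covariates in the
driver table are zone means (over the sampled cells) of the two raw study
layers averaged — the aggregation is unstated in the source description;
means are used, as for the environmental covariates.

## Known limitations

No reprojection or grid alignment (inputs must share a grid); no
spatial-autocorrelation correction of correlation significance; no
propagation of Monte-Carlo uncertainty into the driver or hotspot stages;
areas are cell counts, not km².  These mirror the scope of the analysis
the package reimplements.
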