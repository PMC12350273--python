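# Methods

This note documents the models, the synthetic study design, the defaults
and the numerical conventions used throughout the package, and what the
passing tests do and do not demonstrate about real data.

## Suitability models

**Random forest.** `RandomForestSDM` fits a 500-tree
`RandomForestClassifier` on presence (1) / pseudo-absence (0) rows after a
stratified 75/25 train/holdout split. Reported diagnostics are the
out-of-bag error (and its complement as "accuracy", in percent), holdout
AUC and TSS at the max-TSS threshold, and permutation importance — the
mean decrease in holdout classification accuracy over independent
within-column shuffles (5 repeats by default, with the spread reported).
Tree count, split fraction and seed are explicit model parameters.

**Maximum entropy.** `MaxEntSDM` implements the presence-background
exponential model through its penalized-logistic equivalence. The base
variables are min-max scaled to [0, 1] over the background range and
expanded into linear, quadratic, pairwise-product and forward-hinge
features (10 knots per variable at training quantiles). Coefficients
minimise the mean Bernoulli negative log-likelihood of presence vs
background plus an L1 penalty `alpha * ||w||_1` with

    alpha = regularization_multiplier * 0.1 / sqrt(n_presence)

(the intercept is unpenalized). The exact objective is exposed as
`penalized_nll` so independent grid-search optimisers can verify fits; the
solver is an accelerated proximal-gradient (FISTA) loop with a
parameter-change stopping rule (1e-9, max 20 000 iterations), which the
tests check against a brute-force 1-D likelihood scan to 1e-3. The 0.1
base constant was chosen so that, at the default multiplier of 1.0, a
no-signal model (presences drawn uniformly from the background) shrinks to
a flat surface while genuinely informative features survive. Suitability
is reported on the logistic output scale, `expit(intercept + w·f(x))`;
this is the only output transform implemented (a cloglog variant would be
a one-line change but is deliberately out of scope). Percent contribution
is permutation-based (drop in training AUC per base variable, clipped at
zero and normalised to sum to 100) — an intentional, documented deviation
from the path-based heuristic of the original MaxEnt software, which is
not reproducible from its description. Model evaluation uses a stratified
10-fold cross-validation over presence + background rows; omission is
computed at the training max-TSS threshold of each fold.

## Evaluation conventions

AUC is the rank-based Mann-Whitney statistic with half credit for ties.
Confusion metrics use "predicted present iff score ≥ threshold" (closed
lower bound) with exact integer counts; TSS = sensitivity + specificity −
1, omission = 1 − sensitivity. The default operating threshold is the
argmax-TSS over unique score values (lowest such value on ties), found by
exhaustive scan — a fixed 0.5 can be passed instead. Folds are stratified,
disjoint and covering; k may not exceed the minority class count.

## Variable screening

VIF(x_j) = 1/(1 − R²) from the OLS regression of x_j on all remaining
variables plus an intercept; perfect collinearity reports +inf. The
iterative screen removes the argmax-VIF column (earliest column on ties)
while the maximum is ≥ 10, and never re-admits a removed variable.
Screening operates on presence-site climate values, not the full raster.
Note that on the synthetic grids the screen genuinely removes variables:
TD is exactly MWMT − MCMT and the degree-day family is nearly collinear
with MAT, so infinite/huge VIFs occur by construction.

## Spatial thinning

Distances are haversine on a 6371 km sphere. Thinning maximises retention:
within each connected component of the conflict graph (point pairs closer
than the 5 km threshold) the package keeps a provably maximum conflict-free
subset, computed exactly for components of up to 18 points via a memoised
maximum-independent-set recursion with a lexicographic tie-break; larger
components fall back to deterministic greedy most-conflicted-first
removal. The widely used thinning tools optimise the same objective by
randomised restarts; the exact deterministic approach was preferred here
because it is reproducible and verifiable by enumeration.

## Trait links and the lag analysis

Six candidate forms (linear, quadratic, cubic, logarithmic, exponential,
power) are fitted by least squares — polynomial forms in closed form, the
exponential and power forms by Levenberg-Marquardt seeded from the
log-transformed linear fit. The winner minimises AICc
(n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1), k counting coefficients plus the
residual variance); ties go to fewer parameters. Forms whose domain
excludes the data (log/power at x ≤ 0) are skipped with a note, never an
error. R² is reported against the observed-mean baseline for every form,
including the nonlinear ones.

The lag analysis pools (growth, suitability) pairs across sites and years
(sites × 20 years by default) and fits the linear form at lag 0
(current-year suitability) and lag 1 (previous-year), reporting R² per lag
and the winner. Pooling across sites and years is the default because the
reference analyses show single pooled scatters; a per-site variant can be
built directly from the returned tables. Zoning always consumes the
*linear* lag-1 link for growth (driven by prior-year suitability) and the
linear current-period link for density.

The pipeline fits trait links against both models' suitability and carries
the better-aligned model (higher growth R²) into projections and zoning —
the same model-selection logic used in comparative SDM studies. On any
given synthetic replicate either model may win; at desk scale the MaxEnt
surface often transfers better to trait sites because forest probabilities
at training presence cells are partially memorised.

## Zoning conventions

Habitat classes are left-closed: [0, 0.2) unsuitable, [0.2, 0.4) low,
[0.4, 0.6) medium, [0.6, 1.0] high — a cell at exactly 0.6 is high.
Timber eligibility is strict: growth > 0.6 cm yr⁻¹ AND density
> 0.5 g cm⁻³. The "top 10% / top 20%" production zones rank eligible cells
by the geometric mean of min-max-normalised growth and density
(normalisation over eligible cells; a degenerate zero-range surface
normalises to 1); the cutoff is the ceil(f·n)-th largest score and all
ties at the cutoff are admitted, so optimal ⊆ sub-optimal by construction.
A suitability-only ranking is available via `ZoningConfig(rank_by=
"suitability")`. Areas are exact cell counts × cell area; percent change
against a reference period reports None (not infinity) for classes absent
in the reference.

## The synthetic study

The generator is the package's definition of the study conditions, not a
tuning knob. Defaults: a 60 × 80 lattice of 10 km cells inside the
species' natural range box (23°30′–33°30′N, 103°30′–122°00′E); 213
presences; 587 pseudo-absences; 27 trait populations; 20 annual rings.

*Climate fields* are Gaussian-kernel-smoothed white noise (kernel radius 4
cells by default) placed on realistic subtropical scales (MAT 16 ± 4 °C,
MAP 1300 ± 450 mm, CMD anti-correlated with MAP, degree-day variables tied
to MAT). TD and AHM are always derived from their parents, and the
temperature chain EXT ≥ MWMT ≥ MAT ≥ MCMT ≥ EMT holds by construction
(amplitudes are strictly positive offsets).

*Truth.* Suitability is logistic in z-scored TD, MAP and CMD with
coefficients (−2.4, +3.0, −3.6) and intercept −8. These were set, when the
generator was designed, to produce the sharp realised niche that real
occurrence data show: roughly a tenth of the landscape highly suitable and
presence/background discrimination in the mid-0.9s, rather than the weak
separation a mild logistic would give. For scenario or single-year grids
the z-scores are anchored to the reference-period normals, so a uniform
warming shifts suitability instead of being re-absorbed by
standardisation.

*Scenarios* shift temperature variables additively and scale MAP
multiplicatively (presets: +1.2 °C/0.97 and +1.5 °C/0.95 for the 2020s,
+2.2 °C/0.94 and +3.0 °C/0.90 for the 2050s under the intermediate and
high pathways), recompute TD and AHM, and move CMD by the monotone rule
CMD′ = max(0, CMD + 30·ΔT − 0.3·(f − 1)·MAP): warming or drying never
decreases the moisture deficit. Secondary thermal variables follow fixed
monotone sensitivities. Zero shift and unit factor return the input
bit-for-bit.

*Occurrences* are drawn without replacement with probability proportional
to suitability (sequential PPS via Gumbel-top-k keys, so small cases can
be verified by exact enumeration of ordered draws).

*Traits.* Annual increments follow
growth_t = g0 + u_s + g1·S_{t−1} + g2·S_t + ε_t with defaults g = (0.15,
0.55, 0.15) cm yr⁻¹ — the previous-year weight dominating by design —
site offset u_s ~ N(0, 0.08²) and year noise ε ~ N(0, 0.08²); negative
increments are truncated at zero and counted. Density is d0 + d1·mean(S)
+ ε_d with (0.40, 0.35) g cm⁻³ and noise sd 0.04, spanning the 0.5 g cm⁻³
quality threshold across the suitability range. Annual suitability series
come from per-year grids built as small autocorrelated perturbations of
the normals (temperature sd 0.5 °C, MAP log-factor sd 0.06) — a stand-in
for however annual suitability was derived in the original workflow, which
is not documented. The noise levels place the population-level trait R²
in the 0.4–0.7 band at 27 sites.

## What the synthetic tests do not show

The generator emulates the *statistical* structure of the inputs, not
their geography: no real coastlines or provinces, no 800 m national grid,
no sampling bias beyond suitability weighting, no observation error in
coordinates, no ring-measurement error model, and interannual climate
realisations are independent (real climate is autocorrelated, which is one
reason real lag-0 regressions score higher than ours). Passing tests
demonstrate that the pipeline recovers known generative structure under
these idealised conditions — they do not certify performance on real
occurrence compilations.

## Problem sizes and runtime

Default study: 4 800 cells, 800 modelling points, 27 trait sites × 20
rings, four scenario grids; one full run completes in well under a minute
on a single CPU. Replicated property tests (driver recovery, lag
recovery) use reduced landscapes (a few hundred rows, 150-tree forests)
so the whole suite stays within a couple of minutes.

## Known limitations

* The raster interface is text-based (ESRI ASCII grids plus a JSON
  sidecar); GeoTIFF support would need a geospatial raster dependency.
* MaxEnt feature expansion uses forward hinges only and pairwise products;
  threshold features and the original software's path-based contribution
  are not implemented.
* Forest probabilities at training presence cells are partially memorised;
  trait regressions at desk scale therefore tend to favour the smoother
  MaxEnt surface, and the pipeline's model-selection step makes that
  choice explicit rather than hiding it.
* The VIF screen never re-admits removed variables; with the default
  synthetic grids the retained set varies between seeds (the collinear
  families differ in which member survives).
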