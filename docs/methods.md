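# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `spadgwas`. Everything stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is quoted
from external runs.

## Radiometric calibration and zonal statistics

Calibration is single-point against a whiteboard panel: reflectance =
DN × 0.998 / 65000, linear through the origin, with no dark-current term
(only a single reference is assumed available). When a scene carries a
whiteboard region, the measured mean DN of that region is used as the
reference instead of the nominal 65000, which removes any rendering bias.

Pixel membership uses pixel-center containment in the plot polygon
(shapely), with 0-based row/column raster indexing; pixel (i, j) has center
(j + 0.5, i + 0.5). Genomic positions, by contrast, are 1-based bp
throughout. Plot polygons with zero covered pixel centers are an error that
names the plot. Stage summaries average plot-level means, not pixels — the
cultivar plot is the unit of analysis, matching how the SPAD replicates are
defined.

Stage dynamics are reported as percent declines 100 × (prev − curr)/prev,
rounded to 2 decimals for reporting only.

## Vegetation indices

All 18 indices are computed exactly as printed in the source formula table,
including the non-standard VARIred coefficients (1.7/0.7/2.3/1.3). Two
genuinely open readings are handled explicitly:

* **CARI** — the printed `(Re−R)/0.2*(Re+R)` is precedence-ambiguous. The
  default reads the 0.2 as part of the denominator,
  `(Re−R)/(0.2(Re+R))`, which is bounded and behaves like the other ratio
  indices; the literal left-to-right reading is available via
  `cari_literal=True`.
* **Zero denominators** yield flagged missing values (NaN + validity mask),
  never fabricated zeros; downstream correlations are pairwise-complete.

Property guarantees (tested): pure ratio indices are invariant to a common
positive rescaling of all bands; DVI/EXG/TVI scale linearly; every index
agrees with an independent transcription oracle to ≤ 1e-12.

## Feature selection

Per (environment, treatment, stage) cell: impurity-based random-forest
importance (scikit-learn, 500 trees, unlimited depth, seeded) normalized to
sum to 1, and pairwise-complete Pearson correlation with SPAD. The selected
feature set is top-5 by importance ∪ argmax |r| — an explicit, testable form
of the informal "top importances plus strongest correlate" rule. Ties break
alphabetically. The correlation values are treated as signed Pearson r (a
signed "R²" is not a coefficient of determination). A pooled-treatment mode
is available; the default is per-cell, since drought changes the
spectra–SPAD relationship.

## Inversion network

A literal backpropagation network: one hidden layer of 18 tanh units, linear
output, full-batch gradient descent on MSE, learning rate 0.001, seeded
normal initialization scaled by 1/√fan-in. Features and the response are
standardized internally with training-split statistics only (no validation
leakage); predictions return on the raw SPAD scale. The protocol default of
50 epochs is kept on the model class; the pipeline default raises epochs to
5000 because plain full-batch gradient descent needs far more steps than an
adaptive optimizer to reach the same training error at this learning rate —
convergence on a noiseless affine target (held-out R² ≥ 0.95) is part of the
acceptance suite. A zero-variance target short-circuits to the exact
optimum (constant prediction). Divergence (non-finite loss) raises with the
epoch number.

Evaluation follows the replicated-split protocol: eight independent random
70/30 re-splits (84/35 at n = 119; ceil rounding gives the 84). Metrics:
Pearson r; R² reported as r² (the published metric pairs satisfy R² ≈ r²,
e.g. 0.90→0.80, 0.96→0.91), with the coefficient-of-determination form
emitted as a secondary column; RMSE on the raw scale plus a standardized
RMSE column (the published 0.14–0.28 RMSE range is only consistent with a
standardized scale); RE = mean absolute relative error, the reading
consistent with the published 0.02–0.04 magnitudes. The eight "iterations"
are implemented as re-splits; a restart mode (one split, eight weight
initializations) is available.

## Trait statistics and heritability

Summaries (μ, median, CV, σ, max, min) are computed over genotype means;
per-replicate summaries are available via flag. Heritability uses the
one-way ANOVA estimator with σ²_g truncated at zero (standard fix keeping
h² ∈ [0, 1]); unbalanced replicate counts use the Snedecor–Cochran effective
replicate number. REML-based h² and G×E partitioning are out of scope. The
estimator is verified against a brute-force sums-of-squares oracle and, on
synthetic trials with target h² = 0.7 at n = 119 with 2 replicates, recovers
the target within ±0.1 (mean over 20 seeds).

## Mixed-model scan

* **K** — VanRaden centered genomic relationship matrix,
  K = ZZᵀ / (2Σp(1−p)); missing dosages are mean-imputed per marker (rate
  logged) and markers below MAF 0.05 are dropped before the scan.
* **Q** — top principal components (default 3, matching the three
  subpopulations) of the centered/scaled dosage matrix; a deterministic,
  dependency-free surrogate for model-based structure estimates. Signs are
  fixed for determinism; collinear columns are dropped with a warning.
* **Variance components** — REML on the null model through the eigen
  decomposition of K (grid + Brent on log δ, δ = σ²_e/σ²_u), then fixed for
  all markers (P3D/EMMAX). Exact per-marker REML is available via
  `method="exact"`; under the null the two agree (tested), and P3D runs the
  whole panel in milliseconds.
* **Per-marker test** — whitened (GLS) regression via Frisch–Waugh–Lovell
  residualization, Wald t-test, df = n − p − 1. Marker R² is the partial R²
  of the marker in the whitened model; a raw-phenotypic-scale variance share
  (β² var(x)/var(y)) is emitted as a secondary column since the published
  "MarkerR2" is not formally defined.
* **Calibration** — on structured nulls (three subpopulations, Fst 0.1) the
  Q+K scan holds the type-I error at P < 0.001 within [2e-4, 5e-3] over
  50,000 tests with genomic-control λ ≈ 1.0, while a naive scan (no Q, no K)
  inflates to λ > 1.2 — the motivation for the Q+K model.

Significance is strict (P < 0.001 excluded at equality, per the printed
threshold). The scan reduces exactly to OLS when K = I and Q is empty
(≤ 1e-8 against a per-marker regression oracle).

## LD decay and locus merging

LD decay is estimated from intra-chromosomal pairwise r² binned by distance
(50 equal-width bins, centered 3-bin rolling mean); the decay distance is
the first bin center where the smoothed curve falls below
max(0.1, background), the background being the mean r² of the
upper-quartile-distance bins. With fewer than 100 intra-chromosomal pairs a
configured default (5 Mb, a typical wheat panel scale) is returned with a
warning; a curve that never crosses returns the maximum observed distance,
flagged. On simulated LD blocks of size d the estimate lands within
[0.5d, 2d] (tested).

Loci are single-linkage chains of significant markers within the decay
distance per chromosome (equivalently: split the sorted positions at gaps
exceeding the window — verified against a connected-components oracle). The
representative is the member with minimum P, ties to the smaller bp.
Merging is idempotent on representatives. Measured/predicted overlap pairs
loci on the same chromosome greedily by representative distance within a
window (default: the decay distance), each locus used at most once.
Summaries report per-cell counts, minimum P and marker-R² ranges, plus
per-source totals and arithmetic means — conservation (totals = sum of
cells) is asserted.

Annotation is a local interval lookup into a user-supplied GFF3 (1-based
inclusive, optional flank); malformed lines are skipped and counted.

## The synthetic generator: what it emulates, and what it does not

Defaults are the study design: 119 genotypes split 16/35/68 across three
subpopulations (Balding–Nichols with Fst 0.1), 2000 SNPs on 21
wheat-labelled chromosomes (~800 Mb each, MAF ≥ 0.05), 8 QTLs plus a
polygenic background, target h² 0.7 per cell (published range 0.65–0.72),
SPAD baselines rising from heading (≈54.5) to grain filling (≈57) with a
drought offset, band baselines set to the published treatment × stage means
(hence NIR > red edge > green > red > blue and the stage-wise decline hold
by construction in expectation), and DN = reflectance × 65000/0.998 with a
rendered whiteboard panel.

The SPAD→reflectance forward model is affine per band
(slopes −0.002…+0.0015 reflectance per SPAD unit; visible bands decline
with greenness, NIR rises) plus two noise terms: per-plot reflectance
jitter (sd 0.005, the field heterogeneity plot averaging cannot remove —
this sets the realistic VI–SPAD correlation, giving mean validation r ≈
0.85–0.9) and per-pixel sensor noise (sd 0.01, mostly averaged away within
a plot). How plot spectra relate to 5-plant SPAD means is not observable
from the published material; the affine form is the simplest choice that
gives the feature-selection and inversion stages a realistic signal.

Not emulated: radiative transfer, soil/shadow classes, BRDF/sun angle,
orthomosaic geometry, linkage disequilibrium beyond population structure
(markers are drawn independently within subpopulation), G×E interaction of
QTL effects, multi-year weather. Passing tests therefore demonstrate the
statistical machinery — calibration, index arithmetic, estimator
consistency, scan calibration and power, merging logic — not sensor physics
or real-canopy spectral behavior.

## Problem sizes

The default test and acceptance configuration runs the complete chain at
the study scale (119 genotypes, 2000 markers, 12 cells, 8 network re-splits
per cell) in about a minute on one CPU; dedicated calibration experiments
use 50,000 null marker tests and 20-seed replications. These sizes were
chosen to make the statistical assertions sharp while keeping the whole
suite fast to iterate on.

## Known limitations

* P3D fixes the variance ratio at the null fit; markers with very large
  effects are tested slightly conservatively relative to exact REML (the
  exact mode exists but is O(markers × REML)).
* The ANOVA h² assumes i.i.d. replicate errors within genotype; no spatial
  field trend is modeled.
* The LD-decay estimator needs genuine LD to cross its threshold; on
  structure-only panels it falls back to (or near) the configured default.
* RF importances are not invariant to row order (bootstrap indexing); the
  selected feature set is, and that is what the tests pin down.
* The published per-cell locus counts (sums 308/206/102) and the overlap
  table are reproduced from their transcriptions; the raw scans behind them
  cannot be recomputed without the unpublished genotype and field data.
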