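# Methods

This note records the models implemented in `metfa`, the defaults and the
reasoning behind choices the problem left open.

## Envirotyping

Daily thermal time uses the wheat cardinal temperatures 0 / 26 / 34 °C:
TT = T for 0 < T ≤ 26, TT = (26/8)(34 − T) for 26 < T ≤ 34, else 0, with
T the mean of the daily minimum and maximum.  The function is continuous at
both breakpoints and bounded by [0, 26] degree-days.

Growth stages are timed from sowing: emergence 14 days after sowing when
more than 3 mm of rain fell in the preceding seven days, otherwise 14 days
after the first post-sowing rain day (rain > 0 mm; no threshold is imposed
because none is defensible a priori); end of juvenile phase at 500
cumulative TT after emergence; heading at a regional TT-from-sowing
threshold (North 1374, South 1301, West 1194); flowering, start and end of
grain fill each 250 TT later; maturity 400 TT after end of grain fill.
Cumulative sums run over days strictly after the anchor date and trigger on
the first day the threshold is reached (inclusive).  Intervals are
half-open `[start, end)` so the seven growth intervals partition the season
with no double-counted day.  A weather series that ends before a threshold
raises a censored-stage error naming the stage.

Thirteen ECs are computed per interval (averages of mean/min/max
temperature, day length, solar radiation, VPD and photothermal quotient
PQ = 0.47·SR/T; day counts; rain totals; dry/frost/warm/hot day counts),
plus six multi-interval ECs (rain sowing→flowering, flowering→end of grain
fill, 1 January→sowing; day counts of the two long intervals; frost days
within ±7 days of flowering).  PQ is included for every interval and AveDL
is the daily mean over the interval; days with zero mean temperature
propagate as missing into AvePQ.  Day length uses the sunrise equation with
Spencer's Fourier-series solar declination (an accurate standard
approximation; tests cross-check it against an independent solar-ephemeris
oracle to 0.1 h).

Soil ECs are one value per attribute and depth layer (15 attributes × the
six standard layers = 90 ECs) plus A/B horizon depths.  When EC vectors are
assembled into the matrix **W**, columns whose population variance is below
1e−12 after scaling to unit maximum magnitude are dropped, and remaining
missing cells (censored stages) are mean-imputed.

## Genotype kernels

Markers are coded −1/0/+1 with 0 the heterozygote; pₛ is the +1-allele
frequency among non-missing calls.  Imputation fits, per focal marker, a
random-forest classifier (200 trees by default) on up to 500 most-correlated
markers whose minor-allele-frequency difference is below 0.1, and imputes
only when the out-of-bag error is below 0.2; correlation ties break by
marker order and predictor missing values are mean-filled for ranking and
prediction.  QC removes markers with > 5 % missing, < 0.025 MAF or > 10 %
heterozygous calls (strict inequalities).  Pruning scans markers in input
order and removes not-yet-visited markers with |r| > 0.8 to the current
survivor; the survivor set therefore depends on scan order, which is the
documented convention.  The GRM is MM′/c with M = X + 1 − 2p and
c = 2 Σ pₛ(1 − pₛ); with sample-estimated frequencies every row sums to
zero.  Residual missing calls are mean-imputed per marker before centring.

Purdy strings are parsed by splitting at the highest-numbered cross
separator (left-associative for ties); each intermediate cross product is
selfed seven generations before being crossed again, except backcrosses
(explicit `*n` doses, or a recurrent founder reappearing against a cross)
which mate the recurrent parent to the F1 directly.  Named lines descend
from their final cross by seven selfing generations; lines from the same
cross share selfing-generation individuals up to the point their selection
histories diverge (an approximation — the exact generation-sharing rule is
not documented anywhere authoritative).  Kinship uses the standard
recursion φ(i,i) = (1 + φ(P1,P2))/2, φ(i,j) = (φ(P1,j) + φ(P2,j))/2 with
unrelated non-inbred founders; kinship coefficients are used directly as
the kernel (self-kinship ≤ 1), with an optional ×2 numerator view.

## Single-trial spatial models

Per trial, y = μ + Z_g u_g + [Z_r u_r] + [Z_c u_c] + ε with ε following a
separable correlation over plot rows and columns.  The default candidate
grid is {±row random} × {±col random} × {id, ar1}² (16 models); second-order
autoregressive cells are available behind the `include_ar2` flag, since
independent structures are the common fallback and ar2 rarely survives
selection.  Cells that are unidentifiable on the trial's geometry (a single
row or column) are skipped.  Each candidate is fitted by direct REML
maximisation (L-BFGS-B over log-variances and tanh-transformed
correlations; ar2 parameterised by partial autocorrelations to stay in the
stationary region) and the lowest-AIC converged fit is selected, with
AIC = −2ℓ_R + 2q over the variance parameters.  Genotype reliability is
r_i = 1 − PEV_i/σ²_G from the BLUP prediction-error variance;
environments with mean reliability below 0.3 are excluded from the joint
analysis (strict comparison, boundary retained).

## One-stage factor-analytic MET model

The joint model has fixed environment main effects and genetic covariance
(ΛDΛ′ + Ψ) ⊗ Gₙ; D is fixed to the identity during fitting (scale absorbed
into Λ) and only the rotated solution is interpreted.  Non-genetic
covariance is block-diagonal per environment, σ²ⱼ Bⱼ, where the shape Bⱼ
(autoregressive correlations plus row/column variance ratios) is frozen at
the single-trial selected fit and only the scale σ²ⱼ is re-estimated — the
package's analogue of recycling converged single-trial parameters as
starting values.

Two engines maximise the same residual likelihood (constants included, so
the objective is directly comparable to a dense-matrix evaluation):

* **EM engine** (general): mixed-model equations in the whitened genotype
  basis u = (I ⊗ QΓ^{1/2})w from the eigendecomposition of Gₙ (rank-reduced
  when the kernel is singular), with closed-form EM-REML updates; the FA
  structure is refreshed each iteration by an inner factor-analysis EM on
  the complete-data covariance, keeping the overall iteration a monotone
  generalised EM.  Convergence: relative log-likelihood change < 1e−6,
  cap 200 iterations.  Handles sparse partially replicated designs and
  fixed spatial shapes; dense algebra, intended for roughly p ≤ 30
  environments and a few hundred genotypes.
* **Balanced engine** (complete designs, independent residuals): the
  likelihood decomposes into within-cell contrasts plus a matrix-normal
  cell-mean model diagonalised by the kernel eigenbasis, making every
  evaluation O(np²); maximised by L-BFGS-B over loadings and log-variances.

Warm starts follow the model ladder: DIAG from single-trial variances, FA1
from DIAG (half the specific variance seeded into the first loading
column), FA_k from FA_{k−1} plus a small seeded extra column.  Genotype
scores are the conditional modes f̃ = Û Ge⁻¹Λ, which share the kernel
regularisation of the environment-specific BLUPs Û.  Parameter counts for
AIC/BIC: pk − k(k−1)/2 loadings, p specific variances, p residual scales.

Rotation takes the SVD of Λ: loadings become the orthonormal left singular
vectors, D the squared singular values (non-increasing), and scores are
counter-rotated so fitted genetic values are unchanged; each factor's
loading sum is made non-negative and the first factor majority-positive.
Zero loadings map to 'p' in iClass strings (the boundary is measure-zero);
singleton classes merge iteratively into the class with the highest mean
genetic correlation to the lone environment, recomputed after each merge.
Environments with negative first-factor loadings are flagged (overall
performance does not apply to them) rather than treated specially.

## EC bridge

Per-EC Pearson correlations with each target use a permutation null (the
target shuffled; 95 % band from the pooled 2.5/97.5 percentiles).  Stage-2
models: random forest with 500 trees, a third of the covariates tried per
split and node size 5; LASSO on standardised predictors with the fixed grid
of 100 penalties between 1e−8 and 0.04 selected by 10-fold CV (the grid is
calibrated to loading-scale targets; `LassoCV` computes the path); PLS with
the component count chosen by inner leave-one-out CV capped at
min(10, p−2).  Each loading and the main effect is modelled as a separate
univariate target.  One master seed fans out per (method, target, fold).

Leave-one-environment-out predictive ability is reported as the
**fold-centred** correlation: observed and predicted values are taken as
anomalies from each fold's training mean.  The naive pooled correlation is
biased by leave-one-out mean reversion — a model with no signal predicts
the training mean, which is exactly anti-correlated with the held-out value
(a fully shrunk LASSO scores −1 by identity) — whereas the fold-centred
estimator scores such models 0 and leaves genuine signal essentially
unchanged.  RMSE keeps the plain definition with denominator p.  Mean-
variance adjustment standardises predictions with (e−1)-denominator
variance and rescales to the observed mean and variance (exact by
construction and idempotent); grid predictions of main effects instead use
the intercept/slope of the observed-on-out-of-fold-predicted regression.
Predicted loadings are not variance-adjusted before iClass derivation
(switchable); the class string is always the sign pattern of the predicted
loadings.

## Forward cross-validation

Folds hold out all environments from the cutoff year onward.  The ladder:
MM (one genetic effect per genotype everywhere), DIAG (training-environment-
averaged effects), FA_k (environment-specific EBLUPs main_j + Σ Λ̂_jr f̃_ir
with test-environment loadings and main effects predicted by a stage-2
random forest refit inside the fold on training environments only).
Genotypes absent from the training fit are predicted through the kernel
(conditional mean given fitted genotypes).  Ground truth in each test
environment is the genotype-effect vector from that environment's
single-trial fit, not the simulation truth.  Checks (multi-year genotypes)
are the "tested" group, single-year cohorts "untested".  Comparisons
against MM use paired two-tailed t-tests on within-environment predictive
abilities; a constant nonzero difference vector (zero variance) is reported
with a capped statistic and p = 0, an all-zero one with t = 0, p = 1.

## Synthetic data

The generator defines the study conditions.  Weather: a sinusoidal annual
cycle written on the daily maximum temperature (southern-hemisphere summer
peak in mid-January; default mean 22 °C, semi-amplitude 7 °C, diurnal range
12 °C) with AR(1) daily noise (sd 2.5 °C, autocorrelation 0.6), rainfall as
a seasonally weighted Bernoulli–Gamma process (winter- or summer-dominant;
default 420 mm/yr), radiation tracking the temperature season and VPD
increasing with the daily maximum.  Series cover the calendar year plus the
following January–April so late grain fill is never censored.  Every stream
is split per (module, location, year, genotype) from the master seed, so
adding environments never perturbs existing ones.

Soils: a per-location heaviness index drives the clay/sand balance, water
capacity and cation exchange, and a fertility index the carbon/nutrient
profile, over the six standard depth layers; texture closes to 100 %.
Horizon depths use fixed defaults so they drop out of zero-variance
filtering, leaving exactly the 90 soil ECs of the default attribute set.

Genotypes: fully inbred founders with block-correlated alleles (blocks of
8 markers, within-block correlation ~0.9) and gene-dropping through the
pedigree (recombination 0.02 between adjacent in-block markers, free
between blocks; seven selfing generations; backcrosses to the F1), so the
panel carries realistic LD for imputation and pruning, residual
heterozygosity ≤ 2·0.5⁷, and Purdy strings that round-trip the parser.

Trials: year-specific cohorts plus multi-year checks; the single/double
replicate mix (default 70/30) applies to all entries, reproducing a ~70 %
single-replicate share; plot errors combine row/column effects and an
ar1 × ar1 residual field.  True main effects and loadings are configured
functions of named ECs (standardised across environments) plus noise, and
genetic values are drawn with covariance (ΛΛ′ + Ψ) ⊗ Gₙ.

Two compact benchmark generators skip the weather model and draw ECs
directly: the bridge benchmark (p = 60, w = 150, ECs in blocks of 10 with
within-block correlation 0.9, a 5-EC signal with one dominant driver,
population R² = 0.7) and the forward benchmark (complete designs, 40 checks
across all years plus a 30-line test-year cohort, loadings nearly
deterministic in single ECs under "strong" GEI or constant under "none").

## Problem sizes and limitations

Default analyses run at desk scale: 12 environments × 80 lines for the
end-to-end pipeline, p = 60 for the stage-2 benchmark, 24 environments ×
70 genotypes for the forward benchmark, 120 × 60 marker panels for the
imputation experiment.  The generators emulate the structure of real trial
networks but not everything about real data: no genotype-specific
phenology, no biotic stresses, weather noise is stationary within seasons,
and EC collinearity is stylised.  Passing tests therefore demonstrate that
the estimators recover known structure under the stated generative
assumptions, not field-data performance.  With only ~12 environments the
leave-one-environment-out bridge is weakly powered (the paper-scale regime
is represented by the p = 60 benchmark), dense algebra limits the mixed
models to tens of environments and a few hundred genotypes, and the
iClass/mega-environment stages inherit all upstream generalisation error.
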