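# Methods

This note documents the models, numerical choices and limitations behind
`soilspec`. It covers the synthetic-library generator, the pre-treatment
chain, sample selection, calibration, and the validation statistics, in
that order.

## Synthetic spectral libraries (`soilspec.synth`)

The generator produces libraries whose *marginal statistics* and *spectral
confounds* emulate a continental-scale topsoil survey (the LUCAS library is
the template), so that downstream stages can be exercised under realistic
conditions with known ground truth.

**Properties.** Mineral SOC is drawn from a lognormal truncated to
[0, 200] g C kg⁻¹ whose parameters are solved numerically (at import time,
`scipy.optimize.fsolve` on the truncated-moment equations) so that the
*truncated* law has mean 29.4 and SD 28.9 g C kg⁻¹ — the published mineral
summary statistics; the lognormal shape matches the strong right skew
(≈ 2.7) of field SOC data. Organic-material SOC is a Beta law rescaled to
[156.4, 586.8] g C kg⁻¹ with moments matched to mean 387.1 / SD
101.2 g C kg⁻¹; the implied mild negative skew emerges from the moment
match rather than being imposed. Textures (clay/silt/sand) come from a
Dirichlet with means (18.9, 38.2, 42.9) % and concentration 8, chosen so
the clay SD is ≈ 13 %; the composition closes to 100 % by construction.
Organic samples carry no texture (texture analysis is not performed on
organic materials), nitrogen tracks SOC with a lognormal multiplicative
scatter, and CaCO₃/pH/CEC follow simple laws with the published means.
Every sampler is a pure function of `(n, subset, seed)`.

**Mineral vs organic.** `classify_organic` implements the clay-dependent
definition of organic soil material: the SOC threshold rises linearly from
120 g C kg⁻¹ at 0 % clay to 180 g C kg⁻¹ at ≥ 60 % clay, with 120 used when
clay is missing. A flat 200 g C kg⁻¹ cut would contradict the organic
subset's observed minimum of 156.4 g C kg⁻¹; the ramp is an interpretation
of the FAO definition, not a claim about the reference survey's exact rule.

**Spectra.** Absorbance is additive (Beer–Lambert-like):

    A(λ) = a₀ + a_sand·sand/100 + δ·1{λ ≥ 1100 nm}
           + Σ_b g_b · x_driver(b) · enh_b(sand, clay) · exp(−(λ−c_b)²/2w_b²)
           + noise,

converted to reflectance R = 10^(−A) on a 400.0–2499.5 nm grid at 0.5 nm
(4200 bands). The default band catalog places the organic-matter feature at
620 nm (driver SOC), clay-lattice/bound-water features at 1415, 1455, 1915
and 2207 nm (driver clay), iron-oxide electronic transitions at 540, 640
and 900 nm (driven by CEC as a mineralogy proxy — the property schema
carries no iron column), and an organic N–H/C–H region at 2100 nm (driver
nitrogen). Two documented confounds act multiplicatively on the 620 nm
gain: sand *enhances* the feature by (1 + 0.8·sand/100) (scattering
increases effective path length) and clay *masks* it by
1/(1 + 1.5·clay/100). Both magnitudes were fixed once so the qualitative
orderings seen in real libraries hold (deeper SOC feature at higher sand,
shallower at higher clay); the functional forms are free design choices.
At zero noise the continuum-removed 620 nm depth is strictly increasing in
SOC and strictly decreasing in clay — a tested invariant.

**Noise model.** Three seeded noise sources, all defaults in
`BandCatalog`:

- per-scan, per-band absorbance noise, SD 0.005 (two scans per sample;
  comfortably below the 0.01 QC threshold, mimicking the small fraction of
  removals seen in practice);
- a per-*sample* flat baseline offset, SD 0.02 absorbance, shared by both
  scans (scatter variability; removed by derivatives/SNV, invisible to the
  between-scan QC — deliberately, since it is a sample effect, not a scan
  effect);
- laboratory replicate noise, SD 2.0 g C kg⁻¹, applied to the reported SOC
  and to the optional duplicate analyses (the mineral-soil reproducibility
  error of the reference method is ≈ 2 g C kg⁻¹), so SEL estimates this SD
  consistently.

The splice artifact is injected as a +0.02 absorbance step for bands
≥ 1100 nm so the splice correction has something real to remove.

**What the generator does not emulate.** Radiative transfer, geography and
soil-type frequencies, CaCO₃/pH spectral effects, wavelength-correlated
instrument noise, and non-stationary property–spectrum relationships.
Passing recovery tests therefore demonstrates that the pipeline machinery
is correct and leak-free, not that comparable accuracy would be reached on
real soils — real libraries are harder (the published continental models
reach RPD ≈ 1.7–2.9, whereas the synthetic library admits RPD ≈ 4).

## Pre-treatment (`soilspec.preprocess`)

Order of operations (fixed in `build_design_matrix`): scan averaging + QC →
absorbance → splice correction → trim at 500 nm → SG / SNV per recipe →
1-in-20 decimation. Choices that were genuinely open:

- **QC statistic**: per-band SD between scans (n−1 denominator) averaged
  over bands, compared against 0.01 absorbance. Samples failing are
  excluded and listed; single-scan samples pass through with a warning.
- **Splice correction**: an additive offset is applied to all bands
  ≥ 1100 nm so the first long-detector value equals the extrapolation of a
  quadratic through the last three short-detector values. A two-point
  linear extrapolation was rejected: with an absorption-band shoulder
  crossing the splice its curvature error (~10⁻⁹ absorbance on the default
  catalog) exceeds the exactness we require of offset recovery; the
  quadratic brings it to ~10⁻¹².
- **Trim convention**: drop [400, 500) and keep 500.0 nm — this yields
  exactly 4000 bands and, with decimation anchored at the first post-trim
  band, exactly 200 predictors at 10 nm spacing. Whether "~200" should be
  200 or 201 depends on unstated grid endpoints; the grid is configurable.
- **Savitzky–Golay**: `scipy.signal.savgol_filter`, window 101, polyorder
  3; edge windows are handled by evaluating the terminal window's fitted
  polynomial at off-centre positions (`mode="interp"`), keeping the grid
  length intact for the decimation arithmetic. Derivatives are in
  absorbance per band step (0.5 nm), recorded in provenance; no rescaling
  is applied since downstream models are scale-equivariant.
- **SNV** standardizes each spectrum with its own mean and SD (n−1); it
  runs after SG and before decimation, so the ~200-band rows are only
  approximately standardized — the exactly standardized object is the
  4000-band SNV stage output.
- **Continuum removal** divides reflectance by its upper convex hull
  (endpoints pinned, hull points map to 1). The hull is computed by qhull
  with a monotone-chain extraction of the upper chain and a collinear
  fallback; an O(n²) all-chords oracle verifies it in the tests.

## Sample selection (`soilspec.select`)

PCA is an exact eigendecomposition of the column-centred matrix's
covariance; for wide matrices (n < p) the Gram matrix is decomposed
instead, which is algebraically identical and much faster for 4200-band
spectra. Retention is the minimal prefix of components whose cumulative
explained variance exceeds 0.99. "Normalized score space" is interpreted
as per-component unit-variance scaling of the retained scores (a
Mahalanobis-like metric in the retained subspace); the normalization
constants are stored for projecting new samples.

Kennard–Stone is fully deterministic: the initial pair is the global
farthest pair, each subsequent point maximizes the distance to its nearest
assigned neighbour, and all ties break to the lowest sample index
(recorded in the result). The maximin distance trace is checked
non-increasing on every run, and the implementation matches an O(n³)
brute-force oracle on hundreds of random instances. The train fraction
(default 2/3) is converted to a count by rounding half away from zero.

Note that with the default noise model the 99 % variance prefix on
continuum-removed spectra retains hundreds of components at n = 1000 (the
band-wise noise floor is high-rank); the two leading components still carry
~95 % of the variance and dominate the selection geometry.

## Calibration (`soilspec.calibrate`)

**PLS core.** Univariate NIPALS: weights w ∝ Xᵀy (unit norm), scores
t = Xw, loadings p = Xᵀt/tᵀt, deflation X ← X − tpᵀ, y ← y − qt;
coefficients are mapped back to the original predictor scale via
B = W(PᵀW)⁻¹q. Successive scores are orthogonal (tested to 1e−8), and with
full components the predictions equal ordinary least squares on full-rank
tall problems (tested to 1e−6 against a normal-equations oracle, and
cross-checked against an independent PLS implementation). A constant
response yields the degenerate mean model (zero coefficients) rather than
an error, so resampling loops never die on a pathological half-split.

**Tuning.** Ten random half-partitions (each sample held out with
probability 0.5) are drawn once per tuning seed and reused across the whole
grid; each partition's held-out half is predicted once, giving ten RMSE
resamples per grid point (the swapped-halves variant with twenty resamples
was rejected to keep the stated resample count of ten). Degenerate
partitions (constant response in either half) are redrawn and logged. The
one-SE rule returns the least complex grid point whose mean CV RMSE is
within one standard error (SD/√10) of the minimum; for PLS, complexity is
the number of latent variables (default grid 1–20), and each plugged
family declares its own ordering.

**RFE.** The full model (tuned on all predictors) supplies an importance
ranking — for PLS, |coefficient| × SD of the predictor, i.e. the
standardized coefficient magnitude; tree families use their intrinsic
importances. Each size in the descending sequence (default
{all, 100, 50, 25, 10}) keeps the top-ranked predictors and is scored by
the same CV machinery; the lowest CV RMSE wins, ties to the smaller size.

**Auxiliary fusion.** Sand and/or clay columns are attached either to the
>99 %-variance PC scores of the spectral matrix (so one auxiliary column is
not outweighed by hundreds of collinear bands) or, after RFE has reduced
the matrix to its intrinsic dimensionality, to the selected bands directly;
the fused matrix is column-standardized. All PCA/scaling constants are
computed on training rows only and frozen for test-time projection — the
no-leakage property is tested. Auxiliary predictors are refused for
organic samples, which have no texture data.

**Families.** PLS is the implemented core. Random forest, boosted trees
and radial-basis SVR are exposed through the `ModelFamily` contract
(fit/predict/complexity/importance) backed by scikit-learn; re-implementing
them is out of scope, and SVR, lacking an importance measure, cannot drive
RFE.

## Validation (`soilspec.validate`)

Definitions as in the README. Numerical conventions: SEP₋b uses the n−1
denominator, so the decomposition identity carries its exact (n−1)/n
factor — RMSEP² = bias² + (n−1)/n·SEP₋b² holds to machine precision rather
than the approximate additivity sometimes quoted. RPD is defined as
SD/RMSEP (not SD/SEP₋b): re-deriving the published benchmark rows from
their printed cells reproduces the printed RPD only under this definition
(100.8/50.6 → 1.99, whereas 100.8/49.5 → 2.04). R² defaults to the squared
Pearson correlation, with 1 − SSE/SST available via `r2_method="ssr"`; the
two differ under bias, and the default is the more common convention in
spectroscopic reporting. SEL uses the duplicate-pair form √(Σε²/2n), a
consistent estimator of the replicate SD. Report tables round half away
from zero (decimal arithmetic, so exact halves like 2.615 round up), one
decimal for g C kg⁻¹ columns, two for RPD and R². A perfect prediction
reports RPD = ∞; constant observations are rejected since SD and RPD are
then meaningless. Relative RMSEP per SOC × covariate class is RMSEP(cell)
divided by the cell's mean observed SOC; cells with fewer than three
samples report NaN with their count — undefined cells are data, not
failures.

## Problem sizes in the test and acceptance runs

Moment-matching tests use n = 10⁴ draws. Oracle-equivalence suites use 200
Kennard–Stone instances (n ≤ 40), 100 random spectra for continuum removal,
three window/order settings for SG, and 20 random full-rank problems for
PLS-vs-OLS. The end-to-end recovery study runs 100 seeded experiments on
1000-sample mineral libraries (SG1 + PLS, spectra-only vs sand-fused
sharing one design matrix and split per seed); the reproducibility study
uses 100 seeds × 200 duplicate pairs. `scripts/acceptance.py` performs one
recovery experiment at the given seed plus all deterministic re-derivations.

## Known limitations

- The generator's property→spectrum map is additive-Gaussian with two
  multiplicative confounds; real soil spectra have richer nonlinearities,
  so linear PLS looks better here than it would in the field.
- Band-wise independent scan noise makes the 99 % PCA prefix high-rank;
  real instrument noise is wavelength-correlated.
- The Kennard–Stone split is deterministic and space-filling in score
  space, but no stratified or SOC-balanced alternatives are provided.
- Cubist and MARS, used by the reference workflow, have no open
  implementation in the dependency set and enter only as contract slots.
- The organic/mineral threshold ramp is an interpretation of the FAO
  definition; applications with a different convention should pass their
  own classification.
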