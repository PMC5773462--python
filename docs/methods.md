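# Methods

## The modeling problem

The outcome is the FDG uptake intensity of a biopsied metastatic lesion,
quantified as SUVmean35 (mean SUV inside a 3D isocontour at 35% of the
maximum pixel value) and modeled on the base-2 log scale, where its
distribution is close to normal and on a scale comparable to microarray
log-intensities. The predictors are p ≫ N microarray probes. The
pipeline is: univariate screening of standardized probes → threshold and
component count by cross-validation → a latent-component regression
(PLS with 3 components as the primary model) → internal validation by
repeated cross-validation and external validation on an independent
cohort → unsupervised clustering and gene-set (ssGSEA) diagnostics of
the selected probes.

## PET quantification

All formulas operate on VOI-level statistics; no partial-volume
correction is applied. Lean body mass uses the Janmahasatian sex-specific
equations with BMI = weight/height² (kg/m²); SUL = LBM·SUVmean35/weight;
SUVglu = SUVmean35·glucose/100 mg/dl; MTV is the thresholded VOI volume
in cm³ and TLG = SUVmean35·MTV. TLG uses SUVmean35 as its "SUV mean"
factor — the only mean SUV the record carries; an unthresholded VOI mean,
were it available, could be substituted trivially. Missing VOI volumes
propagate as explicit NaN markers through MTV/TLG and cohort summaries
rather than raising, since real cohorts contain patients without a
volume estimate.

Outlier fences on a reference sample are P1 − 1.5·(P3 − P1) and
P3 + 1.5·(P3 − P1). Percentiles use linear interpolation between order
statistics (numpy's default; the method is a keyword argument).
Classification is inclusive at the fences (≤ low fence / ≥ high fence),
the reference minimum itself is in range, and *influential* denotes the
open interval (low fence, reference minimum). The normality screen
reports Shapiro–Wilk and Lilliefors p-values — Lilliefors being the
Kolmogorov–Smirnov variant appropriate when mean and variance are
estimated from the sample — and flags normality when both exceed 0.05.

## Synthetic cohorts

The generator emulates the study design: a training cohort
(22,814 probes × 71 samples with 909 signal probes at full scale; the
committed analysis configuration scales this to 4,000 × 71 with 300
signal probes to keep a complete run interactive) plus an independent
validation cohort (n = 13) drawn from the same law, optionally with one
influential observation planted strictly between the training low fence
and the training minimum on the SUV scale while its expression profile
remains typical — so a trained signature overpredicts it, as happens
with a real patient whose uptake lies below the prediction range.

Probe intensities are Gaussian with probe-specific location
(μ_j ~ N(8, 1.5)) and scale (s_j ~ U(0.3, 1.2)). The planted signal
probes form a small number of sign-coherent co-expression modules
(default 3, within-module equicorrelation ρ = 0.7):
z_j = √ρ·f_b + √(1−ρ)·u_j, and

    log2 SUV = intercept + Σ_j c_j z_j + N(0, σ),     intercept = log2 6,

with all module members sharing the sign of their coefficients and both
signs present across modules. **Why modules rather than independent
probes:** with independent signal probes the univariate signal-to-noise
per probe is bounded by √(n/n_signal) no matter how large the
coefficients — every other planted probe contributes residual variance —
so at n ≈ 70–100 with tens to hundreds of signal probes a sparse
independent signal is undetectable by univariate screening, and no
parameter-recovery statement could hold. Co-expressed transcriptional
programs (up-regulated proliferation/ribosome-biogenesis-like modules,
down-regulated stromal/cytoskeleton-like modules) are both the realistic
structure of expression data and the regime in which univariate
screening works at these sample sizes. Setting ρ = 0 recovers the
independent special case used by exact-recovery unit tests. The
phenotype variance implied by this law,
Σ_b [ρ(Σ_{j∈b} c_j)² + (1−ρ)Σ_{j∈b} c²_j] + σ², is stored with the
ground truth and checked by a Monte-Carlo test.

A fraction of background probes (default 20%) carries tumor-type
structure: per-type mean shifts (sd 0.7) for 8 nominal histologies.
Without it, the only structure in the full matrix would be the planted
signal, and the all-probe "negative control" clustering would not be a
control at all; with it, histology dominates the full-matrix variance,
as in real cohorts. Default noise is σ = 0.4 on the log2 scale and
default per-probe effect sizes |c_j| ~ U(0.001, 0.0021) at the full 909-
probe scale, putting the planted signal near 75% of phenotype variance
and sd(log2 SUV) ≈ 0.8 — a realistic uptake spread. Training phenotypes
are redrawn (signal and noise together, so expression stays consistent)
until the cohort is free of IQR outliers on the log2 scale, matching the
curated-cohort contract; validation phenotypes are likewise redrawn to
lie inside the training range unless the influential flag asks
otherwise.

PET covariates are drawn uniformly over typical adult-oncology ranges
(weight 45–95 kg, height 1.50–1.90 m, glucose 66–149 mg/dl) and VOI
statistics are made internally consistent with the generated SUVmean35;
they exist to exercise the quantification module, not to model
covariate–expression dependence. Gene symbols are assigned with a fixed
unannotated fraction (default 62/909) and a gene pool smaller than the
probe count so some genes carry several probes. Synthetic gene sets are
sampled either from positive- or negative-coefficient signal genes
("enriched") or uniformly ("null").

What passing tests on these cohorts do **not** show about real data:
microarray artifacts (batch, dye bias), heavy-tailed intensities,
annotation errors, covariate–expression confounding and
histology-uptake correlation are all absent, so real-data performance
claims require real cohorts.

## Feature selection and tuning

Standardization is per probe with the n−1 convention; constant probes
are removed with a warning; training means/sds are frozen and applied to
validation data. β_j is the OLS slope of y on the probe (on standardized
probes, r·sd(y)); selection is inclusive (|β| ≥ θ) and probes without a
gene symbol are retained. Cross-validation of (θ, m): folds are a seeded
random partition; within each training fold, probes are re-standardized
and re-scored (no leakage; a pure-noise test asserts the held-out error
is not deflated), the reduced matrix's principal components are computed
by SVD with component signs fixed so the largest-magnitude loading is
positive, y is regressed on the first m scores, and held-out samples are
projected with the fold's frozen parameters. The objective is pooled
held-out RMSE; grid ties break toward larger θ (fewer probes), then
smaller m — parsimony.

## PLS, PCR and VIP

PLS1 is implemented as NIPALS, which for a single response is closed
form per component (no iteration or tolerance): w_a ∝ Xᵀ_a y_a,
t_a = X_a w_a, p_a = Xᵀ_a t_a/tᵀ_a t_a, q_a = yᵀ_a t_a/tᵀ_a t_a,
deflation X_{a+1} = X_a − t_a pᵀ_a. The compact coefficients
b = W(PᵀW)⁻¹q reproduce the staged predictions in one matrix product;
the intercept is the training mean of y (predictors centered). SIMPLS
would give identical results for one response up to numerical detail;
NIPALS was chosen for its deterministic per-component closed form.
Requesting more components than min(n−1, p) — or than the matrix can
support once deflated — raises an error naming the achievable maximum.
VIP accumulates over all retained components (the standard definition;
a per-component reading of "the VIP of the third component" would
discard the first two components' contributions and break the
mean-square-1 identity); Σ_j VIP²_j = p holds by construction and is
asserted at 1e-6 on every fit. The VIP ≥ 1 selection reports the
fraction of unannotated probes inside and outside the cut with a Fisher
exact test. PCR regresses y on the first m SVD scores with the same
sign convention.

## Model comparison and validation

Repeated CV uses seeded random partitions identical across models, so
the 50 resamples (k = 10 × 5 repeats) are paired; standardization and
feature selection are refit inside every training fold. R² is the
squared Pearson correlation of observed and predicted values (undefined
— NaN with a warning — for constant vectors, e.g. single-sample folds).
Summaries report mean, SD, and both the empirical 2.5/97.5% resample
quantiles and a parametric mean ± 1.96·SD interval, labeled separately,
since either convention is defensible for a resample spread. Pairwise
comparison: paired t on RMSE, Wilcoxon signed-rank on R², both
multiplied by the number of pairs actually compared (6 for 4 models) and
capped at 1. External validation freezes the trained signature and the
training standardization; validation samples are classified against IQR
fences of the raw training SUV — outliers are excluded a priori (as in
cohort curation), influential observations are reported both ways
(rmse_all vs rmse_excluding_influential), and the per-sample table
carries measured/predicted SUV on both scales plus the fold ratio. The
stability sweep retrains selection + PLS per threshold, plus
positive-only and negative-only variants at a reference threshold, and
records failed (empty-selection) variants instead of aborting.

## Clustering and enrichment diagnostics

Sample distances are 1 − Spearman ρ between standardized expression
columns (average ranks for ties); agglomeration is complete linkage; the
tree is cut at k = 5 (configurable). Raw SUVmean35 is compared across
clusters by one-way ANOVA with unadjusted pairwise t-tests (singleton
clusters enter the ANOVA but skip pairwise tests, with a warning). The
negative control runs the identical pipeline on all probes.

ssGSEA ranks genes per sample (higher expression → higher rank, ties by
stable input order), weights ranks by |rank|^α with α = 0.25, and scores
a set as the integrated difference between the in-set weighted ECDF and
the out-of-set uniform ECDF; the score matrix is normalized by its
global max − min. Probe→gene summarization keeps, per gene, the probe
with the largest mean intensity ("probe" mode — one coherent probe per
gene; a per-sample max mode is available but mixes probes across
samples), and drops unannotated probes. Scores are correlated per set
with log2 SUV (Pearson, two-sided p).

## Calibrated study conditions and problem sizes

Two Monte-Carlo experiments were calibrated once, before their
thresholds were frozen into tests, and are reported by
`scripts/acceptance.py`:

* **Parameter recovery** — 2,000 probes × 100 samples, 50 signal probes
  in 3 modules (ρ = 0.7), |c| ~ U(0.05, 0.15), σ = 0.3, 20 seeds. The
  top-50 |β| set recovers ≈ 95–97% of planted probes (calibration mean
  across seed batches 0.95–0.97), and the tenfold-CV RMSE of the
  PLS-3 pipeline averages 0.35–0.39, inside the band [σ, σ + 0.25].
* **Clustering contrast** — 4,000 probes × 71 samples, 300 signal
  probes, σ = 0.4, 20 seeds: signature-probe clustering gives a smaller
  SUV ANOVA p than all-probe clustering in ≥ 19/20 cohorts (sign test
  p < 1e-4), with median p ≈ 1e-8 vs ≈ 0.01–0.5.

These scaled-down sizes (rather than 22,814 × 71 everywhere) were chosen
so the whole suite and the acceptance script each run in well under a
minute; the generator and pipeline accept the full scale unchanged, and
the 22,814-probe defaults of `SyntheticConfig` are exercised directly in
calibration (tenfold-CV RMSE mean 0.48 at σ = 0.4, inside [0.4, 0.65]).

## Numerical choices and degenerate inputs

sd uses n−1 throughout; percentile interpolation is linear; PC and PCR
component signs are fixed by the largest-magnitude loading; NIPALS
degeneracy (exhausted rank) raises with the achievable component count;
empty probe selections raise with advice to lower the threshold (or are
recorded as failed sweep variants); constant probes/columns are removed
or named in errors; disjoint gene sets score NaN with a warning; R² of a
constant vector is NaN, excluded from summaries. All stochastic stages
take explicit seeds; the pipeline fans one master seed out to per-stage
seeds recorded in the run report, and TSV/CSV artifacts carry a
provenance comment header (tool version, stage, config hash).

## Known limitations

The comparator models (SVR, random forest) delegate to scikit-learn and
are compared, not re-derived. The supervised-components CV objective is
held-out RMSE; likelihood-ratio scoring variants exist and may choose
different thresholds. The generator's module structure is exchangeable
and Gaussian; it cannot surface failure modes tied to heavy tails,
nonlinear probe–outcome relations, or confounded covariates. Clustering
k is fixed by configuration, not chosen from the data.
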