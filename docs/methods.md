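# Methods notes

This note records the modeling assumptions, parameter choices, and
numerical conventions behind `latgrad`, in the spirit of the methods
documentation of simulation-first scientific packages.

## 1. The analysis model

### Language metrics

Connectivity is Pearson correlation between region-averaged BOLD series.
Scan-level matrices are Fisher-z transformed, averaged across scans, and
back-transformed with tanh; |r| is capped at 1 − 10⁻⁷ before atanh so
degenerate (perfectly correlated) inputs keep finite z. The diagonal is
stored as 0 and excluded from every sum.

Per subject the five metrics are: network and hub task-beta asymmetry
(mean over flagged left ROIs minus flagged right ROIs, contrast units);
homotopic inter-hemispheric connectivity (mean Fisher z over language
homotopic pairs); and language strength sum and asymmetry. Strength of a
language ROI is the sum of its r values to the *other* language ROIs of
the same hemisphere — the self term is excluded as degenerate; including
it would only add a constant and leave every asymmetry sign unchanged.
Strength is computed on r values (after the tanh back-transform), not on
z values, and negative correlations enter the sums as-is (no
rectification or thresholding).

### Phenotype classification

The five metrics are z-scored (sample SD, ddof = 1 — the scale estimator
is a recorded convention, not a substantive choice) and clustered
agglomeratively with Euclidean distance and Ward's minimum-variance
criterion in the Ward.D2 convention (merge heights in distance units).
`k = 3` is the committed default; the supporting diagnostic is an
ordinary-bootstrap mean Jaccard similarity between the full-data clusters
and clusters found on resampled data, per candidate k. This replaces the
multiscale-bootstrap AU p-values and the 26-index consensus suites of the
wider literature with a single bounded-scope stability score; values near
1 mean the partition is reproducible under resampling. Clusters are named
by their mean raw network task asymmetry: highest → strong typical,
middle → mild typical, lowest → atypical, with ties broken by the hub
asymmetry mean. If the lowest cluster's mean is not negative it is still
named atypical and a warning is recorded, since the naming is positional.

### Gradients

Per subject: row-sparsify the connectivity matrix keeping the
⌈retained·(n−1)⌉ largest off-diagonal entries per row by **signed** value
(default retained = 0.10, i.e. sparsity 0.9; ties keep the lowest column
index); normalized-angle similarity s = 1 − arccos(cos θ)/π between rows;
diffusion-map embedding with anisotropic normalization α = 0.5 and
multiscale scaling λ/(1−λ) (diffusion_time = 0). Both α and the time
convention are exposed in `GradientConfig`. Variance explained is
reported as λ²ᵢ/Σλ² over the nontrivial spectrum; the eigenvalue
normalization behind "percent variance" is itself a convention and no
result in this package depends on reproducing a specific split.

The group template is the embedding of the cohort-mean connectivity
matrix (z-averaged, tanh back-transformed) — the standard choice where a
"group-level gradient" is otherwise unspecified. Eigenvector signs are
arbitrary; template components are oriented by positive correlation with
the within-hemisphere serial position of the atlas rows (which run
unimodal → association), so the association end of gradient 1 is
positive, and individuals inherit orientation through alignment.
Individual embeddings are aligned to the template by orthogonal
Procrustes (rotation/reflection, no scaling), iterated 10 times with the
template refreshed as the mean of the aligned set. Values are then
min-max scaled to 0–100 per component over the whole brain, and network
asymmetry is the left-minus-right mean per canonical network.

### Group statistics

Each outcome is modeled by OLS with phenotype, covariates (age, sex,
intracranial volume, handedness class), and the handedness × phenotype
interaction. The phenotype main effect uses Type-II sums of squares by
model comparison — the interaction is excluded from both the reduced and
augmented model, and the error term comes from the full model; this
respects marginality and reduces to the textbook F = t² identity in the
two-group, no-covariate case. Post-hoc contrasts: Tukey's range test
(exact studentized-range distribution) across the three phenotypes;
two-sided Student's t on the covariate-adjusted model for binary
typical-vs-atypical contrasts. Network grids apply Bonferroni for n = 7
tests (family significance at raw p ≤ 0.05/7). Handedness class uses the
score cut < 30; sex enters as a female indicator; reference levels are
recorded in the coefficient table.

### Heritability

The polygenic model is y ~ N(Xβ, σ²_g·2Φ + σ²_e·I) with expected
relatedness 2Φ = 1 (MZ co-twins), 0.5 (DZ co-twins and full siblings),
0 (across families), 1 on the diagonal (no inbreeding). Estimation is
maximum likelihood: the kinship matrix is eigendecomposed once, the model
is rotated into the eigenbasis where the covariance is diagonal, and the
profile likelihood in h² = σ²_g/(σ²_g+σ²_e) is maximized by bounded
scalar search (β and the total variance are profiled out analytically).
ML is the default so nested-model likelihood-ratio p-values are
consistent; REML is available for SE-only use. The h² = 0 null lies on
the parameter boundary, so T = 2Δlog L is referred to the 50:50 mixture
of a point mass at zero and χ²₁ (p = 1 at T = 0). Standard errors come
from a finite-difference observed information in (σ²_g, σ²_e) with the
delta method; exactly at a boundary the SE is reported unavailable. The
covariate set for heritability runs is age, sex, age², age × sex,
age² × sex, handedness, and intracranial volume. Binary phenotypes
(typical/atypical) are analyzed as 0/1 quantitative traits; a
liability-threshold model is out of scope, so those h² values are
attenuated relative to the liability scale and should be read as
lower-bound-flavored. Singletons are retained in the model by default —
they carry no kinship information but sharpen σ²_e and the covariate
fit. No shared-environment component is modeled.

## 2. The synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Latent gradient.** Each hemisphere's regions carry an equally spaced
latent coordinate g ∈ [0, 1], identical across hemispheres and ordered
unimodal → association, so the "true" first embedding axis is known and
recovery is testable. The seven canonical networks occupy contiguous
stretches of this axis; the language ROIs are the association-end
regions, two of them flagged as frontal/temporal hub analogues.

**Covariance.** The region covariance is built from
exp(−|gᵢ−gⱼ|/bandwidth), scaled by 0.65 within hemisphere and 0.30
across (bandwidth 0.20 — narrow enough that the latent axis dominates
the leading embedding direction rather than competing with the
hemisphere split), plus 0.10 for same-network pairs, 0.35 for homotopic
pairs, and the group's language-block boosts; off-diagonals are clipped
at |r| = 0.97, the matrix is floored to positive definite by eigenvalue
clipping at 10⁻⁶ and rescaled to unit diagonal. Scans are i.i.d. draws
from the resulting Gaussian process (default 4 scans × 200 time points,
40 regions per hemisphere, 9 language ROIs).

**Groups and effects.** A unit-variance latent asymmetry score is drawn
with additive-genetic family covariance h²·2Φ (default h² = 0.30).
Population-quantile cuts of the score assign groups at the configured
proportions (0.48/0.44/0.08), so MZ co-twins share phenotypes more often
than chance in proportion to h². Task-beta effects per group follow the
reported group profiles — network/hub means 1.74/2.64 (strong),
0.70/1.17 (mild), −0.96/−1.16 (atypical), in contrast units — assigned
as ±effect/2 per hemisphere so the noise-free network asymmetry equals
the group effect exactly; per-region Gaussian noise has SD 0.25, and a
within-group multiplier (1 + 0.1 × standardized within-group score)
couples effect magnitude to the heritable latent score. Resting-state
boosts make typical groups left-dominant in language strength, the
atypical group bilateral, and the mild group weaker in overall language
connectivity and homotopic coupling, mirroring the qualitative pattern
of the real phenotypes. The within-group dispersion is a free parameter
of the generator (the source analyses report group means, not
within-group latent variance); 0.1 was chosen once as a realistic
dispersion that keeps the phenotypes distinct, consistent with how
cleanly they separate empirically.

**Injection hooks.** For detection experiments, a configured offset can
be added to the latent coordinate of one network's left-hemisphere
regions, optionally restricted to selected groups.

**What is not emulated.** Hemodynamics, motion, scanner drift, spatial
geometry (no surfaces, no voxels), age/sex effects on the metrics, and
assortative or shared-environment family structure. Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery under the generating model — not robustness to the artifacts
of real fMRI.

**Determinism.** Every subject draws from an RNG stream keyed by
(master seed, subject index), so cohorts are byte-reproducible and
stable under subject-count changes. The pipeline chains stages through
TSV files with fixed numeric formatting; re-running any stage on
identical inputs reproduces identical bytes.

## 3. Numerical conventions and degenerate inputs

- Sparsification ties keep the lowest column index (stable argsort).
- Repeated eigenvalues of the affinity spectrum define their components
  only up to rotation within the eigenspace; orientation and comparison
  conventions therefore apply per simple eigenvalue, and the test suite
  compares degenerate blocks by eigenspace membership.
- Min-max scaling and standardization raise on constant inputs rather
  than silently dividing by zero; connectivity raises on constant
  region series, naming the region.
- Procrustes uses the SVD convention throughout; rank-deficient
  cross-products are handled by the SVD and are never fatal.
- The variance-components fit raises when the kinship matrix is
  (numerically) proportional to the identity, where σ²_g and σ²_e are
  not separately identifiable.
- Empty cohorts and empty pedigrees warn and return empty containers.

## 4. Problem sizes

Defaults were chosen so a full pipeline run and the complete test suite
execute comfortably on a single CPU: cohorts of 120 subjects
(40 regions/hemisphere, 4 × 200 time points) for end-to-end runs, 1000
subjects for phenotype-recovery measurements, 300 + 300 twin pairs for
heritability recovery, and 500–1000 replicates for calibration checks.
All of these are configuration values, not limits.

## 5. Known limitations

- The ANCOVA ignores family structure (no mixed effects); p-values for
  cohorts with many twins are anti-conservative to that extent.
- Binary-trait heritability is on the observed 0/1 scale, not the
  liability scale.
- The bootstrap Jaccard stability score is a diagnostic, not a test; it
  has no null distribution attached.
- The generator's covariance construction is stationary across time and
  subjects apart from the group/latent terms; temporal autocorrelation
  of BOLD is not modeled, so effective sample sizes per scan are larger
  than in real data at the same series length.
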