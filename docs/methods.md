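# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `landgea`. Everything quantitative stated here is
computed by the test suite (`tests/`) or by `scripts/acceptance.py`.

## 1. Data model

Genotypes are alternate-allele dosages (0/1/2, missing = -1) for diploid
individuals at biallelic SNPs, with one population label per individual.
The allele orientation ("alternate") is arbitrary but used consistently
everywhere, including polygenic scoring, which only requires a consistent
per-locus orientation. Population allele frequencies are exact counts:
freq = alt alleles / called alleles; a (population, locus) cell with no
called individuals is recorded as missing and mean-imputed with the
across-population mean of that locus before any ordination, so no locus is
dropped for sporadic missingness (the count is logged).

Variant filters reproduce the standard analysis-ready definition: overall
minor-allele frequency > 0.05 across all called genotypes, and presence in
at least 12 individuals in every population (both thresholds configurable).
Both rules are evaluated on the input matrix, making the filter idempotent.
Read-depth and base-quality filtering belong to the upstream calling stack
and are out of scope.

## 2. Synthetic metapopulation

The generator emulates a continent-scale small-mammal ddRAD design:

* **Drift** follows the Balding–Nichols model: below an ancestor at
  frequency p, a descendant draws from Beta(p(1-F)/F, (1-p)(1-F)/F), whose
  mean is p and whose expected F_ST to the ancestor is F. Drift compounds
  multiplicatively down a population tree. Two topologies are provided:
  a `star` (all populations independently diverged; closed-form expectation
  E[F_ST] ~ F, used for controlled experiments) and a `balanced` hierarchy
  over latitude-ordered sites (the default), whose per-level F values
  [0.25, 0.1, 0.05, 0.03] were calibrated once so that pairwise Hudson
  F_ST spans ~0.05 between neighbours to ~0.45 across the range with mean
  ~0.27 — the differentiation regime of a European-scale rodent
  metapopulation with glacial-refugium lineage structure.
* **Climate** at each site is a_v + b_v·latitude + Gaussian noise. Default
  slopes mimic bioclim gradients (temperature falling, seasonality rising
  with latitude); the noise scale is set to half the latitudinal signal,
  giving |cor(variable, latitude)| ≈ 0.9 and pairwise inter-variable
  correlations ≈ 0.8, in line with real continental bioclim sets. With
  three or more variables the last is latitude-independent. This
  geography–climate collinearity is the central confound the analysis must
  handle.
* **Selection** shifts the logit of the post-drift frequency of each
  selected locus by β·z, z being the standardized driving-variable value at
  the site; β is therefore an effect per SD of environment, and the neutral
  covariance of non-selected loci is untouched. Shifted frequencies are
  clipped to (0.001, 0.999) (logged) so selected loci are not removed
  wholesale by the MAF filter. Defaults: 2000 loci, 50 selected, β = 1.5,
  driving variable = the most latitude-collinear one.
* **Genotypes** are drawn with inbreeding: P(het) = 2p(1-p)(1-f_IS),
  default f_IS = 0.01 (study-scale inbreeding is low); 5% of calls are
  masked missing. Ancestral frequencies are U(0.1, 0.9), the range typical
  of SNPs that survive an MAF filter. Everything is reproducible bit-for-bit
  from one seed.

Loci are unlinked and the generator has no recombination, linkage or
range-expansion surfing; what passing tests show is that the estimators
recover the generating model's parameters and planted signals, not that
they are robust to LD or allele surfing in real data.

## 3. Diversity and differentiation

Watterson's θ_W = S/(a_{n-1}·L) and nucleotide diversity π (per-locus
unbiased heterozygosity 2p̂(1-p̂)n/(n-1), summed and divided by the number
of assayed sites L) are computed per population; because loci differ in
missingness, the n entering the harmonic number is 2 × the median number of
called individuals per locus. Tajima's D uses the standard variance
constants (a1, a2, b1, b2, c1, c2, e1, e2). Reported SDs of θ_W and π are
per-locus SDs of the per-site contributions. F_IS is the method-of-moments
1 - H_obs/H_exp over polymorphic loci.

Pairwise F_ST is Hudson's estimator from sample allele frequencies with the
ratio-of-averages combination across loci; negative pair estimates are
retained (they are informative about sampling noise), but linearized
F_ST/(1-F_ST) entries are clamped at 0 (logged) when used as a distance.
Tests verify the estimator against the closed-form plug-in value, against
brute-force allele-pair enumeration (π, θ_W exactly), and against the
Balding–Nichols expectation on the star tree (mean F_ST = 0.1 ± 0.02 at
F = 0.1, 5000 loci).

## 4. Structure, distances, Mantel tests

Structure covariates come from a Patterson-scaled PCA of the dosage matrix
(loci centered by 2p̂, scaled by sqrt(p̂(1-p̂)), missing cells mean-imputed,
monomorphic loci dropped); population scores are means of member
individuals. Four axes are retained by default (configurable via
`--structure-axes`; the scree-plot judgement is the user's). Climate PCA is
correlation-matrix PCA over sites; two components are used for the
univariate scans by default.

Geographic distance is great-circle (haversine, R = 6371.0088 km), natural
log-transformed for IBD regression; environmental distance is Euclidean on
standardized variables. Mantel r is the Pearson correlation over the
n(n-1)/2 site pairs; the null permutes rows/columns of the dependent matrix
simultaneously; one-sided p = (exceedances + 1)/(n_perm + 1), with full
enumeration available for small n. The partial Mantel test residualizes
both unrolled matrices on the control and permutes the dependent matrix
*before* residualization — the scheme with the better published type-I
behaviour. Calibration: 500 null replicates × 999 permutations give
empirical type-I error within 0.05 ± 0.02 and KS-uniform p-values for the
Mantel, partial-Mantel and RDA permutation tests.

## 5. Redundancy analysis

`fit_rda` column-centers the response (populations × loci frequencies) and
predictors; a conditioning matrix is removed from both sides by least
squares first (partial RDA), and the identity
pRDA(y, x | z) = RDA(resid(y|z), resid(x|z)) holds to 1e-10 by
construction. Constrained axes come from the SVD of the fitted values;
eigenvalues are fitted-covariance eigenvalues; R² is constrained variance
over the total variance of the (possibly residualized) response, matching
vegan's convention (verified against vegan's `rda()` in a test); the
Ezekiel adjustment 1-(1-R²)(n-1)/(n-p-1) uses p = rank of the predictor
matrix, with collinear columns dropped under a warning. "Species"-style
locus scores are unit loadings scaled by sqrt(eigenvalue); the SD-based
outlier rule is invariant to that scaling per axis.

The permutation ANOVA uses pseudo-F = (SS_constrained/p)/(SS_residual/
(n-p-q-1)); the null permutes the reduced-model residuals (rows of the
response when unconditioned). Per-axis p-values use the marginal scheme —
exceedance of the i-th constrained eigenvalue — chosen over forward
sequential testing for simplicity and determinism; per-axis tests are
reported but not used for any decision in the pipeline.

## 6. The three GEA scans and the consensus

**Latent-factor scan.** Two-stage latent-factor scans face an inherent
under/over-correction trade-off when the environment is constant within
populations: factors from a plain SVD of the dosage matrix that span the
full between-population space (k ≥ n_pops - 1) yield calibrated statistics
(raw λ ≈ 1.03 under a structured null) but absorb any population-level
environmental effect, leaving essentially no power; factors that miss even
one structure dimension leave λ seed-dependent. The default mode therefore
estimates the factors on the environment-orthogonalized dosage matrix —
the behaviour of the ridge latent-factor estimator in the small-penalty
limit — which keeps environment-aligned genetic variation out of the
correction and preserves power; the price is a raw λ well above 1 (≈ 6
under the controlled null), which the genomic-control step
(λ = median(z²)/median(χ²₁), p from χ²₁ of z²/λ) is there to absorb. Both
modes (`factor_mode="env_orthogonal"`/`"svd"`) are exposed; k defaults to
10 (the number of latent factors used in comparable 12-population studies).

**Covariance GLS scan.** Standardized frequencies (p_k - p̄)/sqrt(p̄(1-p̄))
are regressed per locus on (intercept, standardized environment) by GLS
with the among-population covariance Ω as error covariance — the same
design as Bayes-factor environmental-correlation methods, but
deterministic. Ω is estimated across loci from the standardized frequency
vectors, ridge-regularized (ε = 1e-4·trace/n) because population-centered
standardization leaves it rank-deficient, and refined once by re-estimating
on loci outside the first-pass top-5% |statistic| tail (the analogue of
estimating the covariance on putatively neutral control SNPs). Outlier
calling defaults to the upper 2.5% tail of |statistic| per environmental
variable — anchored on the per-method outlier rates observed in comparable
studies (2–3% of loci) and analogous to thresholding Bayes factors on
their upper tail, because a t test on n_pops - 2 = 10 degrees of freedom
cannot reach BH-significance at genome scale even for cleanly separated
loci — gated by nominal p < 0.005 so that nothing is force-flagged under a
pure null. BH-FDR calling remains available (`outlier_rule="bh"`).

**RDA scan.** Partial RDA of the frequency matrix on the climate variables
conditioned on the four structure axes; outliers load more than 3 SD from
the mean on either of the first two constrained axes (all thresholds
configurable).

**Consensus.** Candidates are loci flagged by ≥ 2 methods; this is where
the pipeline's false-discovery control lives (measured FDR ≤ 0.05 at the
operating point below). Pairwise method overlaps are reported both as
Jaccard fractions and per-method fractions, since "overlap" is ambiguous
between the two.

**Operating characteristics** (star tree, F = 0.1, 12 × 24, 2000 loci,
50 selected, medians over 20 fixed seeds): consensus sensitivity 0.69 and
observed FDR 0.03 at β = 1.5; null (β = 0) consensus size median 0 and
svd-mode λ median 1.04. Under the full study-emulation defaults
(hierarchical drift, mean F_ST ≈ 0.28, climate ≈ latitude ≈ drift tree)
structure and selection are nearly unidentifiable by construction: even a
GLS oracle given the true neutral covariance ranks planted loci only in
the top ~5% without reaching significance, and the pipeline correctly
returns almost no candidates. That regime demonstrates the confound, not a
power failure of the implementation.

## 7. Variance partitioning and attribution

Components are assembled from differences of full-model R²
(exclusive_climate = R²(climate ∪ structure) - R²(structure), etc.), which
makes exclusive + joint = total exact to machine precision, in raw and
adjusted form; permutation p-values come from the full and the two
conditional pseudo-F tests. Because "% of total" and "% of explained"
normalizations are both in circulation, outputs carry both, explicitly
labeled.

Per-locus attribution fits one single-variable pRDA per climate variable,
conditioned on the remaining variables, z-normalizes the axis-1 locus
loadings across loci and assigns each locus the variable of largest
absolute normalized loading (ties break to variable order, logged). Two
design points matter and were established empirically:

* the response must include the **full locus background**, not only the
  outliers — with outliers alone, loci sharing a single driving variable
  cannot stand out relative to one another and assignment collapses to
  chance;
* conditioning on genotype-derived structure axes is **off by default**
  (`attr_condition_structure`): under clinal selection the leading genotype
  PCs absorb the very gradient being attributed, which empirically drives
  accuracy to chance; the option remains for settings where structure axes
  are established neutral covariates.

At β = 2 (strong selection) assignment accuracy among detected true loci is
0.74 pooled over 20 seeds (chance = 0.2, binomial p < 1e-100); at β = 1.5
it is ≈ 0.66–0.69 — attribution among climate variables that are mutually
correlated at r ≈ 0.8 from 12 sites is intrinsically noisy.

## 8. Polygenic scores and model choice

Per variable, the orientation sign of each assigned locus is the sign of
the across-population Pearson correlation between its allele frequency and
the variable (an exactly zero correlation orients negative, a measure-zero
event); scores sum dosage or 2 - dosage accordingly, so multiplying a
variable by a positive constant changes nothing and negating it maps
s -> 2m - s exactly (tested). Missing dosages are imputed by the rounded
doubled population frequency (logged). Linear vs quadratic score-climate
models are compared by Gaussian AIC = n·log(RSS/n) + 2k with the variance
parameter counted in k; only ΔAIC matters. Under strong selection the
driving variable's score attains median adjusted R² ≈ 0.94 over 20 seeds.

## 9. Numerical and engineering choices

* Permutation p-values use the add-one rule everywhere (minimum 1/(n+1));
  exceedance comparisons use a relative 1e-12 tolerance so exact ties
  count.
* An exact multivariate fit makes the pseudo-F infinite; permuted
  statistics then compare against +inf, giving the minimal p.
* Residuals that vanish to rounding (e.g. a matrix residualized on itself)
  are treated as exactly zero before correlation, avoiding spurious O(1)
  correlations of numerical noise.
* Beta draws floor F at machine epsilon (with a warning) because the
  Balding–Nichols parameters diverge at F = 0.
* All randomness flows from `numpy.random.default_rng(seed)`; the pipeline
  writes its resolved configuration next to its outputs, and a fixed seed
  reproduces every artifact byte-for-byte.

Problem sizes in the test suite and acceptance script (2000 loci, 20
seeded replicates, 500 × 999 permutation calibrations) were chosen as the
smallest at which the measured characteristics are stable; the full suite
runs in about a minute on one CPU.
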