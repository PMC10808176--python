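# Methods

`genebankgp` re-analyses the kind of data a genebank accumulates over
decades: unbalanced multi-year laboratory measurements of grain protein
content (%), lysine content (‰) and thousand grain weight (TGW, g) on a
large, genetically structured collection of a selfing cereal, together
with a genotyping-by-sequencing marker matrix for a much larger set of
accessions.  This note records the statistical models, the choices made
where the design was open, and what the synthetic data does and does not
emulate.

## Phenotype curation

### Trimming

Reliable entry means require replication and connectivity.  Two record
classes are removed, iterated to a fixed point: (1) any year whose
accession set shares no accession with any other retained year (such a
year's effect is confounded with its genotypes), and (2) any accession
left with a single record.  Removing a year can create new single-record
accessions and vice versa, hence the iteration.  An empty fixed point is
an error, not an empty result.

### The year model

Per trait, records follow

    y_ij = mu + g_i + a_j + e_i(j),   a_j ~ N(0, sigma_a^2),
    e_i(j) ~ N(0, sigma_j^2)          (year-specific residual variance).

For outlier testing and BLUEs the genotype term is fixed (cell-means
coding, so each estimate is an adjusted entry mean); for variance
components and heritability both genotype and year are random.  Variance
components are estimated by EM-REML on Henderson's mixed-model
equations — robust for heterogeneous-variance models — followed by an
L-BFGS-B polish of the restricted log-likelihood on the log-variance
scale (EM is slow near variance boundaries; the polish sharpens those
cases).  Convergence: change in restricted log-likelihood < 1e-8, cap
500 EM iterations.  Variances are floored at 1e-10 rather than allowed
negative, since the heritability formulas require non-negative inputs.
The restricted log-likelihood is evaluated through the identity
`-2 lR = log|R| + log|G| + log|C| + y'Py + (n - p) log 2π` with `C` the
MME coefficient matrix, so each evaluation costs one factorization of a
(p + q)-dimensional matrix rather than an n_records-dimensional one.

### Outliers

Residuals from the fixed-genotype fit are standardized by their
year-specific residual SD (plug-in standardization, not
leverage-corrected studentization), given two-sided standard-normal
p-values and corrected familywise by Holm's step-down (default alpha
0.05, configurable).  Flagged records are removed, the table re-trimmed
and the model refitted until no record is flagged (cap 10 rounds).
Heritabilities are reported from random-genotype fits before the first
and after the last removal:

    h2    = sigma_g2 / (sigma_g2 + sigma_e2_bar / n_bar)   (entry-mean)
    h2_pb = sigma_g2 / (sigma_g2 + sigma_e2_bar)           (plot-based)

with `n_bar` the mean number of testing years per accession and
`sigma_e2_bar` the arithmetic mean of the per-year residual variances.

A structural caveat worth knowing: with the genotype term fixed and an
accession measured only twice, a gross error in one record splits
between the entry mean and both residuals, so the *single* offending
record cannot always be isolated.  The loop still removes the
contamination — flagging the larger-|z| sibling leaves a single-record
accession that the re-trim then drops entirely.

## Lysine adjustment

Lysine BLUEs are regressed (unweighted OLS, with intercept) on protein
and TGW BLUEs over the accessions carrying all three traits, and each
genotype is adjusted by

    lysine_adj = lysine - b_P (protein - mean(protein))
                        - b_T (tgw - mean(tgw)).

On the fitting set the adjusted trait is exactly orthogonal to both
predictors and keeps the raw lysine mean (OLS residual properties).  The
fitting-set means are stored with the coefficients, so applying the
model to new accessions (e.g. predicted phenotypes) is a fixed affine
transformation.  BLUE standard errors are not used as weights — the
adjustment is a plain multiple regression on entry means.

## Marker curation and kinships

Filter rules, in order, with defaults: drop monomorphic markers; drop
markers with > 10% missing calls; drop markers whose rarer homozygote
class is < 10% of non-missing calls; drop markers with > 1% heterozygous
calls; impute remaining missing calls to the homozygous state of the
more frequent ("dominant") allele; drop markers with post-imputation
MAF < 1%.  Note that with these defaults the final MAF rule is implied
by the rarer-homozygote rule (post-imputation MAF ≥ 10% × 90% = 9%); it
is kept because the thresholds are all configurable and the rule order
is part of the contract.  Allele frequencies for downstream centering
are taken from the post-imputation matrix — a single reproducible
source; under the 10% missingness cap pre- and post-imputation
frequencies differ negligibly.

The additive kinship is VanRaden method 1, `G = ZZ' / (2 Σ p_k(1-p_k))`
with Z the 2p-centered codes; the epistatic (additive-by-additive)
kinship is the Hadamard square `H = G ∘ G`, positive semidefinite by the
Schur product theorem.

Rogers' distance uses individual allele frequencies in {0, ½, 1}
(heterozygotes surviving the 1% cap are kept at ½, not set missing); for
biallelic data the per-locus term reduces to |c_i - c_j| / 2 and the
distance is the mean over loci, bounded in [0, 1].  Principal coordinate
analysis is classical metric scaling; negative eigenvalues (the
non-Euclidean residue, small for Rogers' distances at these scales) are
dropped without Cailliez correction, and explained proportions are
computed over the positive eigenvalues only.

## Prediction models

All four models regress BLUEs (unweighted) on genomic information and
expose genetic values for *every* accession in the genomic space, so
the same fit serves cross-validation and whole-collection prediction.

* **G-BLUP** — `y = 1μ + g + e`, `g ~ N(0, G σg²)`.  REML profiles the
  restricted likelihood over the single variance ratio on the eigenbasis
  of the training kernel (bounded 1-D search on the log ratio); BLUPs
  for all accessions follow from the conditional expectation
  `ĝ = σg² G[all,train] V⁻¹ (y - μ̂)`.
* **EG-BLUP** — adds `g1 ~ N(0, H σg1²)`.  Two variance ratios,
  maximized by Nelder–Mead on the log scale with three starts
  (derivative-free, cheap at n ≤ 1000).  Fixing σg1² = 0 reproduces the
  G-BLUP fit exactly (same code path).
* **Bayes A** — marker effects with marker-specific variances drawn from
  a scaled-inverse-chi-square prior (scaled-t marginal), Gibbs sampling.
* **Bayesian Lasso** — Park–Casella hierarchy: effects with exponential
  mixing variances (double-exponential marginal), λ² with a weak gamma
  hyperprior centered by the R² heuristic below.

Sampler defaults: 12,000 iterations, 2,000 burn-in, thinning 5, Bayes A
prior df 5.  Prior scales follow common whole-genome-regression
practice: an a-priori R² of 0.5 splits the sample phenotypic variance
between the residual scale and the marker-variance scale (spread over
the realized marker variance sum).  Marker matrices use the same
2p-centered coding as Z in G, which keeps the G-BLUP/ridge-regression
equivalence exact and the epistatic kernel coding-consistent.  Chains
are reproducible from the `ModelSpec` seed; the samplers run in
numba-compiled kernels (chi-square via gamma draws, inverse-Gaussian via
Michael–Schucany–Haas).

A point that matters for interpreting EG-BLUP: between *unrelated*
genotypes the off-diagonal entries of G are near zero, so H = G∘G is
nearly the identity and the epistatic variance is statistically
confounded with the residual — EG-BLUP then collapses onto G-BLUP.  The
Hadamard kernel pays off in structured collections (sib lines,
near-duplicates, subpopulations), which genebanks are.

## Evaluation and selection

Cross-validation: balanced random k-fold partitions (fold sizes differ
by at most one), all models share the folds within a repeat, variance
components are re-estimated inside every training fold (no carry-over),
and the prediction ability is the Pearson correlation between BLUEs and
the pooled test-set predictions — one value per (model, repeat).
Repeats with zero-variance predictions are recorded as undefined and
excluded from summaries with a logged count.

For the derived trait, two routes are compared with the adjustment
refit on each training fold to avoid leakage (direct prediction of
adjusted lysine vs component-wise prediction of lysine, protein and TGW
followed by the adjustment formula), both scored against the full-data
adjusted BLUEs.

Culling-level selection: per trait the threshold is
`mean + Φ⁻¹(level) × SD` of the predicted values over all accessions
(the levels, e.g. 0.99 and 0.999, are read as cumulative probabilities
of the normal distribution); selected accessions exceed every threshold
simultaneously, so a stricter level always selects a subset.  An
empirical-quantile mode is available behind a flag.  Passport
association is the Pearson correlation of predicted traits with
collecting-site altitude over the accessions whose altitude is known.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* biallelic 0/1/2 genotypes with uniform allele frequencies over a MAF
  band, fully inbred by default (selfing crop), with optional
  Hardy-Weinberg sampling, heterozygosity/missingness injection for
  filter tests, and optional RIL-style sib families (`family_size`) to
  produce the relatedness structure real collections have;
* an unbalanced multi-year design given by per-year testing fractions
  (default: one dominant screening year at 69% plus ten small follow-up
  years, yielding many single-record accessions for the trimmer);
* records y = μ + g + a_year + e with year effects, year-specific error
  SDs (default: mild heterogeneity, 0.7–1.3 around the trait's error
  scale — the real per-year values are not published, only their mean)
  and symmetric gross outliers (default rate 0.003 ≈ the observed 17 in
  ~5900 records; unsigned contamination is the harder detection case);
* additive genetic values from i.i.d. normal marker effects, rescaled
  so the realized plot-based variance ratio hits `heritability_target`
  exactly (exact control beats asymptotic control in small fixtures);
  an additive-by-additive share from random interaction effects on a
  random subset of marker pairs (default 200), rescaled to
  `epistasis_fraction` of the genetic variance;
* three coupled traits (protein 17.61 ± genetic SD 2.0 %, lysine
  4.17 ± 0.31 ‰, TGW 40 ± 5 g — scales follow the curated historical
  data) whose marker effects *and* record-level residuals share the
  target correlation matrix (defaults 0.63 / −0.28 / −0.27), so
  BLUE-level correlations track the targets irrespective of
  heritability;
* a collecting-site altitude covariate built from the standardized
  lysine genetic value with correlation `altitude_coupling` (default
  0.45, mean 1200 m, SD 600 m).

Everything is reproducible from a single integer seed, and a truth
object (breeding values, marker effects, epistatic values, year
effects, outlier flags, implied adjustment coefficients, altitude) is
returned for parameter-recovery tests.

What it does **not** emulate: linkage disequilibrium decay and genetic
maps (markers are independent), GBS read-level error, selection-biased
replication (the real follow-up years re-tested only high-performing
accessions), missing-trait patterns (TGW is generated for all
accessions), and multi-trait genotype-by-year interaction.  Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to those real-data features.

## Problem sizes used in the test suite

Simulation-backed checks run at deliberately modest sizes chosen to keep
the estimators well-conditioned and the suite fast: heritability
recovery at 500 accessions × 3 years (10 seeds), residual-variance
recovery of the Bayesian samplers at n = 300 with full 12k chains
(5 seeds), the EG-BLUP/G-BLUP ranking at n = 300, 500 markers, 20
cross-validation repeats, and the outlier-recovery experiment at ~1300
records with 17 planted gross errors.  The fixed-genotype REML needs
records to clearly outnumber genotype effects; below roughly two records
per accession the per-year variance estimates become fragile, which is
the same reason the trimming rules exist.
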