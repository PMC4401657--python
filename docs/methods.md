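# Methods

This note documents the statistical models implemented in `pcgsa`, the
numerical choices behind them, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Gene analysis (tier 1)

### Principal-components regression

For a gene with dosage block X (n samples × m SNPs), columns are centred and
scaled to unit variance, so the eigendecomposition underlying the model is of
the SNP *correlation* matrix.  This makes the pruning fraction independent of
allele-frequency scaling, and makes the F-test invariant to affine recoding of
any SNP (allele flips included).  Writing the SVD of the standardized block as
Z = U S Vᵀ, the component variances are λᵢ = sᵢ²/(n−1).

Pruning retains the smallest K such that the top-K eigenvalues carry at least
a fraction f of the total variance; the default f = 0.999 discards 0.1% of
the variance.  Eigenvalues below 1e−8 of the leading one are always dropped
as numerical rank deficiency, so K never exceeds min(n−1, m) and the retained
score vectors U[:, :K] are orthonormal and mean-centred.  Pruning serves two
purposes: it keeps the regression identifiable under perfect SNP collinearity,
and it removes near-redundant parameters that would dilute the F-test.

The gene test regresses the phenotype on [1, W, U_K] against the null
[1, W], where W is an optional covariate matrix;
F = ((RSS₀ − RSS₁)/K)/(RSS₁/df₂) with df₂ = n − K − c − 1, and the p-value is
the upper tail of F(K, df₂).  Binary 0/1 phenotypes use the identical linear
model; the acceptance suite verifies against adaptive permutation that the
asymptotic p-values remain accurate for balanced and 4:1-skewed designs.
P-values are floored at 1e−300 so perfect fits report a representable minimum
rather than zero.

Samples with a missing phenotype or covariate are dropped listwise before any
gene is analysed, so every gene reports the same n.  Genes that lose all SNPs,
are entirely monomorphic, or leave no residual degrees of freedom are excluded
with a logged reason code, never silently.

### Missing-genotype imputation

The multiple regression needs complete dosage columns.  Each missing entry is
single-imputed deterministically: a least-squares prediction from the nearest
flanking SNP columns (left and right neighbour, whichever are observed for
that sample and have enough jointly observed rows to fit), clipped into
[0, 2], with the column mean as fallback.  With a perfectly correlated
neighbour this reproduces the neighbour-implied value exactly.  Columns that
are missing in every sample are dropped from the gene.  The flanking estimator
is a design choice — one and at most two predictors, chosen for determinism
and O(1) cost per entry; its adequacy is covered by the imputation unit tests.
The SNP-wise models instead mean-impute (see below), deliberately matching the
reference-panel treatment.

### Adaptive permutation

The optional empirical p-value permutes the phenotype — its residuals from the
covariate-only model when covariates are present, a standard but approximate
scheme — and counts permuted F statistics at or above the observed one.  The
estimate is (r+1)/(P+1) rather than the raw proportion r/P, which avoids zero
p-values at a bias of O(1/P).  The schedule defaults to checkpoints at 10³,
10⁴, 10⁵ and 10⁶ permutations, stopping at the first checkpoint with at least
10 exceedances; the 10⁶ cap bounds worst-case cost.

## SNP-wise models

Per-SNP statistics are simple linear-regression tests; the two-sided p-value
is transformed to a 1-df χ² via the inverse upper tail, which also defines the
χ² values recovered from a summary-statistics file.  When only p-values are
available the reference panel supplies the LD; matching is by SNP id only,
since χ² statistics are invariant to allele flips.  In raw-data mode the raw
genotypes play the reference role, with the same mean imputation of missing
entries — by construction, feeding the internally computed SNP p-values back
through the summary path with the raw data as reference reproduces the
raw-data results to numerical precision.

**Mean χ².**  Under the null, the SNP Z-scores of a gene are jointly normal
with correlation equal to the LD matrix, so Σχ² is distributed as Σ λᵢ χ²₁
over the LD eigenvalues (negative eigenvalues from noisy reference panels are
clipped to zero).  The tail is evaluated by a series expansion of the
weighted-χ² distribution into central χ² tails (Ruben/Farebrother), whose
coefficients depend only on the eigenvalues and are precomputed per gene; a
spectrum with equal weights reduces exactly to a scaled central χ².  If the
series fails to decay within its term budget the evaluator falls back to
Imhof's characteristic-function inversion with an explicit error estimate, and
last to a two-moment Satterthwaite approximation.  The series is validated in
the tests against Imhof integration (independent route, agreement ≤ 1e−6) and
against 10⁶-draw Monte-Carlo sampling at the 0.05 and 0.005 tails.

**Top χ².**  No usable closed form exists, so a standard-normal phenotype is
drawn on the LD-source samples and permuted; each permutation yields the
gene's maximum marginal χ², and the empirical p-value is (r+1)/(P+1) under the
same adaptive schedule as above.  When several observed statistics refer to
the same gene and LD source (e.g. replicate phenotypes in the calibration
studies), a batch variant shares one permutation stream across them; each
p-value's marginal distribution is unchanged, only the (negligible)
between-replicate dependence differs.

## Gene-gene correlations

Under the joint null, gene g's model sum of squares is the quadratic form
yᵀP_g y with P_g = U_g U_gᵀ, so corr(SSM_g, SSM_h) = trace(P_g P_h)/√(K_g K_h)
= ‖U_gᵀU_h‖²_F/√(K_g K_h).  Entries are computed for same-chromosome pairs
whose closest boundaries lie within a 5 Mb window (boundary rather than
midpoint distance, so genes sharing SNPs are always within window) and assumed
zero beyond; all stored entries lie in [0, 1] because they are traces of
projector products.  Projectors are built from covariate-free PC scores; when
covariates are used in tier 1 this is an approximation, as the correlations
are derived under the joint null.  The acceptance suite checks the closed form
against empirical correlations of per-gene SSM values across 40,000 permuted
phenotypes on a 30-gene chromosome (max |Δ| < 0.03; the empirical estimate's
own noise floor is ≈0.02 at that permutation count, which is why it exceeds
the spec's 20,000-permutation minimum).

For GLS the banded matrix is densified and, if Cholesky fails, ridged by the
smallest δ ∈ {1e−8, 1e−6, 1e−4, 1e−2, 1e−1} that restores positive
definiteness (logged); banding can break positive definiteness even though
each stored entry is exact.

## Gene-set analysis (tier 2)

Gene p-values are clipped into [1e−12, 1−1e−12] before the probit transform
z = Φ⁻¹(1−p), keeping Z finite.  Genes excluded in tier 1 are absent from
tier 2 entirely; they are not assigned p = 1.

**Self-contained.**  GLS intercept fit on the set's Z-values with the R
submatrix of the set's genes and σ² fixed at 1 (valid because every z_g is
standard normal under the self-contained null): β̂₀ = (1ᵀR⁻¹1)⁻¹1ᵀR⁻¹z, the
statistic β̂₀√(1ᵀR⁻¹1) is standard normal, one-sided.

**Competitive.**  GLS fit of all genes' Z on [1, S_s] plus — on by default —
effective gene size K, density K/m, and their logs (a `--no-size-correction`
flag disables this; the conditional-inclusion rule "if such effects are
present" is replaced by always-on correction because no trigger is specified).
σ² is estimated from the GLS residuals and the one-sided p-value uses a t
reference with df = G − #predictors, which makes the uncorrected,
uncorrelated case *exactly* a one-sided pooled two-sample t-test.  Collinear
covariate columns are dropped greedily in design order (intercept and set
indicator take precedence) with a warning — in simulated panels where every
gene has the same K, all four correction columns are legitimately dropped as
constant.  A fit with zero residual variance raises a degenerate-fit error if
the tested coefficient is nonzero (e.g. a covariate equal to Z itself), and
returns β = 0, p = 0.5 when Z is constant.

**Generalized model.**  The competitive test is a special case of a gene-level
regression on arbitrary named property columns (continuous covariates,
multiple sets, interactions), with one- or two-sided tests per column; the
competitive entry point simply assembles the columns.  Enrichment (β > 0) is
the default orientation throughout; depletion testing is available via the
two-sided option.

**Multiple testing** uses Bonferroni across the sets tested, per test type.

## Synthetic data

The generator emulates the features of GWAS genotype data the analysis is
sensitive to, at a scale that runs in minutes on one CPU:

- **Genotypes**: two independent haplotype chains per individual follow a
  latent-Gaussian AR(1) along the chromosome, with lag-1 correlation
  ρ^(Δbp/spacing), thresholded at the Hardy-Weinberg quantile of a per-SNP MAF
  drawn uniformly from [0.05, 0.5].  Defaults: 2,000 samples, genes of 10 SNPs
  at 1 kb spacing, 5 kb gaps, ρ = 0.9 — strong local LD that decays with
  distance, and nonzero cross-gene LD for neighbouring genes.  The AR(1) model
  was chosen over haplotype resampling for analytic tractability; it does not
  reproduce real human haplotype-block boundaries, recombination hotspots or
  allele-frequency spectra, so passing calibration here shows correctness of
  the statistics under LD, not robustness to every real-data pathology.
- **Phenotypes**: global null (standard normal, or case/control with an exact
  case fraction, e.g. 0.37 to mirror a typically unbalanced case-control
  study); polygenic null with i.i.d. normal effects on randomly chosen
  standardized SNPs, scaled so the realized genetic variance fraction equals
  h² (default 0.5); and a multi-marker gene effect giving the most correlated
  SNP pair opposite-signed effects, so the joint gene R² is controlled while
  every marginal R² stays small — the scenario where joint modelling of a
  gene should outperform per-SNP aggregation.
- Every generator is a pure function of (config, seed), and generated datasets
  round-trip exactly through the PLINK writer/reader.

## Validation scales

The calibration studies run at: 500 genes × 20 phenotype replicates (10,000
gene tests) for gene-model type-I error; 300 genes × 20 replicates × 100
random sets (2,000 set tests) for gene-set calibration under h² = 0.5; 30
genes × 40,000 permutations for the correlation oracle; 200 genes at n = 1,000
with 5,000–50,000 adaptive permutations for binary-phenotype validity.  These
sizes were chosen so the full suite completes in a few minutes while keeping
Monte-Carlo noise well inside the asserted tolerances.

## Known limitations

- X-chromosome genotypes are treated as autosomal; no male hemizygote
  handling.
- Permutation with covariates permutes null-model residuals (approximate).
- Gene-gene correlations ignore covariates.
- No VCF/BGEN or non-integer dosage input; PLINK v1 binary only.
- Self-contained results under polygenic traits are expected to be inflated —
  that is a property of the self-contained null hypothesis, not a defect, and
  the validation suite asserts the inflation direction.
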