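# Methods

## Statistical model

All inference runs on log2 counts-per-million.  Library scaling uses the
trimmed mean of M-values: for sample *j* against the reference sample
(the one whose 75th-percentile count fraction is closest to the cohort
mean), genewise log-ratios M and average log-intensities A are computed
over genes with positive counts in both libraries, genes in the outer 30%
of the M distribution or the outer 5% of the A distribution are trimmed,
and the surviving M values are averaged with inverse delta-method
(binomial) variance weights; factors are rescaled to geometric mean 1.
The implementation reproduces the Bioconductor reference implementation
to machine precision (one test runs the cross-check through Rscript).

Log-CPM uses a pseudo-count: `log2((c + p) / (f·N + 2p) · 10⁶)` with
p = 0.5 by default.  An exp-scale "corrected" matrix — log-CPM with the
fitted nuisance-factor contribution projected out (intercept retained) —
is available for display and correlation analyses only; p-values are
never computed from it.

The linear model is a means model over a "combined category" factor:
`status.sex.onset_side.hemisphere` for disease samples,
`status.sex.hemisphere` for controls, plus centered covariates (illness
duration, age, RIN, log library size, nuclei yield, post-mortem
interval).  There is no per-subject term: the paired structure enters
only through the severity orientation of the category levels.  Precision
weights follow the mean–variance-trend approach: the lowess trend of
quarter-root residual variance against average log2 count, evaluated at
each observation's fitted log2 count, inverted and fourth-powered.

Variance moderation fits a scaled-F prior to the residual variances by
matching moments of log s²_g (with a safeguarded minimum prior df of 0.5;
equal variances yield the infinite-df branch where the posterior equals
the prior).  Contrast tests use t̃ = c'β̂ / sqrt(c'(X'WX)⁻¹c · s̃²) with
d₀ + d_g degrees of freedom and per-contrast Benjamini–Hochberg FDR.

**Contrast weighting.** Contrasts average category levels.  By default
levels are weighted by their sample counts, which equals the marginal
group-mean difference; equal-per-level weighting is available
(`weighting="equal"`).  Size weighting is the default because realistic
cohorts produce singleton design cells (e.g. a single male left-onset
subject), and an equally weighted contrast then inherits that cell's
variance at full weight — measured on the default synthetic cohort,
equal weighting inflated the unscaled contrast variance by ~40–80%.
Size weighting also makes every unilateral subject contribute equal and
opposite weight to the two sides of the asymmetry contrast, so
subject-level effects cancel exactly in its point estimate.

**Unwanted-variation factors.**  Stage 1 fits the clinical model and
ranks genes by the disease contrast; the least-different n genes (default
2000, scaled to 500 for the ~2000-gene synthetic cohorts) are empirical
controls.  A reduced model (category + duration + centered age) is fit,
and the k leading sample-space singular vectors of the control-gene
residual matrix become additional covariates for the final fit
(orthonormal, deterministic sign convention; k defaults to 5 and is
clamped, with a logged warning, to the admissible residual rank in small
stratified runs).  Because linear-model residuals are exactly orthogonal
to the fitted design, these factors can only ever absorb variation
*orthogonal* to the category levels: they restore precision lost to
technical structure but cannot, even in principle, remove a confounder's
component that lies along a contrast.  The practical consequences are
measured and documented below.

## Downstream statistics

*Cohort selection.*  Spearman similarity (mid-ranks for ties) over the
top variable genes above an expression floor; average-linkage
hierarchical clustering on 1 − r; the dendrogram is cut at the largest
gap between merge heights (a single cluster, i.e. no structure, falls
back to all subjects).  A cluster qualifies if every sample in it belongs
to a target-status subject with both hemispheres inside; the qualifying
cluster with most subjects wins and a subject whose hemispheres straddle
clusters is excluded.

*Per-subject asymmetry scores.*  Genes are z-scored across PD samples by
default (configurable to all samples; the report names the scope).  A
subject's score is the mean and SD over set genes of z(severe) −
z(moderate); the sign assigns the stratum with a tie tolerance of 1e-9.
Module correlation reports the mean pairwise Pearson r among primary
members and the r of the alternative member against the per-sample
primary mean, on a named scale, both also rendered as sign(r)·r² because
the field sometimes prints signed squared correlations.

*Classification.*  With per-contrast FDR threshold α (default 0.05) and
effect-size gap δ (default 0.5 log2): doubly significant genes split by
fold-change sign agreement (zero fold changes are reported separately as
`both_zero_direction`); asymmetry-significant, disease-null genes with
|Δlog2FC| ≥ δ are `asym_only_differential`; disease-significant,
asymmetry-null genes are `disease_only_stable`.

*Enrichment.*  Preranked running sum: hits increment by |w|^exponent
normalized over set hits (exponent 1 by default; the all-zero-weight
corner falls back to equal steps), misses decrement 1/(N − set size); ES
is the signed extremum.  Significance by gene-label permutation,
p = (1 + #{|ES*| ≥ |ES|})/(1 + n_perm), BH across sets.  Phenotype
permutation is deliberately not offered — the input is a preranked list.
A hypergeometric over-representation tail is included as a lightweight
alternative to network-based enrichment services.

## The synthetic cohort generator

Counts are gamma–Poisson: `c_gs ~ NB(mean μ_gs, dispersion φ)` with
log2 μ built from a log-normal baseline (N(5, 2) in log2), a per-gene ×
per-subject random effect (SD 0.3 log2, shared by the two hemispheres), a
disease effect (±1 log2 for 10% of genes), a lateralized effect (±0.5
log2 applied with opposite sign to the severe and moderate hemispheres of
unilateral PD subjects, for 7.5% of genes of which a third are
asymmetry-only), a co-regulated 8-gene module plus one anti-correlated
alternative member (subject-level latent activity, SD 1.5 log2, at a high
baseline so count noise does not swamp it; per-subject asymmetry
direction flips for a configurable fraction of subjects), two batch
factors with N(0, 0.5) gene loadings, and a log-normal library-size
offset (SD 0.25).  φ defaults to 0.1 (biological CV ≈ 0.32+, in the
range of human cohort estimates).  Illness duration is N(10, 5) years
clipped to [1, 25]; other covariates are drawn at registry-plausible
values and carry no expression effect.

Two deliberate structural choices:

- **Batch factors are subject-level and block-balanced.**  Both
  hemisphere libraries of a subject share their batch values, and the
  subject-level values are orthogonalized within every
  status × sex × onset cell — the design a well-run core approaches by
  randomizing batches over groups.  This is also what makes the factors
  *identifiable*: a residual-based estimator can only recover the
  design-orthogonal component of a factor, so factor-recovery checks
  compare estimated factors with the design-residualized truth
  (principal angles, typically < 10°).
- **Severity orientation is computed by the same onset rule as the
  pipeline** (default: contralateral — a right-onset subject's left
  hemisphere is severe; configurable to ipsilateral since source cohorts
  record onset differently), so simulator and analysis cannot disagree
  silently.  Bilateral-onset subjects can be generated; they are flagged
  and excluded from asymmetry contrasts.

Each subject draws from its own counter-based substream of the global
seed.  Identical spec + seed reproduces the cohort bit for bit;
regenerating with inverted onset labels flips exactly the planted
lateralized effects.

For simulated cohorts the expression filter is CPM > 10 in at least
min-cell samples — the depth-matched transport of the conventional
"CPM > 1 at tens of millions of reads" rule, since the simulated
libraries hold ~2 × 10⁵ reads over ~2000 genes (CPM 10 ≈ 2 counts).
`hemidiff.presets.simulated_study_config()` carries these matched
defaults.  Recovery statistics are computed among planted genes that
pass this filter.

## What the validation does and does not show

The generator emulates the *statistical skeleton* of a bilateral cohort:
paired libraries, lateralized effects, subject heterogeneity, balanced
technical factors, overdispersed counts.  It does not emulate real
annotation scale (~20k genes), empirical library-size distributions,
gene–gene correlation beyond one module, count-level outliers, or
ambient/contamination structure.  Passing tests therefore establish that
the implementation computes the intended statistics correctly and that
the pipeline recovers planted structure under its own assumptions — not
that those assumptions hold in any particular tissue bank cohort.

Measured properties worth knowing before use on real data:

- **Calibration is exchangeable-null calibration.**  On no-effect
  cohorts without subject random effects, both contrasts' p-values are
  uniform.  With subject heterogeneity the subject-free model (faithful
  to the published formula) makes the asymmetry contrast conservative
  (subject effects cancel in the estimate but inflate the residual) and
  the disease contrast anticonservative (correlated errors within
  subject pairs).  A duplicate-correlation or mixed-model extension
  would address this; it is intentionally out of scope.
- **Residual-based factor correction restores power, not unbiasedness —
  and can raise the raw null false-positive rate.**  Because estimated
  factors are orthogonal to the design, adding them leaves contrast
  point estimates essentially unchanged while shrinking standard errors;
  any confounder component along a contrast, and any between-subject
  variance the disease contrast still carries, remains in the numerator.
  In replicate experiments the corrected model's null FPR was almost
  never lower than the uncorrected model's — the correction's benefit
  appears as recovered power and de-padded variance estimates, not as
  fewer raw false positives.  Users who need strict type-I control under
  strong unwanted variation should pair the factors with a subject-aware
  error model.
- **Power at the published design is modest for the disease contrast.**
  With dispersion 0.1, 14 + 10 subjects and unit log2 effects, the
  asymmetry contrast recovers ~75–80% of planted genes at FDR < 0.05,
  but the disease contrast only ~15–60% across realizations: the
  covariate set (illness duration is near-collinear with the disease
  split because controls have zero duration) and the unmodeled pairing
  roughly double the contrast variance relative to a plain two-group
  comparison.  Point estimates stay unbiased (|mean bias| < 0.1 log2 in
  all runs).

## Numerical choices and degenerate inputs

- TMM: genes with a zero count in either library of a pair are excluded
  from that pair; an all-equal M vector yields factor 1; a zero-total
  sample is an error naming the sample.
- Moderation: the trigamma inverse is solved by Newton iteration;
  non-positive moment estimates select the infinite-df branch; prior df
  is floored at 0.5.
- Nuisance SVD: identically zero residuals are an error; factor signs
  are fixed by making each column's largest-magnitude element positive.
- Ranking ties break lexically by gene id everywhere a selection is
  order-sensitive (control genes, variable genes), so every stage is
  deterministic; the run manifest records SHA-256 checksums and two runs
  with identical config and seed are byte-identical (gzip containers are
  written with a fixed mtime).
- Severity swap is an exact antisymmetry: relabelling severe↔moderate
  negates asymmetry log2FCs and per-subject scores to floating-point
  precision and permutes the strata.
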