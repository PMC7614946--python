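# Methods

## Phenotype preparation

Protein abundances are modelled on the rank scale: values map to
standard-normal quantiles Φ⁻¹((rank − c)/(n − 2c + 1)) with mean ranks
for ties. The default offset c = 0.5 gives the symmetric (rank − 0.5)/n
rule and avoids ±∞ at the extremes; the Blom variant (c = 3/8) is a
config option (`rint_offset`). Transformed values are residualized by
OLS on age, sex, measurement plate (unordered factor, first-level
reference coding) and the top genotype principal components
(`pcs_k`, default 10 at study scale, 4 in the demo where the synthetic
cohort has no population structure to absorb). Residuals are exactly
orthogonal to every covariate column and mean zero; rank-deficient
covariate designs are rejected with the collinear columns named. When a
study is split into design strata (sub-cohort / case set), preparation
runs within each stratum before any cross-stratum combination.

## Sum-of-single-effects fine-mapping

The model is y = Σ_l X b_l + e with e ~ N(0, σ²I); each single effect
b_l has one nonzero coordinate, uniform over the m variants a priori,
with effect size prior N(0, σ₀l²). Fitting is by iterative Bayesian
stepwise selection: for each effect in turn, the expected contribution
of the other effects is subtracted and the single-effect regression is
solved in closed form from the per-variant least-squares estimates
(log Bayes factor of N(0, σ₀² + s²) against N(0, s²), inclusion weights
by softmax). After each sweep σ² is set to its expected-residual
maximizer. Each σ₀l² is re-optimized per sweep by maximizing the
single-effect model Bayes factor (bounded search on the log scale); an
effect whose optimized Bayes factor cannot beat the null is switched
off (σ₀l² = 0), which is what lets null effects drop out rather than
spread uniform weight. The variational objective (ELBO) is evaluated
every sweep, is non-decreasing (asserted in tests to 1e-6), and stops
the iteration when it improves by less than `tol` = 1e-3 (max 100
sweeps). Defaults follow the conventions of the standard implementation
of this model: coverage 0.95, purity threshold 0.5, prior variance
initialized at 0.2·var(y) and optimized. X columns are standardized
internally; reported effect scales are per standardized genotype unless
noted.

Credible sets take, per live effect, the smallest weight-ordered prefix
reaching 95% cumulative inclusion mass; purity is the minimum absolute
genotype correlation among members (singletons have purity 1), and
exact duplicate sets across effects are reported once. The lead is the
maximum-weight member with ties broken by smaller marginal p, then
lower variant index.

**Grid search over L.** Fits are evaluated for L = 10 down to 2 and the
first admissible fit is returned — equivalent to fitting every L and
keeping the largest admissible one, since admissibility is a property
of each fit alone, but roughly 9× cheaper in the common case.
Admissible means: all credible-set pairs disjoint and maximum cross-set
r² ≤ 0.1. Disjointness is added to the LD rule because overlapping sets
are trivially in perfect LD with themselves. If no L in the grid is
admissible the model falls back to L = 1, which always exists; the
typical trigger is two strong causals in moderate LD (0.1 < r² < ~0.5)
that no partition can separate cleanly.

**Joint filter and downstream tests.** All set leads enter one OLS
model with intercept (linearly dependent leads dropped, later lead
loses, with a warning); a set is carried forward only when its lead's
joint two-sided t-test p-value is < 5×10⁻⁸. The same model's R² is the
variance-explained estimate. The sex-interaction test adds sex and
genotype×sex terms to the adjusted model and reports the interaction
p plus sex-stratified slopes; it requires both sexes present.

## Regional association and replication

The marginal scan is simple per-variant OLS — the mixed-model term of
biobank-scale tools is omitted because the modelled design excludes
related individuals, so the genetic relatedness correction is null to
first order; this is an approximation, documented here. Two-sided
p-values use the normal for n > 100 and the exact t below. Cohorts are
combined by inverse-variance fixed-effects meta-analysis after
harmonizing alleles by id (flip beta and reflect eaf when effect/other
are swapped; irreconcilable rows dropped and counted; strand-ambiguous
A/T and C/G pairs warn — the generator never emits them). Replication
refits the exact joint lead model in the independent sample; a lead
replicates iff directionally concordant and p < α/n_tests.

## Colocalization

Per-variant approximate Bayes factors use the Wakefield asymptotic
form with prior effect sd 0.15 for quantitative traits and 0.2 on the
log-odds scale for binary traits (the cited framework's defaults,
exposed as config). Binary-trait rows fitted by linear regression are
converted to log odds ratios by β/(μ(1−μ)) with the stored case
fraction before the Bayes factor. The five-hypothesis posterior is
computed entirely in log space; the distinct-causals mass
p1·p2·(e^{S1+S2} − e^{S12}) is exactly zero for single-SNP regions and
clipped at zero (with a warning) if rounding drives it negative.

The screen declares a protein–trait pair colocalized only when all of:
SNP overlap ≥ 500 after id+allele intersection; trait p < 10⁻⁶ at the
lead cis-pQTL or an r² ≥ 0.8 proxy; the strongest cis-pQTL or such a
proxy present in the overlap; sentinel–sentinel r² ≥ 0.8 (inclusive
comparisons throughout, LD always taken from the supplied matrix); and
PP4 ≥ 0.8 under p12 = 10⁻⁶. eQTL colocalization relaxes p12 to 10⁻⁵,
reflecting the higher prior of a shared signal at the encoding gene.
Trait effect directions are reported per protein-increasing allele at
the pQTL sentinel.

**Multi-trait extension.** `multitrait_coloc` is a deliberate
simplification of multi-trait colocalization (tagged
`method="hyprcoloc-lite"` in its output): the hypothesis space contains
only all-traits-share-one-signal, all-traits-independent, and
all-null — no partial-sharing configurations. The shared mass is
p1·γ^{|T|−1}·Σ_q exp(Σ_t labf_tq); defaults p1 = 10⁻⁴ and γ = 10⁻²
make p1·γ match the pairwise p12 so the two-trait case reduces to PP4
(verified to 0.05 on strong signals). Divisive clustering peels the
trait whose removal most improves the shared posterior (ties to the
lowest index) until it clears 80% or two traits remain; peeled traits
seed the next cluster attempt.

## Catalog annotation, convergence, enrichment

Catalog rows must carry an effect estimate, a risk allele and
genome-wide significance; multiplex-proteomic-assay traits are excluded
via an explicit denylist rather than fuzzy matching. Matching is by
variant id, directly or through any r² ≥ 0.8 proxy of the set lead in
the supplied LD matrix (catalog variants absent from the matrix can
only match directly and are flagged). The classification rubric is an
explicit decision table: *confirmed* when the protein gene is the
unique reported gene; *refined* when it is one of several reported
genes, or only supported by the catalog's nearest-gene mapping; *novel
reassignment* when it appears in neither. Burden convergence counts
genes with an exome-wide-significant burden row (p < 10⁻⁶), genes with
a colocalization at PP ≥ 0.8, and their overlap, restricted to the
covered gene universe; duplicate variant masks for one gene–trait pair
keep only the most significant row. Trait-name harmonization between
the two tables is a user-supplied mapping. Fisher's exact test uses the
full assayed protein panel as background; the two-sided p sums
hypergeometric masses at most as probable as the observed table, the
CI is the Woolf log-OR interval, and zero cells add 0.5 to all cells
for the OR/CI only.

## Synthetic data generator

Genotypes come from a Gaussian copula: one latent standard normal per
sample and variant with block-constant correlation ρ, cut at the two
Hardy–Weinberg quantiles of a MAF drawn uniformly from `maf_range`, so
marginals are exactly HWE while within-block LD is controlled by ρ.
Defaults ρ = 0.8, block size 20, MAF ∈ [0.05, 0.5] give adjacent-pair
r² around 0.5 and near-independence across blocks — enough to exercise
every LD rule the pipeline references (r² thresholds 0.1 and 0.8)
without a coalescent simulation. The block parameters are free knobs,
not calibrated to any particular population's LD spectrum. Effect
sizes are specified on the standardized-genotype scale (per-allele
effects divide by sd of dosage ≈ √(2·maf·(1−maf))), noise is scaled so
the genetic variance fraction hits the target heritability before
covariate effects are added, and finite-sample monomorphic draws are
redrawn so empirical frequencies stay inside (0,1). Replication
cohorts reuse the discovery variant table (same ids, MAFs), i.e. a
fresh sample from the same population. Binary traits threshold the
quantitative liability at the case-fraction quantile and are analysed
by linear regression on 0/1, mirroring the conversion pathway. The
two-stratum case-cohort structure is represented only as a label so
the per-cohort-then-meta rule can be exercised; no sampling weights.

What the generator does **not** emulate: recombination-map LD decay,
imputation uncertainty, strand ambiguity, X-chromosome dosage,
relatedness or population structure (PC correction is exercised via an
explicit two-subpopulation construction in the tests), assay
batch-by-genotype artefacts. Passing tests therefore show the
statistical machinery is correct and calibrated under these idealized
conditions, not that real-cohort QC issues are handled.

## Problem sizes and numerics

The calibration studies run at: 200 single-causal regions (n = 1000,
m = 300, h² = 0.1), 100 two-causal regions (h² = 0.05 each, causal
r² < 0.05), 200 + 200 colocalization pairs (n = 5000, m = 600,
h² = 0.05, ≥ 500 overlapping SNPs), 1000 sex-interaction null
replicates (n = 1000), 20 multi-trait agreement replicates (n = 2000);
the demo pipeline uses 500–800 samples and 150–250 variants per
region. These sizes were chosen so the whole suite runs on a single
CPU in minutes while leaving the Monte-Carlo error of each rate well
inside its acceptance margin. Seeds are threaded explicitly through
every generator and study; the pipeline spawns all stage seeds from
one root seed, making numeric outputs byte-identical across runs.

## Known limitations

- Fine-mapping uses individual-level data only; no summary-statistics
  mode.
- The OLS stand-in for a mixed model is wrong under cryptic
  relatedness.
- The multi-trait posterior ignores partial-sharing hypotheses, so it
  understates evidence when a strict subset of traits shares a signal;
  the divisive peeling recovers the common cases.
- Fisher CIs use the Woolf approximation, not exact conditional
  intervals.
- The GWAS-catalog classification rubric operationalizes reported
  outcomes as three predicates; borderline rows (protein gene supported
  only by the nearest-gene mapping) are labelled *refined* by
  convention.
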