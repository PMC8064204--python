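# Methods

## The model

Two GWAS report, for a shared set of SNPs, effect estimates and p-values
for a principal and a conditional trait. The working assumption is the
standard empirical-Bayes mixture: each SNP is null or non-null for each
trait, and pleiotropy makes the joint tail {p₁ small, p₂ small} heavier
than the product of the margins. The per-SNP conditional FDR is estimated
pointwise,

    cFDR(1|2)ᵢ = min(1, p₁ᵢ · N₂ᵢ / N₁₂ᵢ),

with N₂ᵢ = #{k : p₂ₖ ≤ p₂ᵢ} and N₁₂ᵢ = #{k : p₁ₖ ≤ p₁ᵢ, p₂ₖ ≤ p₂ᵢ}. Ties
count inclusively on both axes and each SNP counts itself, so N₁₂ ≥ 1.
This is the simplest faithful estimator of the conditional false discovery
rate; no lookup-table interpolation or smoothing is applied, and no
running-minimum monotonicity is enforced along sorted p₁ — raw pointwise
values are reported and so flagged in the result metadata. With a constant
conditioning vector the estimator reduces exactly to the classic empirical
FDR p·N/rank, and after step-up monotonicity to Benjamini–Hochberg
adjusted p-values (asserted against statsmodels in the tests). The
conjunction cFDR is the element-wise maximum of the two orderings.
Implementation is an O(N log N) Fenwick-tree sweep in ascending p₂,
inserting whole tie groups before querying; a double-loop counting oracle
in the test suite pins the semantics exactly.

Significance is inclusive (value ≤ α) at α = 0.05 and 0.01. Novelty
filtering removes calls that are listed as known or (when a genotype
reference is supplied) sit at r² ≥ 0.2 with a known SNP on the same
chromosome.

## Enrichment diagnostics

Stratified Q-Q curves plot −log₁₀ p₁, sorted within nested strata
p₂ ≤ {1, 0.1, 0.01, 0.001}, against −log₁₀(i/(|S|+1)). Enrichment is
quantified as the nominal −log₁₀ p₁ at empirical quantile 2 (interpolated),
which must increase strictly across strata under genuine pleiotropy.
Fold-enrichment curves divide each stratum's tail fraction by the full
set's over a 200-point log-spaced nominal grid between 1 and 10⁻⁸; grid
points with an empty denominator are omitted. The genomic-control λ is the
median of z² over the 1-df chi-square median (computed with scipy's
`chi2.ppf(0.5, 1)`, so λ is exactly 1 for uniform-median input), and the
inflation correction rescales the principal trait's chi-squares by λ
floored at 1 — only inflation is corrected, the conventional practice;
deflation is left untouched.

## Harmonization and merging

Inner join on SNP id; trait 2's effects are aligned to trait 1's effect
allele: swapped coding flips the beta sign and complements the frequency,
strand complements pass through, swap-plus-complement flips. For
palindromic SNPs (A/T, C/G) the label categories coincide, so orientation
comes from frequency concordance alone, and SNPs with an effect-allele
frequency inside the closed band [0.42, 0.58] in either study are dropped
as unresolvable. The same rules drive the MR `harmonize` actions 1/2/3
(assume same strand / frequency-resolve with ambiguity drop / drop all
palindromic). The band reproduces the published instrument count: the
48-row packaged instrument table loses exactly its two frequency-ambiguous
palindromic SNPs, leaving the 46 the published estimates are based on.
Zero p-values are clamped to the smallest positive double (needed by the
−log₁₀ transforms) and logged; genomic control is *not* re-applied at
merge time, since consortium summary files arrive already corrected.

## LD pruning and clumping

Pairwise r² is the squared Pearson correlation of dosages with
pairwise-complete missing handling; zero-variance columns yield NaN, which
callers treat as "no LD evidence". `indep_pairwise` (defaults 50 / 5 /
0.2) slides windows over the SNPs *surviving at the start of each pass*
and repeats passes until a sweep removes nothing, so no window over the
final kept list contains a violating pair. Within a window, violating
pairs are resolved highest-r² first (ties broken by index order), removing
the SNP with the larger principal-trait p-value and falling back to the
later positional SNP — the cited pruning tools leave this choice to their
internals, and a deterministic rule is required for reproducibility.
Windows are SNP-count based, not physical distance. `clump_by_pvalue`
accepts SNPs in ascending-p order iff r² with every previously accepted
same-chromosome SNP is strictly below the ceiling (default 0.001).

## Mendelian randomization conventions

IVW is zero-intercept weighted least squares of outcome on exposure betas
with weights 1/se_O²; MR-Egger adds a free intercept after orienting
exposure betas non-negative (required for intercept interpretability).
Both report SE = fixed-effect SE × max(1, σ̂), the multiplicative
random-effects convention floored at fixed effect; p-values are normal for
IVW, t(n−2) for Egger. These conventions are validated empirically: they
reproduce every digit of the published worked example (b = 0.441,
se = 0.207, OR = 1.554, CI 1.036–2.330, p = 0.033; Egger 0.968 / 0.723 /
0.187 with intercept p = 0.450). The weighted median interpolates the
inverse-variance-weighted median of Wald ratios (first-order SEs
se_O/|β_E|); mode estimators maximise a weighted Gaussian KDE with
bandwidth φ·0.9·min(SD, 1.4826·MAD)·n^(−1/5) on a 512-point grid extended
three bandwidths past the data range, φ = 1 by default. Because the mode
is bandwidth-sensitive, its published rows are held only to |Δb| ≤ 0.05.
Median and mode SEs come from a parametric bootstrap (resampling each beta
from its normal; default 1000 draws, fixed seed recorded in the output).
A single instrument degenerates IVW to the Wald ratio; Egger/median/mode
require n ≥ 3. Exact zero outcome betas (rounded log-ORs occur in real
instrument tables) are handled throughout.

## Synthetic data: what it emulates, what it does not

`MixtureSpec` defaults encode the study conditions the property tests run
under: π = (0.94, 0.02, 0.02, 0.02) over {null, trait-1-only,
trait-2-only, pleiotropic}, signal SD σ = 3 on the z scale (a well-powered
locus at consortium sample sizes, giving realistic Q-Q deflections),
signal correlation ρ = 0.5 among pleiotropic SNPs, 30% CpG fraction,
10-SNP LD blocks with adjacent-dosage correlation 0.8, and nominal sample
sizes of 150,000 per trait feeding the standard GWAS SE approximation
se = 1/√(2·n·eaf·(1−eaf)). Genotypes follow a haplotype-copying chain:
within a block each SNP copies its left neighbour's allele with
probability r_ld, else redraws at the block MAF ~ U(0.05, 0.5), so
adjacent dosage correlation equals r_ld directly (a latent-Gaussian
threshold model was rejected because thresholding attenuates dosage
correlation well below the latent parameter). Signals sit on index SNPs
only — association does not leak into LD neighbours — keeping the truth
crisp for false-discovery accounting. The generator has no coalescent
realism, no population structure, no case-control ascertainment, and
independent CpG flags by default; passing tests therefore demonstrate
estimator correctness and calibration under the stated mixture, not
robustness to confounding structure real consortia data may carry.

MR instruments: β_E = |N(0, 0.05²)| + 0.02 (bounded away from zero so
Wald ratios are stable), fixed small SEs (0.003 exposure / 0.03 outcome),
β_O = θ·β_E + α + noise with optional balanced (SD) and directional
(mean) pleiotropy α.

## Problem sizes and numerical choices

The test battery uses panels of 2,000–20,000 SNPs, 200 all-null
replicates at N = 5,000 for conservatism, 100 mixture seeds at N = 5,000
for the realized false-discovery proportion (observed ≈ 0.05 against the
0.10 bound), and 100 seeds of 100 instruments for MR parameter recovery —
sizes chosen so each property estimate has small Monte-Carlo error while
the whole suite runs in well under a minute of compute per battery.
Degenerate inputs: empty strata are omitted with a warning; a stratum of
one SNP yields a single Q-Q point; zero-variance genotype columns are
no-LD; empty instrument sets make a direction "not-estimable" rather than
an error. All randomness flows through `numpy.random.default_rng` seeds
carried in specs/configs; rerunning any generator or pipeline config
reproduces outputs byte-identically (asserted via checksums).

## Known limitations

The pointwise cFDR is conservative but not a formal FDR-controlling
procedure; no LD-aware or covariate-adjusted cFDR variants, no local FDR.
Pruning operates on dosage correlation only (no D′, no haplotype phase).
Multi-allelic variants and indels are rejected at read time; no genome
build liftover. The conjunction call set inherits whatever residual LD the
upstream pruning leaves; no second-stage clumping of hits is applied.
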