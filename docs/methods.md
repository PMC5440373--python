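# Methods

## Model and procedure

`condconj` implements an empirical-Bayes framework for localizing genetic
overlap between two traits from GWAS summary statistics alone. The working
model is the standard two-group mixture: each SNP's test statistic is drawn
from a null or a non-null component, and the (conditional) FDR is the
posterior probability of the null given that both traits' p-values are as
small as or smaller than observed.

The pipeline runs in six stages.

1. **Input validation and harmonization** (`sumstats`). Summary statistics
   are read from tab-delimited files, rows violating basic invariants
   (p outside (0, 1], invalid or identical alleles, z/p disagreement beyond
   5% relative — the slack printed tables need when z is rounded to two
   decimals) are rejected with a per-row report, and the two traits are
   inner-joined on SNP id. Trait 2's z-score is re-oriented to trait 1's
   effect allele, treating strand complements as equivalent and flipping
   the sign for swapped allele pairs. Palindromic SNPs (A/T, C/G) are
   retained — their p-values, hence all FDR quantities, are orientation-free
   — but flagged `direction_defined = False`, and every direction-derived
   quantity downstream reports them as undefined (`NaN`).
2. **Genomic inflation control**. λ = median(z²)/median(χ²₁), estimated by
   default on one random SNP per LD block (a `null_subset`, e.g. intergenic
   SNPs, can be supplied instead); z-scores are deflated by √λ and p-values
   recomputed. The correction is idempotent and scale-equivariant. Which
   subset variant the inflation-control literature intends is left
   configurable because median-χ² control on any rich subset is
   conservative in the presence of true polygenic signal.
3. **Enrichment views** (`enrichment`). Conditional Q-Q, fold-enrichment,
   and conditional-TDR curves over nested secondary-trait strata
   (p₂ < 0.1, 0.01, 0.001 strictly, plus the all-SNP stratum). Q-Q curves
   are averaged over seeded random prunings (default 100 draws; a single
   draw is one flag away, as the choice between the two is not fixed by the
   method). Displays are restricted to nominal −log₁₀ p < 7.3 (p > 5×10⁻⁸):
   the views target sub-genome-wide-significant polygenic signal. The
   restriction applies to plots only, never to FDR estimation.
4. **Conditional / conjunction FDR** (`cfdr`). The conditional FDR
   min(1, π₀ p₁ / F̂(p₁ | p₂ ≤ t)) with π₀ bounded at 1 is evaluated on a
   201 × 201 node grid, equally spaced in −log₁₀ p from 0 to the observed
   maximum (capped at 300), estimated on the random-pruned,
   region-excluded SNP set, then applied to *all* SNPs by bilinear
   interpolation — exclusion protects estimation from long-range-LD bias
   but does not disqualify SNPs from scoring (loci may be reported inside
   the excluded regions). The conjunction FDR is the maximum of the two
   conditional FDRs; significance is strict at 0.05.
5. **Loci** (`loci`). Significant SNPs are clustered into LD blocks
   (connected components of the r² > 0.1 graph induced on the significant
   set — consistent with blocks containing more than one reported SNP, and
   cross-checked against rank-greedy clumping), led by the
   minimum-conjFDR SNP, annotated with the nearest gene (distance 0 inside
   a span; ties break on smaller start then name), and flagged for allelic
   effect-direction concordance.
6. **Replication** (`replication`). The primary trait's substudies are
   randomly half-partitioned (default 500 times); discovery and replication
   z-scores are combined per half by sample-size-weighted Stouffer
   (w_k = √n_k; equal weights available), which preserves N(0,1) nulls.
   Replication success is two-sided p < 0.05 *and* sign concordance with
   discovery (the sign requirement is a flag, default on; without it the
   null success rate doubles from 0.025 to 0.05). Cumulative success
   proportions are computed from the most significant end across 1,000
   equal-width bins spanning each partition's observed discovery
   −log₁₀ p range, then averaged over partitions by bin index; bins empty
   in a partition stay undefined there rather than being interpolated.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `r2_threshold` | 0.1 | strict lower bound for an LD edge (pruning, exclusion, clumping, blocks) |
| strata thresholds | 1.0, 0.1, 0.01, 0.001 | secondary-trait p cutoffs, strict `<` |
| `fdr_threshold` | 0.05 | conjunction-FDR significance, strict `<` |
| `n_grid` | 201 | cFDR grid nodes per axis |
| `min_condition_count` | 50 | smallest SNP count a conditioning stratum may stand on |
| `prune_iters` | 100 | random prunings averaged in the Q-Q view |
| p-value floor | 1e-300 | avoids exact zeros in log-space grids |
| partitions / bins | 500 / 1000 | replication resampling protocol |
| z/p consistency | 5% relative | tolerance for printed-table rounding |

## Numerical choices

- **Monotonization.** The raw empirical estimator p/F̂(p) is sawtoothed
  (rising between order statistics, dropping at each). We use the q-value
  convention in both grid directions: first cfdr(p₁) ← min over p₁′ ≥ p₁,
  then a running minimum along conditioning stringency, giving cfdr
  non-decreasing in p₁ and non-increasing as the secondary threshold
  tightens. Both passes only flatten peaks; they never lift values.
- **Sparse conditioning strata.** A stratum with a handful of SNPs makes
  F̂ ≈ 1 for any p₁ below its few order statistics and the conditional FDR
  collapses to ≈ p₁ — an anti-conservative artifact precisely at the
  stringent corner that drives discoveries. Conditioning columns with fewer
  than `min_condition_count` (50) SNPs therefore inherit the nearest
  adequately populated, less stringent column, generalizing the zero-count
  rule. Under a pure-null simulation this choice is what brings the median
  declared-locus count to zero.
- **Tails.** Beyond the most significant observed p₁, F̂ is extended as a
  constant, so cfdr → 0 as p₁ → 0 instead of jumping to 1 on an empty
  count. Conditioning columns beyond the most significant observed p₂
  inherit leftward. Queries outside the grid clamp to the boundary.
- **Ties and determinism.** Clumping orders by (score, p₁, id); locus
  leads by (conjFDR, p₁, id); nearest genes by (distance, start, name).
  Random pruning sorts SNP ids before drawing, so results depend only on
  the seed, never on input order. Every stage is seeded through
  `numpy.random.default_rng`; pipeline reruns are bit-identical and the run
  manifest records SHA-256 checksums to prove it.
- **Degenerate inputs.** A trait with no signal (all −log₁₀ p ≈ 0) gets a
  floor of 1 on its axis span; empty strata carry all-NaN curves with a
  warning; an empty trait intersection is fatal.

## The synthetic-data generator

`simulate_pair` emulates the structure of two large single-trait GWAS on
independent cohorts: per-SNP causal states from the mixture
π = (0.90, 0.04, 0.04, 0.02) (null / trait-1-only / trait-2-only / shared),
shared effects bivariate-normal with correlation 0.9, and effect scales set
so the median causal |z| is 4 at the default sample sizes (n₁ = 82,315,
n₂ = 59,225) — the discoverable-but-subtle regime the method targets. SNPs
sit at 5 kb spacing on 22 chromosomes in geometric LD blocks (mean 10
SNPs); two high-LD regions placed at the MHC and 8p23.1 coordinates carry
10× larger blocks so the region-exclusion logic is always exercised, as is
allele harmonization (trait 2 is written in scrambled orientations) and the
palindromic path (10% A/T, C/G). A 52-substudy panel decomposes trait 1
with z_k ~ N(√n_k β₁, 1), so the Stouffer combination reproduces the
full-sample mean structure.

**LD model.** Within a block, z-score noise is exchangeably correlated with
correlation r = √(r²_within) (a single latent block factor), and each SNP's
mean is its own causal effect plus r times the *average* of its
block-mates' effects. A coherent sum over all mates — the fully
exchangeable alternative — would make tagged signal grow with block size
times causal density, which at a 10% causal fraction reproduces the
long-range-LD pathology (λ ≈ 2.3, widespread spurious cross-trait blocks)
that the method explicitly masks out by region exclusion, not the behavior
of ordinary LD blocks. With bounded single-factor tagging the generator
yields λ ≈ 1.2, typical of a strongly polygenic GWAS of this size.

**What passing tests do and do not show.** The generator has no allele
frequencies, no population stratification, no variable per-SNP sample
sizes, and block-structured rather than banded LD; real r² matrices decay
with distance and the exchangeable approximation overstates correlation at
block edges. Calibration results on these simulations show the estimator
and its numerical machinery are sound under the stated model; they do not
certify calibration under confounding, cryptic relatedness, or mis-specified
LD references, and the real analysis leans on the same guards (inflation
control, pruning, region exclusion) for exactly those reasons.

## Problem sizes used in validation

The calibration experiment (also re-run by `scripts/acceptance.py`) uses
20 replicates of 2×10⁵ SNPs at the default conditions and measures the
false-shared proportion among declared lead loci, where a locus counts as
false if no SNP in its lead's LD block is truly shared; typical runs give
≈ 0.04 (+2 MC SE ≈ 0.042), inside the nominal 0.05. Null-behavior checks
use a 2×10⁵-SNP pure-null panel (λ within ±0.02, conditional Q-Q inside
Dvoretzky–Kiefer–Wolfowitz envelopes, fold ≈ 1, median zero declared
loci). Enrichment-monotonicity checks average 20 replicates of 4×10⁴ SNPs
with 20 half-partitions per replicate; monotonicity across nested strata is
asserted on mean stratum-to-stratum increments within two Monte-Carlo
standard errors.

## Known limitations

- π₀ is bounded at 1, never estimated: conditional FDRs are upper bounds,
  and power is conceded relative to a fitted two-group model (an explicit
  non-goal).
- The empirical conditional CDF double-dips (each SNP contributes to the
  stratum it is scored in); at genome-wide SNP counts the effect is
  negligible but it is not corrected.
- Scoring all SNPs after estimating on pruned SNPs leaves a mild winner's-
  curse at the block level: a large block gets several correlated chances
  to cross the threshold. The calibration experiment shows the realized
  false-shared proportion stays within the nominal level at the default
  conditions, but heavier LD would erode the margin.
- Nearest-gene annotation is distance-only; no functional weighting, eQTL
  lookup, or fine-mapping (non-goals).
- LD is consumed as pairwise r² or block files; computing r² from genotype
  panels is out of scope.
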