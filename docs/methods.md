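# Methods

This note documents the statistical procedures, the simulator that generates
the study conditions, the numerical choices, and the design decisions taken
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Genotype conventions and QC

Genotypes are coded as dosages of **allele 1**, the alphabetically prior base
of each SNP's allele pair (A before C/G/T; C before G/T; G before T). Using a
fixed, line-independent reference allele — rather than the minor allele,
whose identity can differ between lines — keeps the between-line frequency
difference sign-stable, which window averaging requires. Coordinates are
1-based base pairs, as in MAP files; windows are half-open `[start, start+size)`.

QC removes individuals with ≥ 5% missing genotypes **first**, then SNPs with
combined-sample (both lines pooled) MAF < 5% or call rate < 95%. The order is
a package decision: removing bad individuals first prevents them from
deflating marker call rates. MAF is pooled across lines deliberately — a
marker fixed in opposite directions in the two lines has pooled MAF ≈ 0.5 and
must be retained; it is precisely the signal of interest. All individuals are
treated as diploid at Z markers (in the motivating design the phenotyped
birds are homogametic males); a hemizygous coding flag exists for flagged
females.

## Window scan

Per SNP: `p_line` = allele-1 copies / (2 × called individuals);
`AFD = |p_lean − p_fat|`; expected heterozygosity `H = 2p(1−p)`. Expected
(rather than observed) heterozygosity is the natural statistic when
individual genotypes are available; it depends only on allele frequency, which
also makes the p-q sweep identity exact.

Windows are 0.5 Mb, stepped every 250 kb (half-overlap; the step is a package
default — peaks are often sub-window-sized, and overlap halves the worst-case
misalignment between a sweep and the grid), anchored at the first marker
position rounded down to a step multiple, and dropped below 3 member SNPs to
avoid single-SNP artifacts. Window values are unweighted means over member
SNPs. Standardization is per chromosome with the sample (n−1) SD; AFD against
the chromosome's window-AFD distribution, each line's heterozygosity against
its own within-line distribution (more conservative than pooling the lines).
Chromosomes with fewer than two windows or zero spread yield NaN z-scores and
an `assessable = False` flag — never a silent zero.

Signature calling is an OR over four signals — `AFD ≥ 0.44`, `Z_AFD ≥ +4.0`
(one-sided: AFD is non-negative, so low extremes are uninformative),
`|Z_lean| ≥ 5`, `|Z_fat| ≥ 5` — with per-signal labels retained, since
different regions are typically supported by different signals. Overlapping
or touching flagged windows merge into one signature region. A
heterozygosity decrease in exactly one line labels that line as selected; an
increase is kept as a signal but annotated as possible selection from an
extreme initial frequency. The p-q sweep — an allele-frequency reversal
`p_t = q_0`, `q_t = p_0` — changes expected heterozygosity not at all while
producing `AFD = |1 − 2p_0|`; the AFD signals exist to catch exactly this
case, and `pq_sweep_scenario` constructs it exactly (integer allele counts)
for testing.

## LD, D′ confidence intervals, Gabriel blocks

For loci with allele-1 frequencies `p_A, p_B` and haplotype-11 frequency
`p_11`: `D = p_11 − p_A p_B`; `D′ = D/D_max` with the usual sign-dependent
`D_max`; `r² = D²/(p_A(1−p_A)p_B(1−p_B))`. Pairs with a monomorphic locus are
undefined and excluded from means and block rules. LD is computed within one
line at a time (selection signatures are per-line phenomena) and restricted
to a 1 Mb maximum pair distance by default.

The D′ CI evaluates the multinomial likelihood of the four haplotype counts
on a 101-point grid of |D′| with allele frequencies fixed at the observed
margins and the sign of D fixed at its point estimate; the grid is
normalized, and the bounds are the 5% inclusive lower- and upper-tail
quantiles. The interval is widened, when necessary, to include the grid
maximum-likelihood value so it always brackets the point estimate — this
matters only for near-flat likelihoods with a boundary maximum (tiny
samples). A 10⁴-point fine grid serves as the oracle in tests.

Blocks follow the Gabriel classification: strong LD = CI low ≥ 0.70 and high
≥ 0.98; strong recombination = CI high < 0.90; a span qualifies when it has
at least one informative pair and ≥ 95% of its informative pairs are strong;
maximal non-overlapping spans are kept greedily, largest first. A
`two_marker_strong_low` option raises the strong-LD bar for two-marker spans
(a simplified version of Haploview's size-stratified extras, default off);
both presets are runnable because manually curated block splits and the
default algorithm are known to disagree on real data.

## Haplotype tables and recombinants

Haplotype frequencies within a block are empirical counts over haplotype rows
with no missing base in the block (rows with missing bases are dropped and
counted, not imputed). A haplotype is *X-specific* when its frequency is
≥ 0.40 in line X and ≤ 0.02 in the other line; *shared* when above 0.02 in
both; *minor* otherwise. The thresholds are editorial defaults chosen so the
qualitative categories (virtually line-specific mains, a shared recombinant,
negligible remainders) are reproduced; both are configurable. Recombinant
detection joins two adjacent blocks per haplotype row and reports any
observed combination equal to parent-A's first-block segment plus parent-B's
second-block segment (A ≠ B).

## EHH

`ehh_at` implements `EHH = Σ_h e_h(e_h−1) / n(n−1)` over the distinct
extended haplotypes of the n carriers of a core haplotype — the probability
that two random carriers are identical from the core out to the evaluation
marker. Decay curves extend marker by marker in both directions from the
core boundary, with distances measured from the boundary marker's position,
until EHH < 0.05 (configurable) or the chromosome ends. Rows hitting a
missing base are dropped from that point onward (per-point complete case);
with complete data the curves are exactly non-increasing. Curves are
computed for every core haplotype with ≥ 5 carriers (rarer cores are
statistically meaningless); relative EHH is reported for information only.

For the between-line comparison ("which line was selected?") the package
uses the **pooled haplotype-homozygosity decay**: the probability that two
random haplotypes of the line — not just carriers of one core haplotype —
are identical from the core out to x. It starts at the core's haplotype
homozygosity instead of 1 and equals the count-weighted combination of the
conditional curves. The conditional (per-core-haplotype) comparison is
confounded in a way the pooled one is not: an unselected line's main
haplotype has fewer and more closely related carriers, so its conditional
EHH can decay *more slowly* than the swept line's even though the line as a
whole is far more diverse. The pooled statistic directly measures how much
of the line's local diversity selection has removed, and the trapezoidal
area under it (both directions summed) is the scalar compared between lines.

## Association

The model is `Y = SNP + f + e` with a half-sib family effect `f`. The default
GLS–LS route: (1) estimate the family variance component with the one-way
ANOVA moment estimator `σ̂²_f = max(0, (MSB − MSW)/n₀)` (simple, closed-form,
adequate for a variance used only as a working covariance; REML would be an
option, not a need); (2) estimate fixed non-genetic covariates (hatch by
default) by GLS under the implied compound-symmetry covariance and subtract
them from Y — the family effect itself stays in the model; (3) per SNP, test
an additive contrast (linear trend on dosage 0/1/2) and a dominance contrast
(heterozygote indicator) as two 1-df t-tests in a GLS fit using the same
covariance, whitened per family in closed form. Correcting for two effects ×
two traits in the Bonferroni denominator matches testing the two effects
separately. With a zero variance estimate everything collapses to OLS
(logged). The fixed-family mode replaces the covariance with family
indicator columns. SNPs lacking two genotype classes with ≥ 3 observations
are skipped with a reason; the dominance test alone is skipped when there
are no heterozygotes. p-values are two-sided from the t reference
distribution and floored at the smallest positive float.

## The simulator

`synthetic_data` generates the full breeding design: a base population whose
gametes are drawn from a finite founder haplotype pool, a random split into
two lines, then per generation: phenotype = Σ QTL effects + Gaussian noise
(the environmental SD is set from the founder genetic variance so that
heritability equals the configured h², default 0.5); truncation selection of
the top 25 males (sires) and top 100 females (dams) — downward in the lean
line, upward in the fat line, or random for an unselected line; random
1 sire : 4 dams assignment into 25 half-sib families; and meiosis with
per-interval recombination fractions from a uniform 3 cM/Mb map via the
Haldane function (equivalent to a no-interference crossover process observed
at the marker positions). Offspring sexes are split exactly half and half so
the parent supply is deterministic. The default genome is 5 chromosomes ×
400 markers at 22.5 kb spacing — chip-like marker density at a problem size
chosen so that replicated end-to-end runs remain cheap; `offspring_per_family`
(default 12) sets the census and hence the realized selected fraction
(25/150 among males, 100/150 among females).

**Founder structure.** The default founder pool consists of 20 recombinant
mosaics of **two ancestral haplotypes** (mean ancestry-segment length 1 Mb)
with 5% per-marker residual within-class diversity, and the planted QTL's
favored allele rides ancestral class A at its position. This models a base
population descended from a narrow pedigree bottleneck (a single grandsire
line) and has three consequences that match what divergent-selection data
actually look like: marker MAFs are chip-like (class-differing markers sit
near 0.5, class-identical markers are rare variants largely removed by QC);
selected regions sweep a coherent haplotype class in each line, producing
the observed pattern of two nearly complementary line-specific main
haplotypes; and an additive QTL at founder frequency ≈ 0.5 is exactly the
configuration in which "effect of one phenotypic SD" and "h² = 0.5" are
mutually consistent for a single locus. An unstructured pool
(`n_ancestral_haplotypes=None`, i.i.d. pool haplotypes) is available and is
used for the limiting-case tests (2-haplotype pool → complete LD; very large
pool → near-zero background LD); under it a planted common QTL produces a
soft sweep whose window AFD plateaus well below the calling threshold, which
is why it is not the default.

**What the generator does not emulate:** real chicken genetic maps
(macro/micro-chromosome rate differences), Z-linked inheritance (all
simulated chromosomes are autosomal; the dosage convention still accepts Z
markers in real data), genotyping error and missingness, family-indexed
(rather than individual) truncation selection, and the VLDL-based criterion
of the motivating experiment. Passing tests therefore demonstrate that the
statistics recover planted signals under a faithful *population-genetic*
rendering of the design, not that they are robust to assay artifacts.

**Truth output.** QTL positions and effects, per-generation allele-1
frequency trajectories at tracked markers per line (length generations + 1),
and per-generation line phenotype means.

## Pipeline

Stage order: screen (window scan) → corroborate (LD blocks, haplotype
tables, EHH) → associate. Each signature region is annotated with its
per-line block counts, the line-specificity labels of the region's
haplotypes, pooled EHH areas per line, and the most significant SNP within
the region ± 250 kb for each trait (the flank is a package default). The
inferred selected line is the line with the lower standardized
heterozygosity, tie-broken by the larger pooled EHH area. Reports are
regenerated byte-identically from the same config and seed: all orderings
are deterministic and floats are written with fixed formatting.

## Problem sizes in the validation suites

The statistical suites run at sizes chosen to make sampling error small
relative to the asserted margins: type-I error over 10⁴ permutation-null
tests (binomial SE ≈ 0.002 against an asserted band of 0.04–0.06), power
over 200 replicates at n = 400, and detection recovery over 100 simulated
replicates of the full 11-generation design at the default genome size.

## Known limitations

- The D′ CI tail convention (inclusive 5% per tail on a normalized grid)
  follows the common implementation of the Gabriel procedure but conventions
  vary between tools; it is configurable and documented rather than claimed
  canonical.
- EHH monotonicity can be violated when rows are dropped for missing data
  mid-extension (the per-point complete-case set shrinks); with phased input
  from a model-based phaser this does not arise.
- The moment estimator of the family variance is inefficient for severely
  unbalanced families; family sizes in the intended designs are balanced by
  construction.
- Haplotype frequencies are empirical counts; frequencies finer than
  1/(2n) — as model-based phasing posteriors can produce — are not
  represented.
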