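# Methods

## The phenotypic model

Per-seed rutin content (mg/g) of a parent line is treated as
Normal(μ, σ²) with the line's mean and SD; the F1 seed mean of a cross is
the mixture

    F1 = m·Pm + (1−m)·Pp,

where Pm and Pp are the maternal and pollen-parent group means and m is
the maternal effect. The estimator inverts this at the observed group
means, m̂ = (F̄1 − P̄p)/(P̄m − P̄p), and the pollen-parent effect is its
exact complement 1 − m̂. Assumptions worth stating:

* m̂ is a ratio of sample means, so it is consistent but not exactly
  unbiased at finite n; the test suite checks that its mean absolute error
  shrinks over 15 → 75 → 750 seeds per group and that m = 0.7 is recovered
  within 0.02 at 750 seeds per group.
* m is **not clamped** to [0, 1]. The formula admits values outside the
  interval (over-dominance or sampling noise when the parental means are
  close); results carry an `outside_unit_interval` flag instead of
  truncating.
* m̂ is undefined when P̄m = P̄p (division by zero); this raises a typed
  error rather than returning ±inf.
* m̂ is invariant under affine rescaling of all three means, so unit
  changes (mg/g vs %) cannot move it; this is a property test.

Significance uses Fisher's LSD: one one-way ANOVA per *plot* (all parent
lines and all F1 crosses grown together) pools the error variance
MSE = SSE/(N−k), and each pair is compared with
t = (ȳᵢ−ȳⱼ)/√(MSE(1/nᵢ+1/nⱼ)) on N−k df, two-sided, no multiplicity
adjustment (that is what LSD means). Per-seed values are the replicates
(n = 75 per group at the default design); a `lsd_scope="cross"` option
restricts the ANOVA to the (Pm, F1, Pp) triple. Star codes are
***/**/* at p < 0.001/0.01/0.05, otherwise the p-value itself is printed
at two decimals. With k = 2 the procedure reduces exactly to the pooled
two-sample t-test (a test asserts this identity). Degenerate inputs with
MSE = 0 return p = 1 for equal means and p = 0 otherwise, with a warning.

Block-average rows group crosses by the maternal parent's rutin class
(low < 0.1 ≤ medium ≤ 0.5 < high, in mg/g; both boundaries belong to
medium) and average the per-cross effect values arithmetically.

## The allele-expression model

A heterozygous maternal plant is crossed to (a) its own line — the
self-type cross — and (b) a homozygous line whose cDNA is the mapping
reference — the outcross. Per position we observe nucleotide counts
(A, C, G, T) in both samples. The analysis:

1. **Trim** the first and last 6 bases of each locus (base calls there are
   unreliable); position p is retained iff trim < p ≤ L − trim.
2. **Expression gate**: TPM per sample,
   tpmᵢ = 10⁶·(cᵢ/ℓᵢ)/Σⱼ(cⱼ/ℓⱼ) with estimated count c and effective
   length ℓ; a locus is analysed only when TPM is *strictly* above 1.0 in
   every sample of the pair. Without expression input all loci pass.
3. **Allele presence**: base b is present in a column iff count ≥
   `min_allele_count` (default 3) and count/depth ≥ `min_allele_fraction`
   (default 0.10). A position is a variant iff any present allele differs
   from the reference in either sample; zero-depth positions are skipped.
4. **Pattern classification** (pluggable strategy, default rule):
   * reference present in the self-cross allele set → **pattern I**
     (maternal ref/alt heterozygote; pollen reads confounded);
   * reference absent from self-cross but present in the outcross →
     **pattern II** (maternal plant carries only non-reference alleles;
     outcross reference reads must be paternal);
   * otherwise uninformative.
   Multi-allelic maternal sites (alt1/alt2 with a reference pollen allele)
   fall under pattern II.
5. **Ratio**: at a pattern-II position the pollen-allele ratio is
   100·count(ref)/Σ counts over the *present* alleles of the outcross
   column. Per locus we report the arithmetic mean of per-SNP ratios and
   its standard error (sample SD/√n), the SE being undefined — rendered
   "-" — when fewer than two pattern-II SNPs exist, and the mean undefined
   when there are none. A depth-weighted pooled ratio (Σ ref reads /
   Σ reads over pattern-II sites) is exposed separately; its sampling
   error is binomial in the pooled read count and it is the quantity used
   in recovery tests.
6. **Detection**: a locus counts as "pollen allele detected" when any
   replicate shows at least one SNP of either pattern — pattern-I-only
   loci are detected even though no ratio exists.

Replicates (maternal plants) are analysed independently and reported side
by side; nothing is pooled across replicates except the ratio-distribution
statistics, which deliberately pool locus × replicate averages.

Coding consequences of a SNP are annotated by translating the affected
codon (standard genetic code, CDS frame from `cds_start`) before and after
substitution; positions upstream of the CDS or in an incomplete terminal
codon are noncoding.

### Choice of the pattern taxonomy

The two-pattern rule above is this package's design choice. It is the
unique simple rule consistent with the observable facts of the design:
ratios exist only where pattern II occurs, SE dashes occur exactly at
single-pattern-II loci, and pattern-I-only loci still count as detections.
The classifier is injectable (`AlleleExpressionModel(classifier=...)`) so
an alternative taxonomy can be swapped in without touching the pipeline.

### Presence thresholds and low π

The default thresholds (count ≥ 3, fraction ≥ 0.10) exist to suppress
sequencing-error-level noise in visual-style calling. They have a known
side effect: when the true paternal fraction π is at or below
`min_allele_fraction`, pattern-II sites whose reference fraction falls
under the threshold are dropped, truncating the low tail and biasing the
mean ratio upward. Analyses of *error-free* simulations therefore use
threshold-free calling (count ≥ 1, fraction 0) — with ε = 0 every observed
base is a real allele and filtering is unnecessary. With real data at
ε > 0 the defaults are appropriate, and ratios near the threshold should
be interpreted with this truncation in mind.

## The synthetic-data generator

**Rutin tables.** Per line, `n_plants` × `n_seeds_per_plant` (default
5 × 15 = 75) draws from Normal(mean, sd²). Negative draws are redrawn
until non-negative (`clip_resample`), i.e. the realised distribution is a
truncated Normal — with the bundled high-rutin line (mean 0.60, SD 0.41)
the truncation bias is non-negligible, and a quadrature oracle test pins
the realised mean to the truncated-normal mean. F1 seeds are drawn around
m·Pm + (1−m)·Pp with SD defaulting to the mean of the parental SDs
(matching the intermediate spreads seen in real F1s); true m outside
[−0.5, 1.5] is rejected as implausible. All 75 seeds of a group are
i.i.d. by default; a plant-level random intercept (`plant_sd`, default 0)
is available because real within- vs between-plant variance components are
unknown.

**Pileups.** Per position of each locus the maternal genotype is ref/ref,
ref/alt, alt/alt or alt1/alt2 with configurable rates. The self-cross
pollen plant is drawn from the maternal line's population: at ref/alt
sites each of its alleles is ref or alt with probability 0.5 (one
segregating allele at frequency ½); at alt/alt sites it is alt/alt (the
line is effectively fixed there); at multi-allelic sites each allele is
alt1 or alt2. The outcross pollen allele is always the reference. Read
depth is Poisson(λ) per position and sample; each read is paternal with
probability π and otherwise one of the two maternal alleles with equal
probability; a miscall replaces the base uniformly by one of the other
three with probability ε. Counts are multinomial given these per-position
probabilities; a `read_log=True` mode draws reads individually and returns
the per-read log so tests can re-tally counts and ratios independently.
The truth object lists every variant site with genotypes, the expected
pattern label and π. An optional three-compartment mode mixes embryo
(1:1), endosperm (2:1 maternal:paternal) and testa (maternal) dosage into
an aggregate effective π; it is off by default because the measured
quantity is an aggregate ratio.

What the generator does **not** emulate: read-level artefacts (mapping
bias, duplicates, quality-correlated errors, indels), linkage between
positions (depths are independent Poisson, whereas real adjacent positions
share reads), allele-specific mapping loss, and expression-level noise
models. Passing recovery tests therefore show the estimator logic is
correct under idealised sampling, not that real libraries are free of
mapping bias.

## Numerical and reporting conventions

* Reports round half away from zero (0.375 → 0.38) at 2 decimals via
  `decimal`; all statistics are computed from unrounded values and rounded
  once at report time.
* Absent values are written as "-" and parsed back to an explicit absent
  marker, never 0.
* Positions are 1-based, closed, on the transcript; all tables are UTF-8
  TSV with "." decimals.
* The pathway table's detected-in-reference total spans all ten families,
  while the expressed / pollen-detected totals exclude GTR, whose single
  expressed locus appeared in one plant only; the per-family GTR cells are
  shown in parentheses.
* Band membership for the ratio-distribution summary is inclusive on both
  ends of [20, 40]%.
* Each pipeline stage logs record counts and the active thresholds.

## Problem sizes in the test suite

Tests and the acceptance script run at desk scale: simulated loci of
62–2000 bp at depth λ ≈ 200, three-replicate recovery runs of ~30 000
pooled reads per π level, 10⁵ draws for the truncated-normal oracle, and
30 replicate fits per sample size for the bias-shrinkage check. The whole
suite completes in a few seconds.

## Known limitations

* The LSD replicates per-seed values; if seeds within a plant are
  correlated, its p-values are anti-conservative (the plant-level random
  effect exists only in the generator, not in the test).
* m̂'s standard error is not reported; the LSD answers a different
  question (mean differences), and interval estimation for m would need
  the delta method or a bootstrap.
* The pattern taxonomy cannot distinguish a maternal alt/alt site from a
  site where the self-cross pollen plant happened to contribute the same
  alt allele; both are ratio-informative and treated identically.
* TPM gating uses the pair's expression estimates symmetrically; no
  attempt is made to model isoform-level expression.
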