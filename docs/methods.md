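# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `recburden`.

## Recessive genotypes and variant classes

A recessive genotype (RG) is one sample × gene event in which both gene
copies carry a qualifying allele. Qualifying alleles are rare (allele
frequency < 10⁻³ in both reference panels; absence from a panel counts as
rare, configurable) and damaging:

* **LoF** — stopgain, stoploss, frameshift indel, canonical splice site;
* **D-mis** — missense called deleterious by MetaSVM *or* with CADD ≥ 30
  (either score suffices; with MetaSVM missing, CADD alone decides);
* **nonframeshift indel** — damaging unconditionally, since in-frame
  indels are not scored by missense classifiers.

Synonymous variants form a parallel negative-control stream: every
statistic the package computes for damaging RGs can be recomputed for
synonymous RGs, where the expected signal is null.

Genotype-level QC (GQ ≥ 20, DP ≥ 8, MQ ≥ 40, VAF ≥ 25%, ≥ 3 supporting
reads, outside segmental duplications) is applied only in the contribution
stage, and there to all three members of a trio: gene discovery tolerates
marginal genotypes because the binomial test is robust to sparse noise,
while the contribution estimator is a difference of large expectations and
is sensitive to systematic false positives.

## RG calling

Homozygotes are called in every proband. In trios, a compound heterozygote
requires at least one qualifying heterozygous allele inherited from each
parent; a site carried by both parents is phase-ambiguous and excluded
(conservative — it can only lose true comphets, never invent them). In
singletons, a same-gene het pair is inferred *trans* only when the pair's
co-occurrence count in a reference panel is zero.

One RG per sample × gene: homozygotes take precedence, and when more than
two qualifying heterozygotes exist the reported pair carries the two most
damaging alleles (LoF > D-mis > nonframeshift indel, ties broken by lower
reference allele frequency, then position). This prevents combinatorial
double-counting when a gene harbours several rare alleles; the count of
interest is genotypes per gene, not variant pairs. An RG is `LoF_LoF` only
if every allele is LoF; this class feeds the LoF-only analyses.

## Inbreeding coefficients

*F* is estimated as the autozygous genome fraction: runs of homozygosity
are detected by sliding windows of 50 consecutive markers allowing ≤ 2
heterozygous calls, runs must span ≥ 1.5 Mb, and *F* = Σ ROH length /
covered autosome length. This replaces external HBD phasing with a
self-contained estimator that preserves the *F* ≈ autozygous-fraction
contract; window parameters are exposed in the API. The consanguinity
threshold is *F* ≥ 0.0009, the operational fourth-cousin value (the exact
canonical expectation is 2⁻¹⁰ ≈ 9.8 × 10⁻⁴; the analysis uses 0.0009).
Default strata: ≥ 0.03, [0.0078, 0.03), [0.002, 0.0078), [0.0009, 0.002),
< 0.0009 — approximate cousin-degree bands, configurable.

With 100-kb marker spacing the 50-marker window spans ≈ 5 Mb, so
autozygous segments shorter than that are missed; segments average
≈ 20 Mb (close kin), so the missed mass is ≈ 3% of autozygous length, and
window edges slightly over-extend detected runs in the other direction. On
simulated first-cousin offspring (true *F* = 1/16) the mean estimate lands
near 0.066, comfortably inside the 0.05–0.075 acceptance band.

## Expected RG counts from mutability

Per-gene expected RG counts are fitted from de novo mutability
*m*<sub>g</sub> by nonnegative least squares with no intercept:

    e_g = a·m_g + b·m_g²,  a, b ≥ 0.

The mechanistic reading fixes the degree at 2: a gene's damaging
allele-frequency sum is roughly proportional to its mutability, a
random-mating biallelic genotype needs two independent alleles (∝ m²), and
an autozygous genotype needs one (∝ m). The cohort's consanguinity mix
determines the fitted ratio a/b. The degree is config-exposed. Fitted
values are floored at ε = 10⁻⁶ (floored genes flagged) so enrichments
never divide by zero. The fit normally uses all genes — a genome-wide fit
is robust to sparse signal — but `exclude=` holds candidate genes out of
the fit, which matters for small synthetic panels where a strongly planted
gene would otherwise absorb its own signal.

Gene and gene-set tests are one-tailed binomial: p = P(X ≥ observed),
X ~ Binomial(n, e/n). Bonferroni significance uses α/19,347 = 2.6 × 10⁻⁶
by default (the exome-wide gene count); analyses of smaller panels pass
the tested gene count. BH FDR is computed over the genes actually tested.
The recurrent-gene statistic (number of genes with ≥ 2 RGs) is compared to
a multinomial permutation null with per-gene probabilities ∝ e_g and
empirical p = (1 + #perms ≥ observed)/(1 + n_perm), the +1 correction
avoiding zero p-values.

## Attributable fraction

Parents of affected children are depleted of disease-causing biallelic
genotypes relative to allele-frequency expectation, probands enriched. With
per-gene damaging allele-frequency sums Q_g computed from **parental**
in-cohort frequencies (probands would be enrichment-biased), the expected
biallelic count for individual i is Σ_g (1−F_i)·Q_g² + F_i·Q_g, and

    fraction = (obs_probands − exp_probands·obs_parents/exp_parents) / n_probands.

The (1−F)Q² + FQ form is this package's reconstruction of conditioning on
individual autozygosity; negative estimates are reported as-is (sampling
noise). LD pruning is implemented as carrier-co-occurrence pruning — the
rarer member of a same-gene pair co-carried by > 50% of the rarer member's
carriers is dropped — so no external LD reference is needed; the threshold
is exposed. Parental observed RG counts require phased parental genotypes
(hap1/hap2 columns — known phase in simulated data, or statistical phasing
upstream); proband counts come from the trio caller. The CI is a
nonparametric percentile bootstrap over trios (B = 1,000 by default),
recomputing in-cohort frequencies, expectations, and observed counts per
resample with the pruning mask held fixed; the CI construction is this
package's choice. Stratified estimates recompute frequencies within each
stratum by default; options share whole-cohort frequencies and the
parental depletion ratio, under which the whole-cohort estimate decomposes
exactly into the trio-weighted stratum combination (used as an arithmetic
self-check).

## Founder statistics

Hardy–Weinberg deviation uses the 1-df χ² with Yates continuity
correction, each |O−E| shrunk by 0.5 and floored at 0 — so tables exactly
at HWE give χ² = 0 (conventions differ; this one is documented and makes
the test conservative, which simulation at q = 0.02, n = 410 confirms).
Monomorphic sites return p = 1 by convention.

For a founder allele of age g generations carried by m chromosomes, each
one-sided shared ancestral segment is the minimum of m Exp(g) lengths, so
the two-sided shared genetic length L (Morgans) is Gamma(2, rate = m·g) and
the moment/ML estimator is ĝ = 2/(m·L). The CI uses the exact pivot
m·g·L ~ Gamma(2, 1); with only two observations' worth of information it
is wide — the point estimate is the reliable quantity, and both point and
CI methods are pluggable. A uniform 1 cM/Mb map is the default; a (pos,
cM) map file overrides. The shared haplotype itself is the maximal marker
interval around the focal site over which all carriers agree; marker
quantization shortens it slightly and chance off-segment agreement
lengthens it, effects that nearly cancel at 20-kb spacing.

## Lineage specificity

Expression rows are normalized by their maximum (ratio-of-max; all-zero
rows dropped with a warning). A gene is lineage-specific when its top cell
type is ≥ 5× every other cell type — every other, not just the
second-highest, which is the stricter reading of the rule; ties at the
maximum are never specific. UPGMA (average linkage) clusters the
normalized rows; the distance is Euclidean (config-exposed alternative:
correlation), since only the linkage is prescribed. Lineage gene-set
enrichment delegates to the binomial gene-set test on the
phenotype-restricted subcohort. Mouse→human symbol mapping is consumed as
a two-column table; unmapped genes are dropped with a warning count.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes; its
defaults are the package's study conditions.

* **Gene panel.** Mutability is log-normal (median 10⁻⁵, σ = 0.6, the
  scale of per-gene de novo probabilities). Each gene's damaging
  allele-frequency sum is Q_g = af_scale · m_g, split across enough
  variants that every allele stays below 10⁻³; pools always contain ≥ 1
  LoF and ≥ 1 D-mis plus synonymous (1.5×Q) and benign-missense (1×Q)
  variants. The default af_scale = 25 puts the median gene at
  Q ≈ 2.5 × 10⁻⁴, the upper range of real genes; analyses that need
  large-study cohort totals over a compressed panel raise af_scale
  explicitly (see study conditions below).
* **Trios.** Parental haplotypes carry each allele Bernoulli(q); one
  haplotype per parent per gene is transmitted. Genome model: 22 autosomes
  of 130 Mb, 1-based coordinates, uniform marker spacing.
* **Autozygosity** is per contiguous segment, not per locus: segment count
  ~ Poisson(F·G/μ) with exponential lengths (μ = 20 Mb, the close-kin
  scale), wrapped at chromosome ends so the expected autozygous fraction
  equals the assigned F exactly. Inside segments the proband is homozygous
  for a single ancestral haplotype whose content both parents also carry
  on their transmitted haplotypes; transmitted background heterozygotes
  are removed there, so autozygous regions are internally consistent. The
  default F mixture — 88% outbred, 6% at 0.004, 4% at 0.016, 2% at 1/16 —
  gives a mean F ≈ 2 × 10⁻³, matching a referral cohort with a
  consanguineous minority; the cohort's true F distribution is not public,
  so this is a modeling choice.
* **Markers.** A separate common-marker channel (MAF ~ U(0.1, 0.5), HWE
  outside segments, homozygous inside) supports ROH-based F estimation for
  probands. Parental marker genotypes are not emitted; the Mendelian
  consistency guarantee applies to the rare-variant channel.
* **Causal planting.** Each proband is causal with the target attributable
  fraction; a causal gene is drawn with probability proportional to
  penetrance (an affected-only cohort conditions on disease, so relative
  penetrance governs which gene appears), and an RG is planted — compound
  heterozygous through the two parents, or homozygous with probability
  0.3 (both parents carrying), roughly the outbred hom/comphet mix.
* **Founder haplotypes.** Carrier chromosomes retain the ancestral
  haplotype over one-sided Exp(age) genetic lengths and are resampled from
  marker frequencies beyond the breakpoints.
* **Not emulated:** linkage disequilibrium outside the founder haplotype,
  sequencing error beyond the optional QC-noise switch, X-chromosome
  inheritance, population structure in allele frequencies. Passing
  calibration on these cohorts therefore demonstrates the estimators'
  internal consistency under the stated model, not robustness to
  real-data artifacts such as LD-driven cis pairs or batch effects.

Identical configs produce identical outputs; all randomness flows through
the config seed.

## Study conditions for the property checks

* **Parameter recovery:** 50 cohorts of 5,000 trios, 600 genes, 30 causal
  genes, planted attributable fraction 0.02, default af_scale and F
  mixture; expected counts use the simulated true F so the check isolates
  the contribution estimator. The mean estimate must sit within 3 standard
  errors of 0.02, and the synonymous control within 3 SE of 0.
* **Null calibration:** 20 cohorts of 1,000 trios, 300 genes,
  af_scale = 600 (raising per-gene expectations to ≈ 0.07–3 so the
  binomial tests operate away from the degenerate zero-count regime), no
  causal genes; ≥ 19/20 cohorts must yield zero Bonferroni-significant
  genes at α/300.
* **Power:** the highest-mutability gene planted at ≈ 10× its null rate in
  2,000-trio cohorts, model fitted with that gene held out; detected in
  the majority of 5 replicates (observed power printed by the test).
* **Founder recovery:** 500 haplotype sets at age 50 with 6 carriers,
  1,500 markers at 20-kb spacing; the median age estimate must fall within
  15% of truth. F recovery: 100 first-cousin-offspring genomes.

These sizes keep the whole suite within a few minutes while leaving the
Monte-Carlo error well inside each acceptance band.

## Numerical and degenerate-input choices

* Binomial tails via `scipy.stats.binom.sf`; NNLS via
  `scipy.optimize.nnls`; Fisher, KS, χ², hypergeometric via scipy;
  BH via statsmodels. Hand-rolled counterparts exist only inside tests, as
  independent oracles.
* Zero expected counts raise errors in the estimators; the pipeline
  converts a degenerate class (no qualifying carriers in a tiny cohort)
  into a NaN row with a logged warning instead of aborting the run.
* Pair selection and leaf ordering are made deterministic by stable sorts
  with documented tie-breaks (severity, then allele frequency, then
  position; input order for clustering ties).
* Bootstrap resampling uses multinomial trio weights and sparse matrices,
  so B = 1,000 over thousands of trios costs milliseconds.

## Known limitations

* The inferred-comphet caller trusts panel absence as proof of trans
  phase; in real data, small panels under-count co-occurrence and
  overcall ICHs.
* The contribution estimator's (1−F)Q² + FQ expectation ignores
  within-gene LD beyond the carrier-co-occurrence pruning.
* The allele-age CI reflects only the m-carrier minimum-segment
  information and is far wider than estimators that use pairwise sharing
  among all carriers.
* The ROH estimator's resolution is set by marker density; F below
  ~10⁻³ is effectively indistinguishable from outbred at the default
  spacing.
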