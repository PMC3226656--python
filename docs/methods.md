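# Methods

## The problem and the model

Multiple loss-of-function (LOF) alleles of the same gene typically occur at
low frequency (1–5%) and act recessively: a phenotype appears in
homozygotes for any one allele, but also in **compound heterozygotes
(CH)** — individuals carrying two *different* LOF alleles on opposite
chromosomes.  Single-SNP association tests are nearly blind to such
architecture: the rare homozygote class is tiny (frequency `q²`), and
heterozygotes look like non-carriers.  Jointly, however, the CH genotype
is common relative to either homozygote — for two variants at equal
frequency `q` under independent Hardy–Weinberg equilibrium (HWE),

    f(AaBb) / f(AAbb) = 4·q²(1−q)² / q²(1−q)² = 4,

an identity that holds at every `q` and is the source of the power gain
from analysing pairs.

The **collapsed double heterozygosity (CDH) test** forms, for a SNP pair,
the 3×3 cross-genotype table (rows/columns = minor-allele dosage 0/1/2)
separately in cases (`D`) and controls (`U`), pools a declared set of risk
genotypes into one "risk-collapsed" column against everything else, and
tests the resulting 2×2 case/control table with a 1-df Pearson chi-square
(Fisher's exact test for sparse tables — see *Numerical choices*).

Two collapsing rules:

* **causal** — for directly observed causal variants: risk cells
  `{(2,0), (0,2), (1,1), (2,1), (1,2), (2,2)}` — every genotype carrying
  two or more minor alleles.  The three cells involving a double dose of
  both variants are essentially unpopulated at low MAF and low LD.
* **tagging** — for marker SNPs in LD with unobserved causal alleles:
  risk cells `{(2,0), (0,2), (1,1)}` only.  A chromosome carrying both
  *tag* minor alleles does not tag any causal allele when the causal
  alleles reside on different haplotypes (the causal–causal haplotype has
  frequency ≈ 0), so the remaining double-minor genotypes join the
  reference group.  This is the rule a chip-based genome scan should use.

## Disease model and analytic power theory (`analytic`)

Penetrance is `alpha·beta` (baseline prevalence × genotype relative risk,
GRR) on the risk cells and `alpha` elsewhere; validity requires
`alpha·beta ≤ 1`.  Sampling is population-based: at total size `n` the
expected case counts are `D = n·R∘F` and controls `U = n·R∘(1−F)`, where
`R` is the HWE product-frequency matrix.  The *expected P* of a test is
the chi-square upper-tail probability of the Pearson statistic evaluated
on these real-valued expected tables (1 df collapsed, 2 df for the 2×3
single-SNP margin).  No rounding is applied before the chi-square — the
construction is continuous, and a statistic below 1e-12 is clamped to 0 so
the null model reports P = 1 exactly.  `grr_threshold` inverts the
expected P in GRR by Brent bisection on the log scale over [1, 50], capped
at `1/alpha` where the penetrance model becomes invalid.

Reference points computed by the package (and re-derived by the
acceptance script): at `N = 10,000`, `alpha = 0.05`, `q = 0.05`, the
single-SNP 2-df test reaches `P = 5×10⁻⁸` only at GRR ≈ 5.59, while the
collapsed test crosses the same threshold at GRR ≈ 3.05; at
`q = 0.045`, GRR = 4, the expected collapsed chi-square is ≈ 51.9
(P ≈ 6×10⁻¹³).

## Synthetic data (`simulate`)

No external dataset is used; three generators emulate the study designs.

**Independent pairs.**  Dosages are binomial(2, q) per SNP; the phenotype
is Bernoulli with probability `alpha·grr` on risk genotypes.  The
power/type-I tables use MAFs drawn uniformly from [0.01, 0.05]
(configurable): the band is the stated study condition, but the
within-band density of a real genotyping chip is not available, so
uniform is declared.  Pairs are independent by default; real chip pairs
are a mixture (a majority with r² < 0.01, but roughly a quarter with
r² > 0.5), which matters for the comparisons below.

**Linked pairs at a target r².**  Two-locus haplotype frequencies are
constructed with positive D so that the causal minor allele rides
preferentially on tag-minor haplotypes; the feasibility bound
`r²max = min(q_c(1−q_t), (1−q_c)q_t)² / (q_c(1−q_c)q_t(1−q_t))` is
enforced with an informative error.  Individuals are two multinomial
haplotype draws; a quartet (two causal/tag pairs) is drawn with the pairs
mutually independent.

**Regions.**  A 200-kb chip region is emulated as `m = 38` SNPs (550K-chip
density) assembled from a founder pool of `K = 20` haplotypes with
Dirichlet(1) frequencies.  Each SNP's minor allele is assigned to a
greedily chosen founder subset whose total frequency approaches a target
MAF drawn from a chip-like mixture (45% uniform[0.01, 0.05], 55%
uniform[0.05, 0.5]); transmitted haplotypes mutate per site with
probability 0.002.  This yields block-like intra-region LD and controlled
MAF spectra.  Under the **recessive-set model**, a fraction
`portion_causal` of the SNPs with pool MAF < 0.05 is flagged causal (at
least one when the fraction is positive; exactly none when it is zero,
which gives an exact null region); an individual is *exposed* — phenotype
probability `alpha·grr` instead of `alpha` — if homozygous for any causal
variant or heterozygous at ≥ 2 distinct causal variants.  The CH
condition is genotype-level by default (phase not checked, matching what
an unphased test can see); a phase-aware option requires minor alleles on
opposite homologues.

**What the generator does not emulate.**  Founder-pool LD is blockier
than real chip LD: two rare SNPs assigned the same small founder are in
*perfect* LD, which happens more often here than on a real chip (where
only ~18% of close rare pairs have r² > 0.9).  Consequently rare
non-causal variants tag masked causal variants better than in the real
benchmark, which inflates the measured power of *both* regional tests and
of the burden comparator in particular.  Passing tests therefore
demonstrate correct mechanics and the CDH-vs-WSS ordering, not absolute
power levels on real chips.

**Reproducibility.**  All generators take an explicit
`numpy.random.Generator`; replicate loops seed one substream per
(seed, setting, replicate) via `default_rng([seed, i, rep])`, so results
replay bitwise and are order-independent.

## The WSS comparator (`wss`)

The weighted sum statistic uses Madsen & Browning's allelic coding:
variant weights `w = sqrt(n·q̂(1−q̂))` with
`q̂ = (mᵁ+1)/(2nᵁ+2)` estimated in the unaffected with pseudocounts,
per-individual score `Σ dosage/w`, midranks for ties, and the case
rank-sum standardized by `k = 1000` phenotype permutations (weights and
ranks recomputed per permutation, sample SD with k−1 denominator,
one-sided upper-tail normal P).  Genotype rows are deduplicated before
ranking — individuals with identical mutation profiles always share a
score — which makes the permutation loop a small matrix product plus a
sort over unique rows, exact to the definition.  Whether the original
benchmark used allelic or genotypic coding is not documented; allelic is
the comparator's published default and is what is implemented.

## Haplotype follow-up (`haplo`)

Two-locus haplotype frequencies are estimated by EM (initialized at
linkage equilibrium, tolerance 1e-8 on the largest frequency change, at
most 1000 iterations; only the double-heterozygote class is
phase-ambiguous and is fractionally assigned each E-step).  r² and D′
follow the standard definitions; monomorphic loci report r² = 0 with a
flag.  The CH-vs-DH follow-up contrasts case/control frequencies between
trans (true compound heterozygote) and cis (same-chromosome double
heterozygote) individuals.  **Limitation:** at exactly two loci every
double heterozygote shares the same cis/trans posterior, so hard
max-posterior assignment puts all of them in one class and the contrast
cannot be formed from unphased genotypes alone; the test accepts a
per-individual `trans_mask` (from phasing over a wider marker set or a
phased generator) and raises a clear degenerate-data error without it.

## Genome scan (`scan`)

The sliding window pairs each index SNP with the following `window_n`
SNPs (default 100) on the same chromosome; windows truncate at chromosome
ends and never span chromosomes.  The minimal pair P per window is
addressed to the index SNP and Bonferroni-corrected by the tests actually
performed, so the per-chromosome total is exactly
`Σᵢ min(n, N−i) = n·N − n(n+1)/2` (N > n), verified by enumeration in the
tests.  Monomorphic SNPs are skipped with a logged reason and excluded
from the correction factor.  The regional scan tests all pairs and
corrects by `m(m−1)/2`; its counting kernel forms all collapsed 2×2
tables at once from per-dosage indicator matrix products (float32
products are exact for counts below 2²⁴ and are cast back to integers),
and is unit-tested against the plain per-pair loop.

## Numerical choices

* No Yates continuity correction anywhere; the power theory is the
  uncorrected Pearson statistic.
* Sparse 2×2 tables switch to the two-sided Fisher exact test.  Two rules
  are provided: the default follows Cochran's convention (smallest
  *expected* cell < 5), `exact_rule="observed"` switches on the smallest
  observed cell instead.  The choice is consequential: Fisher's exact
  test is conservative, and at MAF 1–5% the collapsed tables are sparse,
  so the default test's realized type-I error at nominal 0.05 is ≈ 3.5%
  rather than 5%, and its power at stringent thresholds is lower than the
  observed-cell variant's.
* Missing data: pairwise complete-case per test; every result carries the
  usable `n`.  Genotypes are oriented to the minor allele per cohort at
  construction; an exact tie at MAF 0.5 keeps the input allele order.
* Empty margins are dropped before computing degrees of freedom; a table
  smaller than 2×2 after dropping is a degenerate-input error, except the
  collapsed test, which reports P = 1 flagged `no-risk-genotypes` when no
  individual carries a risk genotype (so scan bookkeeping stays exact)
  and falls through to Fisher when the risk column is populated in only
  one phenotype class.
* Identical SNPs or r² = 1 pairs are still tested (no silent skip);
  filtering is the scan layer's job.

## Problem sizes

The shipped acceptance computation uses 3,000 replicates per GRR for the
power tables (n = 10,213 individuals) and 300 synthetic regions
(n = 10,000) for the regional benchmark with k = 1000 WSS permutations;
the test suite uses 2,000 replicates and the same 300 regions.  These
sizes put Monte-Carlo standard errors at ~0.3–0.5 percentage points for
the table entries and ~0.03 for the regional powers.

## Known limitations

* Binary traits only; no covariates, logistic models or quantitative
  traits.
* Strictly pairwise collapsing; regions are handled by iterating pairs,
  not by collapsing more than two SNPs at once.
* Integer dosages only (no imputed fractional genotypes).
* The regional LD generator overstates rare-variant taggability (see
  above), so absolute regional power levels are optimistic relative to
  real chip data; the CDH-vs-WSS ordering is robust to this.
* With the default expected-count Fisher switch the test is conservative
  at chip-scale MAFs; users who want the nominal-level behaviour of the
  observed-cell rule can select it per call.
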