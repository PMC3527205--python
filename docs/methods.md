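# Methods

## Study design and selection model

The pipeline targets an extreme-phenotype sampling design: from a large
phenotyped population, only the two tails of the heat-pain suprathreshold
(HPST) distribution are exome sequenced, and gene-level rare-variant burden
is compared between tails. Tail membership requires concordance of the two
phenotypes: *insensitive* means HPST ≥ the insensitive cut-off **and** HPT
strictly above the population HPT median; *sensitive* means HPST ≤ the
sensitive cut-off **and** HPT strictly below it. HPST comparisons are
inclusive, the HPT-median comparison strict. The two built-in threshold
sets are (49.2, 45.5, 46.6) °C and (48.9, 45.4, 46.0) °C.

Twin resolution: a monozygotic twin enters only if the co-twin occupies the
same tail; a dizygotic pair split across tails is excluded entirely; a
concordant pair (either zygosity) contributes its more extreme member. "More
extreme" is lower HPST in the sensitive tail and higher HPST in the
insensitive tail, with HPST ties broken by the more extreme HPT, then by
lexicographic subject id — the tie-break is a package convention, since the
protocol does not define one.

## Variant QC

Sites with QUAL < 20 are dropped; genotypes whose recorded depth falls
outside [8, 300] are set missing; sites outside the capture target region
are dropped (an empty region table is refused rather than silently dropping
everything). Dual-caller consensus keeps a site iff both callers report it
and a genotype iff both agree; disagreeing genotypes are set missing — the
conservative substitute for re-calling, which is out of scope. Internal
coordinates are 0-based half-open, converted at the VCF (1-based) and BED
boundaries.

Gene blocks collapse qualifying functional classes (nonsynonymous, stop
gained/lost, splice site) inside each gene region. The minor allele
frequency is the minor-allele count over twice the number of non-missing
genotypes, per site; alleles are re-oriented (dosage → 2 − dosage) so MAF ≤
0.5. MAF is estimated from the pooled extreme sample by default (the
reference group for the 5 % threshold is not dictated by the design;
controls-only estimation is a one-line change at the call site). The
platform-concordance outlier threshold defaults to 0.90 — swapped or
contaminated samples sit near 50 % concordance and genuine samples near
99 %, so any value between separates them.

## The burden battery

All six tests consume the same per-gene input: a subjects × sites dosage
matrix, the binary phenotype *y* (1 = insensitive), per-site MAF q̂_j, and
"rare" meaning MAF < 0.05. Missing dosages are mean-imputed within site for
the score-based tests and treated as non-carrier for the carrier-based
tests.

* **Carrier fixed-threshold (CAST-style).** 2×2 table of carrier (≥ 1 rare
  allele) vs non-carrier by phenotype; two-sided Fisher exact p by the
  point-probability convention (sum over tables whose probability does not
  exceed the observed), which is what reproduces the published worked
  examples. No rare site → missing result.
* **Pearson χ² (CCRaVAT-style).** Same table, 1-df χ² without continuity
  correction; missing on zero margins.
* **Madsen–Browning.** Control-group weights
  q̂_j = (m_j + 1)/(2 n_ctl + 2), w_j = √(n_ctl q̂_j (1 − q̂_j));
  subject burden γ_i = Σ_j d_ij f_j / w_j with optional PolyPhen weights
  f_j ∈ {0.25, 0.5, 1} (benign / possibly / probably damaging, a {1, 2, 4}
  score-up renormalised by its maximum — the exact published weighting is
  unspecified, so the mapping is a documented, configurable default). The
  statistic is the absolute centred Wilcoxon rank sum of γ in cases, making
  the permutation test two-sided; either tail can carry the excess.
* **aSum (Han–Pan).** Per-site marginal logistic *score* tests screen for
  negative effects at α₀ = 0.1; flagged sites are recoded 2 − d before the
  gene-level score test of y on the dosage sum. The score-test form is used
  throughout (rather than maximum-likelihood fits): it is the standard
  permutation-friendly formulation, never fails on separation, and makes the
  per-permutation re-screening a pair of matrix products. α₀ = 0 disables
  screening and reduces exactly to the plain sum test.
* **SSU.** U = Σᵢ(yᵢ − ȳ)xᵢ; statistic U′U; permutation p by default, or a
  Satterthwaite scaled-χ² matching the first two permutation moments
  (V = ȳ(1−ȳ)·XᶜᵀXᶜ) on request.
* **Allele-matching kernel.** Pairwise similarity
  K(i,k) = Σ_j w_j (4 − 2|d_ij − d_kj|)/4 over sites observed in both
  subjects, w_j = 1/q̂_j (pseudo-counted), so matches at rare alleles
  dominate; statistic = mean within-tail minus mean between-tail similarity.
  This is a deliberately simplified similarity test that keeps the
  allele-matching principle without the full locus-specific integration
  machinery of AMELIA (a stated non-goal).

**Permutation engine.** Label shuffles preserving class counts;
p = (1 + #{T_b ≥ T_obs})/(B + 1) for sampled permutations (so p ≥ 1/(B+1)
and never 0). When C(n, n₁) ≤ B the engine enumerates all distinct label
assignments and returns the exact proportion ≥ the observed statistic.
Default B = 10 000 (a conventional choice; the study protocol being
reimplemented does not fix one); per-gene streams
are spawned deterministically from the battery seed. Ties are compared with
a relative tolerance of 1e-12 to keep floating-point noise from breaking
T_b = T_obs ties.

The battery keeps only genes where all six tests return a p-value
(mirroring the "consistently non-missing" restriction) and records, per
gene, the direction of effect as the sign of the rare-carrier-rate
difference (insensitive − sensitive) — the design does not define
"direction" operationally, and carrier excess is the quantity all six tests
respond to.

## Aggregation

Per gene the six p-values are summarised by the second order statistic
p₍₂₎ — a gene must look associated under at least two tests, so one
anomalous test cannot dominate. Cohorts are combined by Fisher's method,
X = −2(ln p₁ + ln p₂) against χ²₄, and genes tiered:

* **High**: min(combined, merged) < 0.00044;
* **Very High**: the cross-cohort combination itself is below 0.00044 *and*
  the merged-genotype reanalysis is more significant than that combination
  (synergy of direction across halves);
* **Medium**: not High and either summary < 0.001.

The tier thresholds are configuration constants defaulting to the printed
values; 0.00044 is not re-derived (no obvious inversion of Fisher's method
against the gene-count Bonferroni level reproduces it exactly). The
Very-High rule above is the reading consistent with the published gene
table, where genes reaching the High level only through their merged
summary are labelled High, not Very High.

The network-stage input list keeps genes with merged p₍₂₎ below 0.01 and
concordant non-zero direction in both cohorts. The sign-excess diagnostic is
an exact two-sided binomial test at probability ½ (point-probability
convention). Test-correlation matrices are Pearson correlations of −log₁₀ p
across genes, pairwise-complete; QQ coordinates pair sorted observed
p-values with uniform order-statistic expectations i/(n+1).

## Causal reasoning

A hypothesis is (regulator, direction), direction +1 = gain, −1 = loss of
activity. Sign propagation multiplies edge signs along directed paths of
length ≤ depth (1 or 2) from the regulator; a gene reached by paths with
conflicting net signs is *ambiguous*. Ambiguous genes count as reached for
enrichment but enter neither the consistent nor the contradicting class of
the correctness statistic — the cited method's exact treatment is not
published, so this choice is isolated behind the background-partition
interface.

*Enrichment*: one-sided hypergeometric upper tail P(X ≥ k) for k input
genes among n reachable, drawing K from the background N, with odds ratio
k(N−K−n+k)/((K−k)(n−k)).

*Correctness*: each input gene carries an assumed sign (default −1,
loss-of-function transcripts); the statistic is #sign-consistent −
#contradicting input genes. Under the null the input list is a uniform draw
without replacement from the background partitioned into (matching a,
contradicting b, other c) classes, so the statistic's distribution is an
exact trivariate-hypergeometric convolution, computed on the (≤ K × K) grid
in log space. With b = 0 it reduces exactly to the enrichment tail. The
statistic is configurable to #consistent alone; the difference form is the
default so contradictions penalise. The published correctness null lives in
an unavailable curated database, so this construction is a faithful,
independent formalisation — its corrected values are reproduced
arithmetically from the published nominal inputs, not re-derived.

Bonferroni correction uses H = the number of (node, ±1) hypotheses actually
evaluated on the supplied network (those reaching ≥ 1 background gene) —
the published H = 1108 is a property of that database and is reproduced in
fixtures, not hard-coded. Results are ranked by correctness then enrichment
p.

## Synthetic data generator

The generator's defaults emulate the study conditions: two cohorts sized
(101, 102) and (114, 96) (sensitive, insensitive); tail phenotypes drawn
from per-tail truncated normals matching the published tail means/SDs, so
classification recovers the generated labels exactly; a twin fraction of
0.2 whose co-twins are generated strictly less extreme in the same tail (so
twin resolution deterministically retains the sequenced member); site
frequency spectrum 80 % rare sites from Beta(0.5, 8) truncated to
(0, 0.05] — reproducing the observed excess of very rare novel variants —
plus 20 % common sites uniform on (0.05, 0.5]; functional classes drawn at
the observed exome mix (≈53 % nonsynonymous, 39 % synonymous, 7 % splice
site, 1 % nonsense); 20–30 sites per gene region (treating each region as a
union-exon gene so the planted-recovery regime of ≥ 20 rare sites holds at
the defaults); genotypes as Hardy–Weinberg Binomial(2, q) draws with no
linkage disequilibrium (an explicit non-goal); 1 % genotype missingness;
and a second capture design dropping 10 % of gene regions
(capture_overlap = 0.9), emulating the two-platform mismatch.

Planted genes multiply the per-site rare-carrier probability in the
designated tail by the configured relative risk (default 4.0): baseline
p = 1 − (1−q)², target p′ = min(1, RR·p), implemented by promoting
non-carriers to heterozygotes with probability (p′−p)/(1−p) (or demoting
carriers when RR < 1). The effect acts on carrier status — dominant coding,
matching the carrier-based tests — and is configurable. The true effect
size at the phenotype extremes is unknown, so it is a parameter, not an
assertion.

The network generator plants one loss-of-activity regulator whose
activating (sign-consistent under the loss hypothesis) targets are
over-sampled into the input gene list at rate 0.5; defaults are a
500-gene background, 30 regulators with out-degree 8–40 (60 for the
planted one), 100 gene–gene edges for depth-2 structure, and 50 input
genes. A deterministic reference geometry (one regulator, 204 activating
targets, 86 input genes with 12 overlapping, background 9275) reproduces
the published overlap arithmetic for end-to-end checks.

What the generator does **not** emulate: read-level error, population
structure and relatedness beyond the twin device, LD, per-gene site counts
as small as real exome regions, and annotation error. Passing tests
therefore demonstrate the statistical machinery under idealised
Hardy–Weinberg genotypes, not robustness to those real-data features.

## Numerical choices and problem sizes

QUAL/DP bounds are inclusive; genotypes without a recorded depth are left
untouched by the depth filter. Degenerate margins give enrichment p = 1
with an undefined-flagged odds ratio. Permutation tie comparison uses
relative tolerance 1e-12. The hypergeometric convolution works in log space
via log-gamma to avoid underflow at background sizes ~10⁴.

The test suite and the acceptance script use scaled study sizes chosen to
exercise each property cleanly: null calibration on 500-gene studies with
100 subjects per tail and B = 1000 (the suite pools three replicate studies
so the size check reflects the tests' true operating characteristics rather
than single-batch binomial noise); planted-gene recovery on 120-gene
studies (10 planted, carrier excess 4.0) over 20 replicates; regulator
recovery over 50 network replicates. Exact-oracle equivalences run at
n ≤ 8 where full label enumeration is feasible.

## Known limitations

Indels are not modelled (SNV dosages only); covariates and
quantitative-trait versions of the tests are out of scope; the merged-cohort
reanalysis assumes harmonised site keys across platforms; the correctness
null is this package's formalisation and need not match the proprietary
implementation it parallels; hypothesis-specific backgrounds (which some
curated-database workflows appear to use) are not implemented — the global
background is the documented default.
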