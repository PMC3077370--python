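# Methods

## Scope and data model

`alrexscan` analyses the 5′ end of coding regions for nucleotide features
associated with splicing-independent mRNA export (ALREX), contrasting genes
with and without 5′UTR introns (5UIs). The unit of analysis is a
`TranscriptRecord`: a coding sequence (multiple of 3, ≥ 150 nt after
filtering), its 5′UTR exonic length and 5UI count derived from a
refGene-style annotation in transcript orientation, and a leader class
(SSCR / MSCR / other) supplied as id lists. Throughout, the "positive" set
is the 5UI-lacking group (where ALREX features are expected) and the
"negative" set the 5UI-containing group.

Coordinates are 0-based half-open (UCSC convention); positions in
human-facing TSV output are 1-based and labeled as such. An intron counts
as a 5UI only when it lies entirely 5′ of the CDS start in transcript
orientation; a CDS failing both sanity filters is counted once under the
frame rule, which is checked first.

## Composition features

The leader window is the first 69 nt (23 codons) — long enough to contain
essentially any signal peptide — compared against the rest of the ORF.
Per-sequence features: adenine count/percentage; per-amino-acid counts;
and codon-class counts where a codon is "adenine-lacking" iff it contains
no A, tallied only over the seven amino acids possessing both codon kinds
(L, V, A, P, S, G, R), with the analogous thymine classes over nine
(A, T, P, H, N, D, R, S, G). Stop codons contribute to nucleotide counts
but not amino-acid tallies.

Group comparisons: adenine percentage uses the Wilcoxon rank-sum test on
per-sequence values with group medians and bootstrap standard errors;
count ratios (L:I, R:K, codon classes) are tested on pooled per-group
counts with Fisher's exact test, which is what yields an odds ratio with a
Woolf confidence interval. Per-gene mean ratios are emitted alongside
(genes with a zero denominator are dropped and counted) because both
summaries are informative and they answer slightly different questions.

## Exact statistics

The enrichment machinery is built on the closed-form hypergeometric pmf
`P(i | N, m, n) = C(m,i) C(N−m,n−i) / C(N,n)` with tail probabilities by
direct summation in log-gamma arithmetic; tails whose range covers the
whole support return exactly 1. Fisher's two-sided p uses pmf ordering
(the convention of mainstream statistical software; the relative gate
1 + 1e-7 absorbs floating-point noise when comparing pmf values). The
odds ratio is the sample ad/bc; the Haldane +0.5 correction is applied
only when the table contains a zero cell, leaving nonzero tables
untouched. A zero margin yields p = 1 with a missing effect rather than
an exception.

The Wilcoxon rank-sum test enumerates midrank assignments exactly for
pooled sizes ≤ 12 — midranks make the exact path well-defined under ties
(identical samples give p = 1, as they must) — and otherwise uses the
normal approximation with tie and continuity corrections. The bootstrap
median SE is the standard deviation of B seeded resample medians
(default B = 1000, minimum 100). Welch's t uses Satterthwaite degrees of
freedom; the one-sample KS test against a fitted normal inherits the usual
estimated-parameter caveat (nominal p is descriptive, not exact).

## Motif scanning and thresholds

A PSSM is a 4 × m column-stochastic matrix with background frequencies;
windows in the first 99 nt are scored as Σⱼ log₂(pⱼ(base)/bg(base)) (bits).
Log-odds was chosen because a Dirichlet-null column with mean equal to the
background then scores ≈ 0 on background sequence — a clean calibration.
Since every stride-1 window overlaps its neighbours, "collapse overlapping
windows to the best one" is implemented as greedy non-maximum suppression:
repeatedly retain the highest-scoring window (ties → leftmost) and
suppress all windows overlapping it. Retained hits are therefore pairwise
≥ m apart, and multiple non-overlapping occurrences per sequence survive —
a prerequisite for the multiplicity analysis. The scan is threshold-free;
t\* and t′ analyses filter the same hit set downstream.

t\*: candidate thresholds are the distinct observed per-sequence maxima;
a sequence is motif-containing iff its maximum ≥ t; the returned t
minimizes the greater-tail hypergeometric p of the 2 × 2 (motif-containing
× 5UI status) table, ties resolving to the more stringent threshold.

ROC curves sweep the union of observed maxima with ±∞ sentinels, so the
(0,0) and (1,1) endpoints are always present; TPR-at-FPR uses step
(staircase) interpolation — the TPR at the smallest threshold whose FPR
does not exceed the grid value. t′ maximizes the target's TPR minus the
null-median TPR at the target's own FPR, ties again to the larger
threshold. (The verbal definition of t′ in the source material is
ambiguous; this is its most literal reading.)

Null motifs draw each column independently from Dirichlet(α) with α equal
to the background frequencies (Σα = 1, hence sparse, information-rich
columns comparable to real motifs). The background is the empirical base
composition of the pooled first-99-nt prefixes. The percentile of a target
at a grid FPR is the fraction of null motifs with strictly lower TPR; a
mid-tie variant (strictly below + half of exact ties) is also reported and
is the right quantity for calibration checks, because the strict count is
sub-uniform when TPRs tie on the discrete 1/n grid. A null-drawn target's
mid-tie percentile is uniform (KS-checked in the test suite over 200
repeats).

The exhaustive degenerate k-mer scan (alphabet A, C, G, T, S = C/G,
W = A/T; k ≤ 8) is a deliberately simple, fully enumerable discriminative
search: patterns are ranked by the greater-tail hypergeometric p of their
per-sequence presence in the positive versus negative set, Bonferroni-
corrected over the 6^k enumeration. It is a stand-in for external
discriminative motif discovery tools, not a reimplementation of any of
them.

## Redundancy reduction

Before motif statistics, near-duplicate leaders are collapsed: first-99-nt
prefixes are locally aligned pairwise (match +1, mismatch −1, gap −2, via
Biopython's PairwiseAligner), pairs with identity ≥ 0.9 over ≥ 60 aligned
columns are linked, single-linkage components form clusters, and one
seeded-random representative per cluster is kept. The identity/overlap
thresholds replace a database-size-dependent E-value criterion with an
equivalent intent: merge only near-duplicates. An 8-mer-sharing prescreen
skips pairs that cannot reach the threshold (≤ 6 mismatches over 60
ungapped columns force a shared exact 8-mer); it is a speedup, not a
change of definition, and the test suite's oracle aligns all pairs.
Alignment is forward-strand only, appropriate for mRNA-level motifs.

## Category enrichment

Per term, the 2 × 2 (in-term × 5UI status) two-sided Fisher p and
LOD = log₁₀ OR (Haldane-corrected only at zero cells) are computed; rows
sort by |LOD| (or ascending LOD for the depletion view). Family-wise
adjustment is Westfall–Young min-p: labels are permuted over transcripts
preserving the number of 5UI⁺ genes — preserving the dependency structure
between overlapping terms — and
p_adj = (1 + #{permutations with min p ≤ p_raw}) / (1 + R) with add-one
smoothing and monotone step-down enforcement. Default R = 10,000; tests
and the acceptance script use R = 500–1,000, which bounds the family-wise
error just as well at the cost of p-value resolution.

The 5′UTR-length control stratifies transcripts into length-quantile bins
(default 10) and applies the Cochran–Mantel–Haenszel common-odds-ratio
test of (leader-class × 5UI) across strata (statsmodels'
StratifiedTable); zero-margin strata are dropped with a warning and
reported in the audit output. This is a stated dialect of a
length-matching correction, not a claim of equivalence to any particular
published variant.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with defaults set to the genome-wide study conditions: group sizes
2,594 (5UI⁻) / 938 (5UI⁺); CDS length 300 nt; relative leader adenine
depletion 0.182; pooled L:I and R:K odds ratios 1.55 and 2.15 (midpoints
of the reported interval estimates); planted consensus CGSSGC with
presence 47.5% vs 22.2% and ≥ 2-copy fractions 26.8% vs 7.14%;
hit-position medians 39 vs 45 (0-based window starts, 5′-skewed); 5′UTR
length medians 150 vs 249 nt (log-normal, σ = 0.6; 99 nt difference);
one fixed 500-nt 5′UTR intron for every 5UI⁺ record.

Mechanics and calibration:

- Leader codons (positions 2–23; codon 1 is ATG) are drawn from a
  hydrophobic-rich amino-acid profile with a two-parameter nucleotide
  tilt: synonymous codons weighted by wA^(#A) · wT^(#T), wT = 0.6 in both
  groups. The L:I and R:K preferences are applied at the amino-acid level
  (√OR up-/down-weighting in the positive group), so the pooled odds
  ratios hit their targets in expectation independently of the nucleotide
  tilt.
- Because the window adenine count is an integer out of 69, the
  configured *relative median* depletion must be realizable on that grid:
  the default baseline (11/69 ≈ 15.9% adenine for 5UI⁺ leaders) puts the
  group medians at 11 and 9 adenines, whose relative difference 2/11 =
  0.1818 is the achievable value closest to 0.182. wA is solved by root
  finding so that the median of the *post-planting* count distribution —
  the 22-codon convolution minus a binomial-thinned removal over the
  planted-overlap distribution (the consensus contains no adenines) —
  sits mid-cell on the target integer, making sample medians stable.
- Planted copy counts follow P(≥1) = presence, P(≥2) = multi (two copies
  at most); positions are negative-binomial (r = 3) truncated to the
  scannable range, with the parameter solved on the exact mixture pmf the
  planting procedure induces (single-copy marginal plus the
  separation-conditioned pair marginal) so the realized position median
  lands on the configured value. Degenerate letters are instantiated
  uniformly.
- The first 99 nt are scrubbed of chance consensus matches outside
  planted positions (offending codons resampled; a record that cannot be
  cleaned — e.g. a match straddling a planted site — is regenerated), so
  the planted presence/multiplicity fractions and positions are exactly
  identifiable by the scanner. The truth ledger records every planted
  instance and the realized group parameters.

What the generator does **not** emulate: real codon usage tables (the ORF
body is uniform over sense codons), GC isochores, full-length mRNAs with
3′UTRs, alternative splice variants with distinct leaders, graded or
degenerate motif matches (planted instances are exact consensus draws),
or any dependence between leader composition and 5′UTR length beyond the
group labels. Passing tests therefore demonstrate that the pipeline
recovers known planted structure under idealized sampling noise — not
that it would reach the same power or effect estimates on genome
annotations, where motif matches are graded, sequences are phylogenetically
correlated, and annotation error is present.

One consequence of exact planting deserves note: with a uniform
background, all consensus instantiations score identically and the
target's ROC is a step function with no operating points below
FPR = presence of the 5UI⁺ group. The empirical background (A ≈ 0.18,
C ≈ G ≈ 0.28, T ≈ 0.26 on default data) breaks this degeneracy —
instantiations score distinctly — which is one more reason the null and
the scoring share the pooled empirical background.

## Problem sizes used in tests and the acceptance script

Recovery and ranking checks run at n = 500 per class with 1,000 random
motifs (the genome-wide analysis used 40,000–100,000; the `full` pipeline
profile restores those sizes), the null self-rank calibration at
n = 150 per class with 100 nulls × 200 repeats, and the family-wise error
calibration over 200 simulated datasets × 50 terms × 500 resamples. The
oracle equivalence checks are exhaustive over all 2 × 2 tables with
N ≤ 50 and cover 1,000 random scan instances. These sizes were chosen so
the whole validation is a few minutes of desk compute while every
statistical guarantee is still sharply testable.

## Known limitations

- The exact Wilcoxon path is combinatorial and restricted to pooled
  n ≤ 12; beyond that the tie-corrected normal approximation is used.
- The pmf-ordering two-sided Fisher p relies on a 1 + 1e-7 relative gate;
  tables with astronomically close but unequal pmf values could in
  principle be mis-ordered (not observed anywhere in the exhaustive
  N ≤ 50 sweep).
- Bonferroni over the 6^k degenerate k-mer enumeration is conservative
  because patterns are heavily nested.
- The CMH length control conditions on quantile bins, not exact lengths;
  residual within-bin confounding is possible with very coarse strata.
- Percentile ranking against n_null nulls has Monte-Carlo resolution
  1/n_null; the convergence test bounds the n_null = 1,000 error at 0.03.
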