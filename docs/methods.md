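# Methods

This note records the models, rules, parameter choices and numerical
conventions behind `cistroscreen`, and what the synthetic benchmarks do and
do not establish about real data.

## Threshold calibration on control loci

Peak callers emit a q-value per peak; rather than adopting a universal
cutoff, the pipeline calibrates one against an experiment-internal control
design: a positive control locus (an androgen-responsive enhancer such as
the *KLK3* enhancer) that a working AR ChIP must detect in every ChIP
sample, and samples/loci where a call would indicate non-specific signal (a
housekeeping promoter; a no-androgen or no-antibody control sample).
`calibrate_q_threshold` returns the largest `t` such that the genome-wide
rule "called iff q < t" (strict) detects the positive locus in every
positive sample, in no negative sample, and never calls the negative locus
anywhere. Because the rule is strict, the supremum is the limiting negative
q itself, which is what the function returns; when no negative-side peak
constrains the choice, a fallback cap (default 0.25) applies. If some
positive sample's best q is at or above the limiting negative q the controls
are not separable and calibration fails loudly with both values. On the
synthetic benchmark, where the separation point is planted at q = 0.129,
calibration recovers exactly that value.

## Consensus sites, annotation, classification

Filtered peaks are merged across replicates per chromosome by single-linkage
on ≥ 1 bp overlap: a chain of pairwise-overlapping peaks forms one maximal
cluster whose interval spans all members. Support counts *distinct
replicates* (two peaks from one replicate count once), and clusters below
`min_support = 2` (of 3 replicates) are dropped. The per-site signal is the
arithmetic mean of contributing peak signals. Tests verify the merge against
a brute-force pairwise-overlap connected-components oracle on random
instances.

A gene is annotated as bound if a consensus site overlaps its body or its
strand-aware upstream window `[tss − 20000, tss)` for + genes and
`(tss, tss + 20000]` for − genes (0-based half-open internally). Two
readings of "within a 20-kb range" exist; the default mode `upstream`
implements the promoter rule (in-gene OR ≤ 20 kb upstream), and mode
`symmetric` (gene body ± 20 kb, strand-agnostic) is available for the
broader reading. Overlap is ≥ 1 bp with no minimum-fraction requirement.
Annotation is strand-symmetric: mirroring all coordinates and flipping
strands leaves the bound-gene set invariant (property-tested).

Genes bound in exactly one condition are exclusive by presence. Genes bound
in both are classified by signal fold change FC = (s_A + ε)/(s_B + ε) with
pseudocount ε = 0.01 signal units (guards division by zero; negligible at
realistic signals): FC ≥ 2 or FC ≤ 0.5 (inclusive, exactly as printed) makes
the gene exclusive, otherwise shared. Making presence-only genes exclusive
regardless of fold change keeps the rule total over all bound genes; the
partition is disjoint and exhaustive by construction and is re-checked on
every run. Overlap percentages are rounded half-up to one decimal, matching
how such concordance figures are conventionally printed.

## Expression filters and candidate integration

Differential expression is a threshold rule, not a count model: condition
means across replicates, expression floor fpkm > 3.0 applied to the
*upregulated* condition, mean fold change > 4.0 (both strict; the microarray
re-analysis mode of the same screen uses 1.5), pseudocount ε = 0.01 on both
means. Lists are ranked by fold change (the ranking statistic behind "top
30" is not uniquely determined by the published text; mean-difference
ranking is available via config), with boundary ties broken by gene id so
the head is deterministic.

The alteration filter takes the max percent over cohorts with an inclusive
5% boundary. A final candidate must be in a top-30 list, pass the alteration
filter, carry an ARBS in either condition, and have a true external
validation flag; flags record known qRT-PCR failures, and genes without an
entry are treated as validated. Candidate records retain every intermediate
flag so the attrition (e.g. 12 → 7) is auditable, and integration is
monotone: relaxing any single threshold can only grow the final set
(property-tested).

The microarray signature filter requires a one-way ANOVA F-test p ≤ 0.001
(scipy's F distribution on an explicit between/within decomposition —
tests verify 10-significant-figure agreement with a long-hand oracle), mean
fold change > 2.5 of the target over the comparator group, and ≤ 10% overlap
of the two groups' 95% t-based CIs for the mean. Overlap is normalised by
the shorter interval (normalisation by the union is available); zero
within-group variance gives a point CI, treated as zero overlap unless the
group means coincide. Probe collapse drops A- and M-flagged probes first,
then takes the per-gene, per-sample maximum; probes mapped to more than one
gene are rejected outright.

## Enrichment screen

The single-sample enrichment score uses rank weights `r_i = N − pos_i + 1`
raised to α = 0.25 (the conventional single-sample weighting; α is
configurable) and the *total-sum* statistic ES = Σ_i [P_in(i) − P_out(i)]
rather than the maximum deviation. Ties in expression are broken by gene id,
making the score deterministic and a pure function of ranks, hence invariant
under strictly monotone transforms of expression (property-tested). Sets
equal to, or disjoint from, the expressed universe are rejected (P_out or
P_in would be undefined). Score matrices are min-max normalised to [0, 1]
using the global extrema by default (per-set normalisation available);
constant matrices are rejected.

Differential enrichment per set uses d = (mean_A − mean_B)/(s + s0) with
s the pooled two-sample scale. The fudge factor s0 defaults to the median of
per-set s over the run — a deliberate, simple stabiliser; a ROC-optimised s0
is out of scope, and an explicit s0 can be supplied (needed when scores are
noise-free and every s is 0). Inference is two-sided by permutation of group
labels with +1 smoothing, p = (1 + #{|d*| ≥ |d|})/(1 + #splits); all
C(n, n_A) splits are enumerated when that count is ≤ 200, otherwise splits
are sampled with a seeded generator. A |d*| ≥ |d| comparison uses a 1e-12
relative tolerance so the observed split always counts. q-values are
Benjamini–Hochberg step-up (via statsmodels), and the two-dataset screen
intersects sets with q strictly below each dataset's FDR bound (0.075 and
0.001 by default). Note BH is monotone in p-rank but *not* idempotent;
tests assert monotonicity and agreement with a long-hand step-up recursion.
Over-representation uses the upper-tail hypergeometric probability of at
least the observed overlap.

## Assay formulas

PCR efficiency is fixed at 100% (base 2, a module constant). Percent input
adjusts the input Ct for the reserved fraction before exponentiating;
it is invariant under shifting both Cts (property-tested). An infinite Ct is
accepted as the no-amplification sentinel and yields 0% with a warning.
Tumor volume is V = L·W²·0.5 with L required to be the largest diameter.
Repeated-measures group comparison of growth curves is deliberately left to
standard statistics packages; only the per-measurement quantification is
implemented here.

## Synthetic benchmark: what it emulates and what it does not

The generator reproduces the *structure* of a paired AD/CR xenograft study:
two conditions × 3 ChIP replicates plus one negative-control sample,
fixed-width 400-bp peaks standing in for caller output, control loci on a
dedicated control contig with the true/non-specific separation planted at
q = 0.129, gene bodies of 1–10 kb spaced ≥ 45 kb apart (so 20-kb promoter
windows never overlap and every planted site annotates exactly one gene),
binding classes allocated by largest-remainder rounding of the configured
fractions, shared-gene signal ratios drawn strictly inside (0.5, 2),
log-normal mean-one expression noise, sub-5% background alteration
frequencies, and uniformly drawn gene sets plus one planted coherent set.
One pseudo-random stream per artifact, derived from the master seed by
CRC32-labelled sub-seeding, keeps outputs stable when generators are added.

Default noise levels — 10% replicate dropout, 5 spurious peaks/Mb/sample,
expression sigma 0.25 — are stipulated realistic magnitudes, not estimates
from any dataset: no published noise model exists for these assays at this
granularity. Spurious peaks are placed only ≥ 20 kb clear of any gene body,
so they stress the consensus caller, not the annotator. Consequently the
zero-noise recovery results establish *correctness of the chain's logic*
(every filter, threshold and merge behaves exactly as specified), and the
dropout grid establishes the expected monotone degradation; they do not
establish robustness to correlated artifacts real ChIP data exhibit
(copy-number bias, mappability, fragment-length effects), which are
explicitly out of scope.

## Problem sizes and determinism

The benchmark-scale acceptance run uses 10,000 genes on a 600-Mb synthetic
genome with 2 × 3 replicates — comfortably the size of the real gene-level
analysis — and completes in seconds; oracle-agreement checks use 1,000
random instances each (≤ 200 peaks; N ≤ 50 expression profiles). All
randomness flows from explicit seeds; pipeline re-runs with identical config
and inputs are bit-identical, and the run manifest records the config hash,
seed and package version. Pipeline outputs are written to a staging
directory and renamed into place only on success, so a failed stage leaves
nothing behind.

## Known limitations

Peak calling itself, read alignment, motif analysis and histone-mark
integration are out of scope: peak calls are inputs. The exact moderated-
statistic variant and its s0 rule, the ssGSEA normalisation scope, and the
"top 30" ranking statistic are under-determined by the published
descriptions this chain follows; the defaults above are declared choices
with config overrides, not inferences. The alteration table is an input —
cohort alteration calling is not reproduced. Validation flags are ingested,
never computed.
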