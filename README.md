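# cistroscreen

Integrative screening of androgen-receptor (AR) cistromes and
transcriptomes for castration-resistant prostate cancer (CRPC) candidate
genes.

In AR-dependent CRPC, the receptor keeps driving transcription after
androgen deprivation, but from a partly remodelled set of binding sites.
Studies that profile paired androgen-dependent (AD) and castration-resistant
(CR) tumors with AR ChIP-seq and RNA-seq identify therapeutic candidates by
intersecting three kinds of evidence: where AR binds, what changes in
expression, and which genes are recurrently altered in patient cohorts.
`cistroscreen` implements that post-peak-call analysis chain as a tested,
reusable Python library, together with a synthetic-data module that plants a
known truth so every stage can be validated without any external download.

## What it computes

**Cistrome side** (`cistroscreen.cistrome`)

- *Control-locus calibration*: given peak calls for each sample and a
  positive/negative control design (e.g. the *KLK3* enhancer, which a
  working AR ChIP must detect, vs a housekeeping promoter, which it must
  not), find the largest q-value threshold `t` such that calling
  "q < t" genome-wide detects the positive locus in every ChIP sample and
  never in a control sample.
- *Consensus binding sites*: peaks surviving the threshold are merged across
  replicates by single-linkage on ≥ 1 bp overlap; a consensus AR-binding
  site (ARBS) must be supported by at least `min_support = 2` of the 3
  replicates.
- *Gene annotation*: a gene carries an ARBS if a consensus site overlaps its
  body or its strand-aware 20-kb upstream promoter window.
- *Differential classification*: genes bound in only one condition are
  condition-exclusive; genes bound in both are exclusive when the binding
  signal fold change FC = (s_AD + ε)/(s_CR + ε) satisfies FC ≥ 2 or
  FC ≤ 0.5, and shared otherwise. Venn counts and cross-study overlap
  percentages (rounded half-up to one decimal) summarise the partition.

**Expression and integration side** (`cistroscreen.screen`)

- *Threshold-rule differential expression*: a gene is upregulated in CR iff
  its CR mean fpkm > 3.0 and mean fold change > 4.0 (both strict), ranked
  by fold change; the top 30 of each direction enter the candidate chain.
- *Alteration filter*: a gene passes iff it is altered in ≥ 5% of cases in
  at least one cohort (inclusive boundary).
- *Candidate integration*: a final candidate must be top-ranked DE,
  frequently altered, carry an ARBS in either condition, and survive
  external qRT-PCR validation; each record keeps per-filter provenance.
- *Microarray re-analysis*: probe collapse by per-gene maximum after
  dropping poor-quality (A/M-flagged) probes, and a signature filter
  requiring one-way ANOVA p ≤ 0.001, fold change > 2.5, and ≤ 10% overlap
  of the two groups' 95% t-based confidence intervals.

**Pathway side** (`cistroscreen.enrich`)

- *ssGSEA*: per sample and gene set, with genes ranked by expression
  descending and rank weight `r_i = N − position_i + 1`,

      ES = Σ_i [ P_in(i) − P_out(i) ],
      P_in(i) = Σ_{j≤i, j∈S} r_j^α / Σ_{j∈S} r_j^α,
      P_out(i) = |{j≤i, j∉S}| / (N − |S|),    α = 0.25 by default.

- *Moderated statistic*: per gene set, `d = (mean_A − mean_B)/(s + s0)`
  with `s = sqrt((1/n_A + 1/n_B)·pooled variance)` and fudge factor `s0`
  defaulting to the median per-set `s`; two-sided permutation p-values
  (exhaustive when the number of label splits is ≤ 200), Benjamini–Hochberg
  q-values, and a two-dataset common-pathway screen with strict FDR bounds
  (q < 0.075 and q < 0.001 by default). A local hypergeometric
  over-representation test stands in for web-service pathway analysis.

**Assay formulas** (`cistroscreen.assay`): ChIP-qPCR percent input and fold
over IgG, 2^−ΔΔCt relative expression, caliper tumor volume
V = L·W²·0.5 mm³, and blank-corrected proliferation normalization.

**Synthetic benchmarks** (`cistroscreen.synthio`): seeded generators for
genomes, two-condition cistromes with planted exclusive/shared genes and
control loci, log-normal expression with planted fold changes, cohort
alteration tables, and gene-set collections with a planted coherent set —
all with a machine-readable truth table.

## Worked example

`examples/candidate_screen.py` runs the integrative chain on the published
12-gene worked-example table and recomputes the published summary numbers:

```
12 genes entered the chain; 7 final candidates:
  CLSTN2, CP, MGLL, NMNAT2, OPRK1, ROBO1, TRPA1
  dropped TSPAN7: no AR-binding site
  dropped STARD4: no AR-binding site
  dropped ADRIF1: no AR-binding site
  dropped DPP4: failed qRT-PCR validation
  dropped KCTD12: no AR-binding site

overlap with tissue_AD: 810/1371 = 59.1%
overlap with tissue_CR: 730/1371 = 53.2%
overlap with cells_AD: 59/396 = 14.9%
overlap with cells_CR: 52/396 = 13.1%
venn total xenograft_AD_vs_CR: 11083 bound genes
venn total LNCaP_vs_AILNCaP: 5406 bound genes
```

Twelve top-ranked, frequently altered genes enter; four lack an AR-binding
site and one fails validation, leaving the seven final candidates (among
them *OPRK1*). The overlap lines are the percentage of external reference
cistromes (human tumor tissue and cell lines) shared with the xenograft
cistrome; the Venn totals are the bound-gene universes of the two
comparisons.

The other example scripts each exercise one capability end to end:
`consensus_cistrome.py` (calibration → consensus → annotation →
classification on synthetic peaks), `enrichment_screen.py` (a planted
coherent gene set surfacing with the best q), `assay_quantification.py`
(the qPCR/volume formulas), and `full_pipeline.py` (the whole screen from
files on disk via `RunConfig`/`run_screen`). A thin CLI wraps the two
shell-worthy entry points:

```sh
cistroscreen simulate --out bench/ --seed 1      # synthetic bundle + truth
cistroscreen run --config run.yaml               # full screen from a config
```

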