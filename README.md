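# rddmscan

Comparative transcriptome/epigenome analysis for RNA-directed DNA
methylation (RdDM) mutant studies, modelled on the maize Pol IV
(*rpd1/rmr6*) vs B73 wild-type comparison.

## The scientific problem

Plant RNA polymerase IV drives the production of 24-nt siRNAs that guide
cytosine methylation and transcriptional silencing of transposable
elements (TEs) and nearby genes. Loss of Pol IV removes most 24-nt
siRNAs and mCHH islands, yet triggers only a modest set of conventional
differentially expressed genes — the interesting signal is distributed:
a small global rise in the transcribed fraction of the genome, a shift
in the whole expression distribution, and effects concentrated on genes
with TE insertions near their transcription start sites. `rddmscan`
packages the statistics needed to see that distributed signal:

- **Transcribed fraction** — the share of the genome covered by at
  least `min_reads` alignments after seeded down-sampling to a common
  alignment count, averaged over replicates; genotypes are compared as
  the relative increase `100·(b−a)/a`.
- **Expression-distribution comparison** — an expressed-gene filter, a
  Fisher exact test on the 2×2 zero-FPKM × genotype table, and a
  two-sample Kolmogorov–Smirnov test with the conjunction decision
  rule: distributions are called different only when both
  `D_obs > D_crit = c(α)·√((n₁+n₂)/(n₁n₂))` (with `c(0.01) = 1.62762`)
  and the asymptotic p < α. Positive FPKM values are histogrammed in
  unit-width log₂ bins centred on integers (bin 0 ⇔ FPKM = 1) with
  cumulative curves and their maximum vertical distance; Mann–Whitney U
  compares expression between genotypes per TE superfamily.
- **TE context** — strand-aware classification of genes by TEs in the
  1-kb upstream flank, gene body, 1-kb downstream flank, and the
  −500/+500 bp TSS window (class I elements > 1 kb and class II > 50 bp
  only); nearest-TE gap distances; distance-binned expression profiles;
  TE-insertion frequency tables; and HC-TE / PR-TE / non-TE transcript
  classification from homology bit score and coverage.
- **Window co-localization** — 100-kb genome windows, per-window
  normalized gene and DE-gene content, and a random-gene-set null:
  clustering shows up as the query set occupying fewer distinct windows
  than same-size random draws from the expressed universe.
- **Region permutation tests** — gene-identity resampling from a
  universe with mean nearest-TE-distance and mean flank-methylation
  evaluators, quartile-based fold-change bins of DE genes, and 100-bp
  flanking-window methylation metaplots per context (CG/CHG/CHH).
- **Subgenome / siRNA analysis** — frequencies of subgenome-1/2
  singletons and duplicates and non-syntenic genes with Fisher
  enrichment, homeolog-pair DE classification with the recessive-member
  fraction, and per-position 24-nt siRNA-locus occupancy over gene
  flanks.
- **Synthetic data** — a generator producing a full toy dataset
  (genome, genes, TEs, siRNA loci, methylation tracks, two-genotype
  FPKM, alignment footprints) with every injected effect recorded in a
  truth record, so each statistic has a parameter-recovery test.

## Worked example

```python
from rddmscan import (SimulationConfig, simulate_dataset,
                      transcribed_fraction, compare_transcribed_fraction,
                      filter_expressed, zero_fraction_test, ks_compare)

ds = simulate_dataset(SimulationConfig(seed=1))

reports = {g: transcribed_fraction(ds.alignments[g], ds.genome,
                                   min_reads=2, seed=5, genotype=g)
           for g in ("wt", "mut")}
print({g: round(r.fraction, 4) for g, r in reports.items()})

expr = filter_expressed(ds.expression)
print(zero_fraction_test(expr)["p"])
ks = ks_compare(expr.fpkm_wt[expr.fpkm_wt > 0],
                expr.fpkm_mut[expr.fpkm_mut > 0])
print(round(ks.d_obs, 4), round(ks.d_crit, 4), ks.significant)
```

prints

```
{'wt': 0.1032, 'mut': 0.1094}
0.061828322203294754
0.2538 0.107 True
```

The estimated transcribed fractions recover the configured genotype
targets (10.32% wild type, 10.94% mutant) exactly at this genome size.
The Fisher test sees the injected zero-inflation asymmetry (5 wild-type
zeros vs 0 mutant zeros among the 465 filtered genes) but at this toy
sample size the count is too small for significance (p ≈ 0.06) — at
genome scale the same asymmetry is overwhelming. The K-S conjunction
rule fires decisively: the default one-log₂-unit up-shift on
TSS-proximal-TE genes separates the two FPKM distributions (D-obs 0.254
above the critical distance 0.107 at α = 0.01).

A `rddmscan` console script exposes the same operations on files
(`rddmscan simulate | coverage | exprdist | tecontext | classify-te |
cluster | permtest | sirna`), reading BED/GFF3/TSV/bedGraph and writing
JSON or TSV.

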