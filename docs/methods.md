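# Methods

This note documents the models, conventions, numerical choices and
limitations behind `rddmscan`. Everything stated here is computed by the
package's tests or by `scripts/acceptance.py`; nothing is an external
empirical claim.

## Coordinates and distances

All internal coordinates are 0-based half-open (BED convention); GFF3's
1-based inclusive coordinates are converted at the read/write boundary.
Two intervals overlap iff they share at least one base — abutting
half-open intervals do not overlap. Distance between regions is the
edge-to-edge gap, `max(0, b.start − a.end, a.start − b.end)`, which is 0
for overlapping or abutting intervals; this matches distance-to-nearest
semantics in genomic-ranges toolkits, and midpoint distance was
deliberately rejected. Gene strand is mandatory; TEs and siRNA loci may
be unstranded. The TSS is the 5′-most transcribed base (start on `+`,
end − 1 on `−`), so "upstream" always means 5′ of the gene: for a `−`
strand gene the upstream flank lies at higher coordinates. Flank
windows extending past a chromosome edge are clipped, not discarded.
Gene-to-TE distances are measured from the annotated gene body, not
from the TSS.

## Transcribed fraction

The estimator down-samples the alignment set to a fixed target count
(uniform, without replacement, seeded), counts genome positions with
alignment depth ≥ `min_reads` (default 2) using a per-chromosome
difference array — contract-equivalent to per-base counting and tested
against it — and repeats this `n_replicates` times (default 3),
reporting per-replicate base counts, their floored-integer mean, and
the full-precision mean fraction. Down-sampling operates on alignment
records; when footprints represent multi-mapped reads the
reads-vs-alignments distinction is collapsed, because the inputs are
already footprint records. The genotype comparison reports the absolute
bp difference and the relative increase `100·(b−a)/a`, rounded to the
nearest integer percent for the headline field and kept at full
precision alongside.

## Expression distributions

The expressed-gene filter keeps rows with test status `OK` in at least
one analysis column; without status columns it falls back to keeping
rows with FPKM ≥ 1 in at least one genotype. Zeros never enter the
distributional statistics: they are diverted to a 2×2
(zero vs non-zero × genotype) Fisher exact test (scipy, two-sided
hypergeometric-summation convention, verified against full enumeration
in the tests). When both genotypes have zero zeros the odds ratio is
flagged undefined and p = 1.

The two-sample K-S statistic `D_obs = sup|ECDF₁ − ECDF₂|` is computed
on the raw positive FPKM values — it is invariant to the monotone log₂
display transform, asserted on random samples — with the asymptotic
Kolmogorov p-value and the critical distance
`D_crit = c(α)·√((n₁+n₂)/(n₁n₂))`, `c(0.01) = 1.62762`,
`c(0.05) = 1.35810`, `c(0.10) = 1.22385`. Significance is the
conjunction `D_obs > D_crit and p < α`. p-values are floored at 1e−15
with a flag; an exact zero is never reported. Samples smaller than 8
attach a warning but still return a result.

Histograms use unit-width log₂ bins centred on integers: bin *k* covers
`[k − 0.5, k + 0.5)`, so FPKM = 1 falls in bin 0 and FPKM = 4 in bin 2.
Frequencies are normalized over positive values only, with the zero
fraction held separately. The maximum cumulative-curve distance is
evaluated on the union bin grid and reported in percent. Whether the
original analysis ran the K-S on raw or binned values is not stated in
its description; raw values are used here and binning is treated as
presentation.

Rank comparisons (per TE superfamily) use Mann–Whitney U, two-sided:
exact enumeration when `n₁·n₂ ≤ 400` and no ties, otherwise the
tie-corrected normal approximation with continuity correction (average
ranks for ties).

## TE context

Only class I retroelements longer than 1 kb and class II DNA elements
longer than 50 bp are kept — the length thresholds are strict, taking
"longer than" literally — and labelled low-complexity/tandem-repeat
records are dropped. A gene's context flags are set by any overlap of a
kept TE with the strand-oriented 1-kb upstream flank, the gene body,
the 1-kb downstream flank, or the `[TSS − 500, TSS + 500)` window; one
TE can set several flags at once. Distance-binned expression profiles
put body-overlap genes in bin 0 and distances in `((k−1)·500, k·500]`
in bin *k* (upper-edge-closed, a choice the source leaves open).
Frequency-table percentages round half-up to two decimals, matching the
printed-table rendering. TE-transcript classification uses strict
thresholds: high-confidence = bit score > 500 and coverage > 50%;
putative/relic = not high-confidence and (bit score > 250 or
coverage > 30%); transcripts with no hit are non-TE. The best hit per
transcript is the highest bit score, ties broken by higher coverage
then lexicographic subject id.

## Window co-localization

The genome is tiled into non-overlapping 100-kb windows (last window
truncated). Each gene is assigned to exactly one window by its 5′-most
coordinate so spanning genes are never double-counted — a deliberate
deviation from a pure interval-overlap assignment. Per-window gene
content is normalized by the chromosome's gene total and DE content by
the window's gene count. The clustering statistic is the number of
distinct windows the query set occupies; the null draws same-size gene
sets without replacement from the expressed universe (no duplicate ids
within a draw, seeded). The empirical p is one-sided toward clustering
(fewer occupied windows) with an add-one correction, so
`p ≥ 1/(draws+1)`. A two-sided Wilcoxon rank-sum comparing observed
per-window query counts against the pooled null per-window counts is
exposed as a second output; the original description of this comparison
is ambiguous, so both statistics are reported and the rank-sum variant
is flagged as an interpretation.

## Permutation tests and methylation

Randomization resamples gene identities from the universe (not
coordinates), matching a resampleRegions-style scheme; the full gene
set is used as the universe without excluding the query. Evaluators:
mean nearest-TE gap distance (genes on TE-free chromosomes excluded,
with the exclusion count reported) and mean flank methylation as the
mean of per-gene flank means. With `alternative='auto'` (default) the
test direction follows the sign of the observed deviation from the null
mean — convenient for "above/below average" heatmap calls — but a
data-driven direction makes the one-sided add-one p anti-conservative
by roughly a factor of two under the null. The calibrated mode is an
explicitly pre-specified `'greater'`/`'less'`; the test suite verifies
uniform null p in that mode and documents the ~2× inflation of auto
mode. `z = (observed − null mean)/null sd`, reported as undefined for a
degenerate (constant) null.

DE genes are filtered at |log₂FC| > 1 and FDR < 0.05, then binned per
direction by fold-change-magnitude quartiles (linear interpolation):
bin 1 below Q1, bin 2 the interquartile range (boundary values
inclusive), bin 3 above Q3; down-regulated bins carry negative signs.
Fewer than four genes in a direction is an error.

Methylation tracks are per-position level tables in [0, 1] per context.
Flank metaplots divide the 2-kb (CG/CHG) or 1-kb (CHH) flanks into
100-bp strand-oriented windows — upstream windows indexed from the TSS,
downstream from the TTS — and pool covered positions across genes
(position-weighted). The permutation evaluator instead uses
mean-of-gene-means; the source specifies neither, so both conventions
are implemented and documented.

## Subgenome and siRNA occupancy

Frequencies use the dual-scale convention: singleton/duplicate
percentages over subgenome-assigned genes, non-syntenic percentages
over all genes in the set. Enrichment per category is a 2×2 Fisher
exact test against the reference set. In homeolog-pair DE
classification the "recessive member caused the differential
expression" fraction counts pairs where only the subgenome-2 member is
DE, divided by pairs with ≥ 1 DE member — the only reading consistent
with the printed 40/64 = 62.5% arithmetic — rounded half-up to one
decimal. siRNA association uses the strand-oriented
`[TSS − 1 kb, TSS + 1 kb)` window (half-open; TTS anchoring available
as an option); occupancy profiles are per-position covered fractions
(coverage semantics), not locus counts.

## The synthetic-data generator

The generator encodes the study conditions as defaults and records
every injected effect in a truth record:

| parameter | default | meaning |
| --- | --- | --- |
| `n_chrom` × `chrom_length` | 2 × 2 Mb | toy genome |
| `n_genes`, `gene_length` | 500, 2 kb | non-overlapping genes, one per jittered slot |
| `te_near_gene_prob` | 0.66 | share of TEs placed within 1 kb of a distinct gene's TSS (the observed two-thirds of genes with a TE within 1 kb) |
| `transcribed_frac_wt/mut` | 0.1032 / 0.1094 | target ≥ 2-read genome fractions (the genome-scale headline values) |
| `zero_rate_wt/mut` | 0.02 / 0.001 | per-genotype zero-FPKM injection (the ~20× asymmetry) |
| `baseline_log2fpkm_mean/sd` | 1.0 / 2.0 | log-normal expression baseline |
| `te_effect_log2` | 1.0 | mutant log₂ up-shift on genes with a TE in the TSS ± 500 window; a free parameter — the source quantifies the effect only through cumulative-curve distances |
| `cluster_effect_log2`, `n_clusters` × `cluster_size` | 2.0, 20 × 5 | runs of consecutive genes marked up-regulated, for co-localization recovery |
| `frac_sub1/sub2/nonsyntenic` | 0.31 / 0.18 / 0.51 | subgenome partition approximating the filtered-gene-set counts 12,190 / 7,175 / 20,291 of 39,656 |
| `sirna_sub2_bias` | 2.0 | relative weight of subgenome-2 genes as siRNA-locus hosts |
| `meth_cg_te/chg_te/chh_island` | 0.9 / 0.8 / 0.4 | methylation levels in TE bodies and mCHH islands over a 0.05 background |
| `island_offset` | (−600, −400) | mCHH island placement in the upstream flank |
| `footprint_length` | 50 bp | alignment footprint (single-end read length) |

Near-gene TEs target a random permutation of genes without replacement,
so the fraction of genes with a nearby TE tracks
`Binomial(n_tes, p)/n_genes` and is testable against a binomial CI.
Alignments realize the target ≥ 2-read fraction exactly: the genome is
divided into footprint-length slots, the required number of slots is
drawn without replacement, and two identical footprints are stacked per
slot. Per-genotype expression draws are independent normal log₂ samples
(so the no-effect case is a genuine null, not two copies of one draw);
effect genes receive a mean shift. One pooled FPKM value per gene per
genotype is generated — the pooled-conditions design — with per-sample
replicates left as a config extension. Methylation tracks subsample
positions on strides (background every 101 bp outside TE bodies, TE
bodies every 10 bp, islands every 5 bp); genomic background positions
falling inside TE bodies are excluded from the CG/CHG background so the
in-TE level is governed by the TE parameter alone. All randomness flows
through one seeded numpy Generator; a fixed seed reproduces every file
byte-for-byte.

What the generator does not emulate: read sequences or mapping
ambiguity (the multi-mapping ≤ 10-positions filter is upstream of this
package's inputs), stress conditions or replicate structure, realistic
TE family composition, linkage between methylation and expression
beyond the injected effects, or genome-scale sample sizes. Passing
recovery tests therefore demonstrate estimator correctness and
sensitivity under the configured effect sizes at desk scale, not
biological validity at genome scale.

## Problem sizes and numerical choices

Calibration and recovery run at sizes chosen to make Monte-Carlo error
small relative to the tested tolerances: 500 null replicates at
n = 200/200 for the K-S false-positive rate, 300 permutation null runs
at n_perm = 99, 100 seeds at 5,000 genes (30% affected) for K-S
detection, 40 seeds for cluster detection, 100 null draws per
co-localization test, permutation n = 200 by default. Binomial 99%
confidence intervals bound all rate assertions. Percent roundings are
half-up (two decimals for frequency tables, one for the recessive
fraction, nearest integer for the coverage headline). The K-S p floor
is 1e−15; add-one corrections bound permutation and empirical p away
from zero.

## Known limitations

- The interval engine is a per-chromosome sort-and-sweep adequate for
  annotation-scale inputs, not a BAM-scale query structure; no tabix or
  BAM support in the core (alignments enter as BED footprints).
- The original analysis reports both 66,153 and 66,163 filtered
  transcripts in different places; the discrepancy is noted and not
  resolved — this package's filter is deterministic on its inputs.
- Whether flank windows at chromosome edges were clipped or dropped in
  the original pipeline is unknown; clipping is used here.
- Gene coordinates for distances are the annotated gene body; the
  primary-transcript alternative is not implemented.
- The auto-direction permutation p is intentionally regioneR-like and
  is not a calibrated one-sided test (see above).
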