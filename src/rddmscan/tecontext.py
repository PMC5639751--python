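"""Gene classification by transposable-element context.

Strand-aware flags for TEs in the 1-kb upstream flank, the gene body,
the 1-kb downstream flank, and the TSS-spanning -500/+500 bp window;
nearest-TE gap distances; distance-binned expression profiles;
TE-insertion frequency tables per gene category; and the classification
of transcripts as TE-related from homology-hit bit score and coverage.

"Upstream" always means 5' of the gene: for a '-' strand gene the
upstream flank lies to the right of its rightmost base.  Flank windows
are clipped at chromosome edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .intervals import GeneModel, TEAnnotation, gap_distance

__all__ = ["TEContextFlags", "TETranscriptClass", "filter_te_annotation",
           "classify_gene_te_context", "nearest_te_distance",
           "distance_expression_profile", "te_frequency_table",
           "classify_te_transcript", "percent_half_up"]

# annotation length filter: retroelements must exceed 1 kb, DNA TEs 50 bp
MIN_CLASS_I_LENGTH = 1_000
MIN_CLASS_II_LENGTH = 50


@dataclass(frozen=True)
class TEContextFlags:
    gene_id: str
    upstream_1kb: bool
    body: bool
    downstream_1kb: bool
    tss_500: bool
    nearest_te_distance: int | None  # None when no TE on the chromosome
    nearest_te_superfamily: str | None


@dataclass(frozen=True)
class TETranscriptClass:
    """TE-relatedness of a transcript from its best homology hit.

    High-confidence TE: bit score > 500 and query coverage > 50%.
    Putative/relic TE: not high-confidence, but bit score > 250 or
    coverage > 30%.  Everything else (including no hit) is non-TE.
    """

    transcript_id: str
    bit_score: float
    coverage: float
    klass: str  # HC_TE | PR_TE | NON_TE


def filter_te_annotation(
    tes: list[TEAnnotation], drop_families: frozenset[str] = frozenset({"dust", "trf"})
) -> list[TEAnnotation]:
    """Apply the length filter: class I > 1 kb, class II > 50 bp (strict).

    Records labelled as low-complexity/tandem-repeat families are
    dropped first.
    """
    kept = []
    for te in tes:
        if te.family in drop_families:
            continue
        if te.te_class == "I" and len(te) > MIN_CLASS_I_LENGTH:
            kept.append(te)
        elif te.te_class == "II" and len(te) > MIN_CLASS_II_LENGTH:
            kept.append(te)
    return kept


def _flank_windows(
    gene: GeneModel, chrom_len: int | None, flank: int = 1_000
) -> dict[str, tuple[int, int]]:
    """Strand-oriented (start, end) half-open windows around a gene."""
    iv = gene.interval
    hi_cap = chrom_len if chrom_len is not None else float("inf")
    if gene.strand == "+":
        upstream = (iv.start - flank, iv.start)
        downstream = (iv.end, iv.end + flank)
        tss500 = (gene.tss - 500, gene.tss + 500)
    else:
        upstream = (iv.end, iv.end + flank)
        downstream = (iv.start - flank, iv.start)
        tss500 = (gene.tss + 1 - 500, gene.tss + 1 + 500)
    out = {}
    for name, (lo, hi) in (
        ("upstream_1kb", upstream),
        ("downstream_1kb", downstream),
        ("tss_500", tss500),
    ):
        lo = max(0, lo)
        hi = int(min(hi_cap, hi))
        out[name] = (lo, hi)
    return out


def classify_gene_te_context(
    genes: list[GeneModel],
    tes_filtered: list[TEAnnotation],
    genome: dict[str, int] | None = None,
) -> list[TEContextFlags]:
    """Per-gene TE-context flags plus nearest-TE gap distance.

    A flag is set iff a TE interval overlaps the corresponding window;
    the same TE can set two or three flags at once.  Nearest distance is
    measured edge-to-edge from the gene body (0 for a body overlap) and
    is None when the chromosome carries no TE.
    """
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for te in tes_filtered:
        by_chrom.setdefault(te.interval.chrom, []).append(te)

    flags = []
    for gene in genes:
        chrom_len = genome.get(gene.interval.chrom) if genome else None
        windows = _flank_windows(gene, chrom_len)
        tes_here = by_chrom.get(gene.interval.chrom, [])
        up = body = down = tss = False
        best_d: int | None = None
        best_sf: str | None = None
        for te in tes_here:
            ts, te_end = te.interval.start, te.interval.end
            if ts < gene.interval.end and gene.interval.start < te_end:
                body = True
            lo, hi = windows["upstream_1kb"]
            if ts < hi and lo < te_end:
                up = True
            lo, hi = windows["downstream_1kb"]
            if ts < hi and lo < te_end:
                down = True
            lo, hi = windows["tss_500"]
            if ts < hi and lo < te_end:
                tss = True
            d = gap_distance(gene.interval, te.interval)
            if best_d is None or d < best_d:
                best_d, best_sf = d, te.superfamily
        flags.append(
            TEContextFlags(
                gene_id=gene.gene_id,
                upstream_1kb=up,
                body=body,
                downstream_1kb=down,
                tss_500=tss,
                nearest_te_distance=best_d,
                nearest_te_superfamily=best_sf,
            )
        )
    return flags


def nearest_te_distance(
    genes: list[GeneModel], tes_filtered: list[TEAnnotation]
) -> dict[str, int | None]:
    """Minimum edge-to-edge gene-body-to-TE gap per gene (None if no TE)."""
    flags = classify_gene_te_context(genes, tes_filtered)
    return {f.gene_id: f.nearest_te_distance for f in flags}


def distance_expression_profile(
    genes: list[GeneModel],
    distances: dict[str, int | None],
    expression: pd.DataFrame,
    bin_width: int = 500,
    fpkm_cols: tuple[str, str] = ("fpkm_wt", "fpkm_mut"),
) -> pd.DataFrame:
    """Mean FPKM +/- SE per genotype, binned by nearest-TE distance.

    Bin 0 holds body-overlap genes (distance 0); bin k holds distances
    in ``((k-1)*bin_width, k*bin_width]``.  Empty bins appear with count
    0 and NaN means.
    """
    expr = expression.set_index("gene_id")
    rows = []
    binned: dict[int, list[str]] = {}
    for gene in genes:
        d = distances.get(gene.gene_id)
        if d is None or gene.gene_id not in expr.index:
            continue
        b = 0 if d == 0 else int(np.ceil(d / bin_width))
        binned.setdefault(b, []).append(gene.gene_id)
    max_bin = max(binned) if binned else -1
    for b in range(0, max_bin + 1):
        ids = binned.get(b, [])
        row: dict = {"bin": b, "n_genes": len(ids)}
        for col in fpkm_cols:
            if ids:
                vals = expr.loc[ids, col].to_numpy(dtype=float)
                row[f"mean_{col}"] = float(np.mean(vals))
                row[f"se_{col}"] = (
                    float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else 0.0
                )
            else:
                row[f"mean_{col}"] = np.nan
                row[f"se_{col}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def percent_half_up(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage rounded half-up to ``decimals`` (table-rendering rule)."""
    if denominator == 0:
        return float("nan")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(10) ** -decimals
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def te_frequency_table(
    categories: dict[str, list[str]],
    flags: list[TEContextFlags],
) -> pd.DataFrame:
    """TE-insertion frequency per gene category.

    For each named category: gene count, number and percentage with an
    upstream-1kb TE, and number and percentage with a TSS-spanning TE
    (percentages half-up to two decimals).
    """
    by_id = {f.gene_id: f for f in flags}
    rows = []
    for name, gene_ids in categories.items():
        n = len(gene_ids)
        n_up = sum(1 for g in gene_ids if g in by_id and by_id[g].upstream_1kb)
        n_tss = sum(1 for g in gene_ids if g in by_id and by_id[g].tss_500)
        rows.append(
            {
                "category": name,
                "n_genes": n,
                "n_upstream_1kb": n_up,
                "pct_upstream_1kb": percent_half_up(n_up, n),
                "n_tss_500": n_tss,
                "pct_tss_500": percent_half_up(n_tss, n),
            }
        )
    return pd.DataFrame(rows)


def classify_te_transcript(hits: pd.DataFrame) -> list[TETranscriptClass]:
    """Classify transcripts as HC/PR/non-TE from best-hit statistics.

    ``hits`` has columns transcript_id, bit_score, coverage (fraction of
    the transcript aligned, in [0, 1]); at most one best hit per
    transcript.  Thresholds are strict inequalities.
    """
    out = []
    seen = set()
    for row in hits.itertuples(index=False):
        if row.transcript_id in seen:
            raise ValueError(f"multiple hits for transcript {row.transcript_id}")
        seen.add(row.transcript_id)
        cov = float(row.coverage)
        if not (0.0 <= cov <= 1.0):
            raise ValueError(
                f"coverage outside [0, 1] for {row.transcript_id}: {cov}"
            )
        bit = float(row.bit_score)
        if bit > 500 and cov > 0.5:
            klass = "HC_TE"
        elif bit > 250 or cov > 0.3:
            klass = "PR_TE"
        else:
            klass = "NON_TE"
        out.append(
            TETranscriptClass(
                transcript_id=row.transcript_id,
                bit_score=bit,
                coverage=cov,
                klass=klass,
            )
        )
    return out


def best_hits(raw_hits: pd.DataFrame) -> pd.DataFrame:
    """Reduce a multi-hit table to one best hit per transcript.

    Best = highest bit score; ties broken by higher coverage, then by
    lexicographically smallest subject id.
    """
    cols = ["transcript_id", "bit_score", "coverage"]
    sort_cols = ["transcript_id", "bit_score", "coverage"]
    ascending = [True, False, False]
    if "subject_id" in raw_hits.columns:
        sort_cols.append("subject_id")
        ascending.append(True)
    ranked = raw_hits.sort_values(sort_cols, ascending=ascending, kind="mergesort")
    return ranked.drop_duplicates("transcript_id", keep="first").reset_index(drop=True)
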