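"""Subgenome partition, homeolog-pair DE classification, siRNA occupancy.

Maize genes partition into the dominant subgenome 1, the recessive
subgenome 2 (each with retained duplicates and singletons), and
non-syntenic genes.  This module reports category frequencies of gene
sets with Fisher enrichment against a reference set, classifies
homeolog pairs by which member is differentially expressed, and
computes per-position 24-nt siRNA-locus occupancy profiles over gene
flanks (coverageBed-style fractions, not locus counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, SiRNALocus

__all__ = ["HomeologPairRecord", "OccupancyProfile",
           "subgenome_frequency_report", "homeolog_pair_de",
           "sirna_flank_occupancy", "sirna_association_flags"]


@dataclass(frozen=True)
class HomeologPairRecord:
    pair_id: str
    gene_sub1: str
    gene_sub2: str
    de_status: str  # h1_only | h2_only | both | neither
    direction: str  # up | down | mixed | none


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-position fraction of genes with >=1 siRNA locus at that offset.

    ``positions`` are strand-oriented offsets: -flank..-1 upstream of
    the TSS, +1..+flank downstream of the TTS.
    """

    positions: tuple[int, ...]
    fraction_covered: tuple[float, ...]
    n_genes: int


_CATEGORIES = (
    "sub1_singleton",
    "sub1_duplicate",
    "sub2_singleton",
    "sub2_duplicate",
    "nonsyntenic",
)


def _categorize(gene: GeneModel) -> str | None:
    if gene.subgenome == "sub1":
        return "sub1_duplicate" if gene.homeolog_partner else "sub1_singleton"
    if gene.subgenome == "sub2":
        return "sub2_duplicate" if gene.homeolog_partner else "sub2_singleton"
    if gene.subgenome == "nonsyntenic":
        return "nonsyntenic"
    return None


def subgenome_frequency_report(
    gene_sets: dict[str, list[GeneModel]],
    reference: str,
) -> pd.DataFrame:
    """Category frequencies per gene set with Fisher enrichment vs reference.

    Syntenic percentages (singletons/duplicates of each subgenome) are
    computed over subgenome-assigned genes only; the non-syntenic
    percentage is computed over all genes in the set (the dual-scale
    convention).  Per category, a 2x2 Fisher exact test compares the
    set's composition with the reference set's.
    """
    if reference not in gene_sets:
        raise ValueError(f"reference set {reference!r} not among gene sets")
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    assigned: dict[str, int] = {}
    for name, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        cat_counts = {c: 0 for c in _CATEGORIES}
        n_assigned = 0
        for gene in genes:
            cat = _categorize(gene)
            if cat is None:
                continue
            cat_counts[cat] += 1
            if cat != "nonsyntenic":
                n_assigned += 1
        counts[name] = cat_counts
        totals[name] = len(genes)
        assigned[name] = n_assigned

    rows = []
    for name in gene_sets:
        for cat in _CATEGORIES:
            n = counts[name][cat]
            denom = totals[name] if cat == "nonsyntenic" else assigned[name]
            pct = 100.0 * n / denom if denom else float("nan")
            if name == reference:
                fisher_p = 1.0
            else:
                ref_n = counts[reference][cat]
                ref_denom = (
                    totals[reference] if cat == "nonsyntenic" else assigned[reference]
                )
                table = [[n, denom - n], [ref_n, ref_denom - ref_n]]
                fisher_p = float(stats.fisher_exact(table)[1])
            rows.append(
                {
                    "set": name,
                    "category": cat,
                    "n": n,
                    "denominator": denom,
                    "pct": pct,
                    "fisher_p_vs_reference": fisher_p,
                }
            )
    return pd.DataFrame(rows)


def homeolog_pair_de(
    pairs: list[tuple[str, str, str]],
    de_genes: set[str],
) -> dict:
    """Classify retained homeolog pairs by which member is DE.

    ``pairs`` holds (pair_id, sub1_gene, sub2_gene); ``de_genes`` is the
    DE gene set for one direction.  Counts pairs with at least one DE
    member and reports the recessive fraction: the percentage of DE
    pairs where only the subgenome-2 (recessive) member is DE, rounded
    half-up to one decimal.
    """
    seen: set[str] = set()
    for _pid, g1, g2 in pairs:
        for g in (g1, g2):
            if g in seen:
                raise ValueError(f"gene {g} appears in two pairs")
            seen.add(g)
    h1_only = h2_only = both = 0
    for _pid, g1, g2 in pairs:
        de1, de2 = g1 in de_genes, g2 in de_genes
        if de1 and de2:
            both += 1
        elif de1:
            h1_only += 1
        elif de2:
            h2_only += 1
    n_pairs_de = h1_only + h2_only + both
    if n_pairs_de == 0:
        raise ValueError("no pair has a differentially expressed member")
    frac = Decimal(h2_only) * 100 / Decimal(n_pairs_de)
    recessive = float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return {
        "n_pairs_de": n_pairs_de,
        "h1_only": h1_only,
        "h2_only": h2_only,
        "both": both,
        "recessive_fraction_pct": recessive,
    }


def _flank_offsets(gene: GeneModel, flank: int) -> dict[int, tuple[str, int]]:
    """Map strand-oriented offset -> (chrom, absolute position)."""
    iv = gene.interval
    out = {}
    chrom = iv.chrom
    for off in range(1, flank + 1):
        if gene.strand == "+":
            up_pos = iv.start - off  # upstream of TSS
            down_pos = iv.end - 1 + off  # downstream of TTS
        else:
            up_pos = iv.end - 1 + off
            down_pos = iv.start - off
        out[-off] = (chrom, up_pos)
        out[off] = (chrom, down_pos)
    return out


class _LocusIndex:
    """Merged sorted locus spans per chromosome for membership queries."""

    def __init__(self, loci: list[SiRNALocus]):
        spans: dict[str, list[tuple[int, int]]] = {}
        for locus in loci:
            spans.setdefault(locus.interval.chrom, []).append(
                (locus.interval.start, locus.interval.end)
            )
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, items in spans.items():
            items.sort()
            merged: list[tuple[int, int]] = []
            for s, e in items:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._merged[chrom] = (
                np.array([s for s, _ in merged]),
                np.array([e for _, e in merged]),
            )

    def covered(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: is each position inside any locus."""
        if chrom not in self._merged:
            return np.zeros(pos.size, dtype=bool)
        starts, ends = self._merged[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        result = np.zeros(pos.size, dtype=bool)
        result[ok] = pos[ok] < ends[idx[ok]]
        return result

    def any_overlap(self, chrom: str, lo: int, hi: int) -> bool:
        """Does any locus overlap the half-open span [lo, hi)?"""
        if hi <= lo or chrom not in self._merged:
            return False
        starts, ends = self._merged[chrom]
        idx = int(np.searchsorted(starts, hi, side="left")) - 1
        return idx >= 0 and ends[idx] > lo


def sirna_flank_occupancy(
    genes: list[GeneModel],
    sirna_loci: list[SiRNALocus],
    flank: int = 1_000,
) -> OccupancyProfile:
    """Per-offset siRNA coverage fraction over strand-oriented gene flanks.

    For each offset in [-flank, -1] (upstream of the TSS) and
    [+1, +flank] (downstream of the TTS), the fraction of genes whose
    flank base at that offset falls inside at least one siRNA locus.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not genes:
        raise ValueError("empty gene group")
    index = _LocusIndex(sirna_loci)
    offsets = np.concatenate([np.arange(-flank, 0), np.arange(1, flank + 1)])
    covered_counts = np.zeros(offsets.size)
    for gene in genes:
        iv = gene.interval
        off_up = np.arange(-flank, 0)  # -flank .. -1
        off_down = np.arange(1, flank + 1)
        if gene.strand == "+":
            pos_up = iv.start + off_up  # start - flank .. start - 1
            pos_down = iv.end - 1 + off_down
        else:
            pos_up = iv.end - 1 - off_up  # end .. end + flank - 1
            pos_down = iv.start - off_down
        pos = np.concatenate([pos_up, pos_down])
        valid = pos >= 0
        mask = np.zeros(pos.size, dtype=bool)
        mask[valid] = index.covered(iv.chrom, pos[valid])
        covered_counts += mask
    fractions = covered_counts / len(genes)
    return OccupancyProfile(
        positions=tuple(int(o) for o in offsets),
        fraction_covered=tuple(float(f) for f in fractions),
        n_genes=len(genes),
    )


def sirna_association_flags(
    genes: list[GeneModel],
    sirna_loci: list[SiRNALocus],
    within: int = 1_000,
    down_regulated_loci: list[SiRNALocus] | None = None,
    anchor: str = "tss",
) -> pd.DataFrame:
    """Flag genes with >=1 siRNA locus overlapping the TSS+/-within window.

    The window is ``[TSS - within, TSS + within)`` strand-oriented
    (half-open: a locus abutting the window end does not count).  A
    second flag marks overlap with a designated down-regulated locus
    subset when given.  ``anchor='tts'`` switches to TTS windows.
    """
    if within <= 0:
        raise ValueError("within must be positive")
    index = _LocusIndex(sirna_loci)
    down_index = _LocusIndex(down_regulated_loci) if down_regulated_loci else None
    rows = []
    for gene in genes:
        site = gene.tss if anchor == "tss" else gene.tts
        if gene.strand == "+":
            lo, hi = site - within, site + within
        else:
            lo, hi = site + 1 - within, site + 1 + within
        lo = max(0, lo)
        flag = index.any_overlap(gene.interval.chrom, lo, hi)
        down_flag = (
            down_index.any_overlap(gene.interval.chrom, lo, hi)
            if down_index is not None
            else False
        )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "sirna_associated": bool(flag),
                "down_locus_associated": bool(down_flag),
            }
        )
    return pd.DataFrame(rows)
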