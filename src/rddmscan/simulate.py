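"""Synthetic genome/annotation/expression/methylation generator.

Produces a complete toy dataset — chromosomes, non-overlapping genes with
subgenome labels and homeolog pairs, TE annotations biased toward gene
flanks, 24-nt siRNA loci enriched upstream of recessive-subgenome genes,
per-context methylation tracks with mCHH islands, two-genotype FPKM
tables with genotype-dependent zero inflation and a TSS-proximal-TE
up-regulation effect, and alignment footprints realising a configured
transcribed fraction per genotype.  Every injected effect is recorded in
a truth record so downstream statistics have parameter-recovery tests.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config, so a fixed seed reproduces the dataset exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    CLASS_I_SUPERFAMILIES,
    CLASS_II_SUPERFAMILIES,
    GeneModel,
    GenomicInterval,
    SiRNALocus,
    TEAnnotation,
    write_bed,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_annotation",
           "simulate_expression", "simulate_methylation",
           "simulate_alignments", "simulate_dataset", "write_dataset"]

_CLASS_I = sorted(CLASS_I_SUPERFAMILIES)
_CLASS_II = sorted(CLASS_II_SUPERFAMILIES)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults encode the study conditions.

    The transcribed fractions default to the multi-mapped genome-coverage
    fractions of the wild type (10.32%) and the Pol IV mutant (10.94%);
    ``te_near_gene_prob`` defaults to the 66% of genes that lie within
    1 kb of an annotated transposon; the zero-expression rates encode the
    ~20x asymmetry in never-expressed genes between genotypes; subgenome
    fractions approximate the filtered-gene-set partition (sub1 31%,
    sub2 18%, non-syntenic 51%).
    """

    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 500
    gene_length: int = 2_000
    n_tes: int = 500
    n_sirna: int = 300
    te_near_gene_prob: float = 0.66
    frac_sub1: float = 0.31
    frac_sub2: float = 0.18
    frac_nonsyntenic: float = 0.51
    homeolog_pair_frac: float = 0.5
    zero_rate_wt: float = 0.02
    zero_rate_mut: float = 0.001
    baseline_log2fpkm_mean: float = 1.0
    baseline_log2fpkm_sd: float = 2.0
    te_effect_log2: float = 1.0
    cluster_effect_log2: float = 2.0
    n_clusters: int = 20
    cluster_size: int = 5
    sirna_sub2_bias: float = 2.0
    meth_cg_te: float = 0.9
    meth_chg_te: float = 0.8
    meth_chh_island: float = 0.4
    meth_background: float = 0.05
    chh_island_frac: float = 0.5
    island_offset: tuple[int, int] = (-600, -400)
    footprint_length: int = 50
    transcribed_frac_wt: float = 0.1032
    transcribed_frac_mut: float = 0.1094
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "te_near_gene_prob": self.te_near_gene_prob,
            "frac_sub1": self.frac_sub1,
            "frac_sub2": self.frac_sub2,
            "frac_nonsyntenic": self.frac_nonsyntenic,
            "homeolog_pair_frac": self.homeolog_pair_frac,
            "zero_rate_wt": self.zero_rate_wt,
            "zero_rate_mut": self.zero_rate_mut,
            "meth_cg_te": self.meth_cg_te,
            "meth_chg_te": self.meth_chg_te,
            "meth_chh_island": self.meth_chh_island,
            "meth_background": self.meth_background,
            "chh_island_frac": self.chh_island_frac,
            "transcribed_frac_wt": self.transcribed_frac_wt,
            "transcribed_frac_mut": self.transcribed_frac_mut,
        }
        for name, value in probs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.frac_sub1 + self.frac_sub2 + self.frac_nonsyntenic > 1.0 + 1e-9:
            raise ValueError("subgenome fractions must sum to <= 1")
        for name in ("n_chrom", "chrom_length", "n_genes", "gene_length",
                     "footprint_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sirna_sub2_bias <= 0:
            raise ValueError("sirna_sub2_bias must be positive")

    @property
    def genome(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}


@dataclass
class SyntheticDataset:
    """The generated toy dataset plus the record of injected effects."""

    config: SimulationConfig
    genome: dict[str, int]
    genes: list[GeneModel]
    tes: list[TEAnnotation]
    sirna: list[SiRNALocus]
    methylation: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    alignments: dict[str, list[GenomicInterval]]
    truth: dict


def _tss_window(gene: GeneModel, up: int, down: int, chrom_len: int) -> GenomicInterval:
    """Strand-oriented window [TSS - up, TSS + down), clipped to the chromosome."""
    if gene.strand == "+":
        lo, hi = gene.tss - up, gene.tss + down
    else:
        lo, hi = gene.tss + 1 - down, gene.tss + 1 + up
    lo, hi = max(0, lo), min(chrom_len, hi)
    return GenomicInterval(gene.interval.chrom, lo, max(hi, lo + 1), gene.strand)


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], list[TEAnnotation], list[SiRNALocus], dict]:
    """Place genes, TEs, and siRNA loci; return them with a truth record.

    Genes are non-overlapping (one per regularly spaced slot with random
    jitter).  A fraction ``te_near_gene_prob`` of TEs is placed within
    1 kb of the TSS of a distinct random gene; the rest land uniformly.
    siRNA loci sit in 1-kb upstream gene flanks, with recessive
    subgenome-2 genes drawn ``sirna_sub2_bias`` times more often.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = list(config.genome)
    # distribute genes across chromosomes as evenly as possible
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    pad = 1_200  # room for 1-kb flank + jitter without slot collisions
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_on_chrom in zip(chroms, per_chrom):
        if n_on_chrom == 0:
            continue
        slot = config.chrom_length // n_on_chrom
        if slot < config.gene_length + 2 * pad:
            raise ValueError(
                "genome too small to place requested genes without overlap: "
                f"slot {slot} bp < gene {config.gene_length} bp + padding"
            )
        for k in range(n_on_chrom):
            lo = k * slot + pad
            hi = (k + 1) * slot - pad - config.gene_length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:05d}",
                    interval=GenomicInterval(
                        chrom, start, start + config.gene_length, strand
                    ),
                )
            )
            gid += 1

    # subgenome labels and homeolog pairing
    n = len(genes)
    n_sub1 = int(round(config.frac_sub1 * n))
    n_sub2 = int(round(config.frac_sub2 * n))
    n_nonsyn = int(round(config.frac_nonsyntenic * n))
    labels = (
        ["sub1"] * n_sub1 + ["sub2"] * n_sub2 + ["nonsyntenic"] * n_nonsyn
    )
    labels += ["unassigned"] * (n - len(labels))
    labels = list(rng.permutation(np.array(labels[:n])))
    sub1_ids = [g.gene_id for g, lab in zip(genes, labels) if lab == "sub1"]
    sub2_ids = [g.gene_id for g, lab in zip(genes, labels) if lab == "sub2"]
    n_pairs = int(round(config.homeolog_pair_frac * min(len(sub1_ids), len(sub2_ids))))
    partners: dict[str, str] = {}
    for a, b in zip(
        rng.permutation(np.array(sub1_ids))[:n_pairs],
        rng.permutation(np.array(sub2_ids))[:n_pairs],
    ):
        partners[a] = b
        partners[b] = a
    genes = [
        GeneModel(
            gene_id=g.gene_id,
            interval=g.interval,
            biotype=g.biotype,
            source=g.source,
            subgenome=lab,
            homeolog_partner=partners.get(g.gene_id),
        )
        for g, lab in zip(genes, labels)
    ]

    # clustered (co-localised) up-regulated genes: runs of consecutive genes
    cluster_genes: list[list[str]] = []
    if config.n_clusters > 0 and config.cluster_size > 1:
        n_needed = config.n_clusters * config.cluster_size
        if n_needed > n:
            raise ValueError("not enough genes for the requested clusters")
        max_start = n - config.cluster_size
        starts: list[int] = []
        candidates = rng.permutation(max_start + 1)
        for s in candidates:
            if all(abs(s - t) >= config.cluster_size for t in starts):
                starts.append(int(s))
            if len(starts) == config.n_clusters:
                break
        if len(starts) < config.n_clusters:
            raise ValueError("could not place non-overlapping gene clusters")
        for s in starts:
            cluster_genes.append(
                [genes[i].gene_id for i in range(s, s + config.cluster_size)]
            )

    # TEs: near-gene placements target a permutation of genes (no gene twice
    # until all genes used), so the fraction of genes with a nearby TE tracks
    # Binomial(n_tes, p) / n_genes
    near_flags = rng.random(config.n_tes) < config.te_near_gene_prob
    target_order = rng.permutation(n)
    tes: list[TEAnnotation] = []
    next_target = 0
    for i in range(config.n_tes):
        if rng.random() < 0.5:
            superfamily = _CLASS_I[int(rng.integers(len(_CLASS_I)))]
            te_len = int(rng.integers(1_100, 3_001))
        else:
            superfamily = _CLASS_II[int(rng.integers(len(_CLASS_II)))]
            te_len = int(rng.integers(60, 401))
        if near_flags[i]:
            gene = genes[int(target_order[next_target % n])]
            next_target += 1
            tss = gene.tss
            lo = max(0, tss - 1_000)
            hi = min(config.chrom_length - te_len, tss + 1_000)
            start = int(rng.integers(lo, max(hi, lo) + 1))
            chrom = gene.interval.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - te_len))
        tes.append(
            TEAnnotation(
                interval=GenomicInterval(chrom, start, start + te_len),
                superfamily=superfamily,
                family=f"{superfamily}_fam{i % 20}",
            )
        )

    # siRNA loci in 1-kb upstream flanks, biased toward subgenome 2
    weights = np.array(
        [config.sirna_sub2_bias if g.subgenome == "sub2" else 1.0 for g in genes]
    )
    weights = weights / weights.sum()
    sirna: list[SiRNALocus] = []
    host_idx = rng.choice(n, size=config.n_sirna, p=weights)
    for k, gi in enumerate(host_idx):
        gene = genes[int(gi)]
        length = int(rng.integers(100, 301))
        win = _tss_window(gene, 1_000, 0, config.chrom_length)
        span = len(win) - length
        if span <= 0:
            start = win.start
        else:
            start = win.start + int(rng.integers(0, span + 1))
        sirna.append(
            SiRNALocus(
                interval=GenomicInterval(gene.interval.chrom, start, start + length),
                locus_id=f"sirna{k:05d}",
            )
        )

    # truth: which genes actually got a TE in the TSS+/-500 window / 1-kb flank
    te_tss500, te_1kb = set(), set()
    tes_by_chrom: dict[str, list[TEAnnotation]] = {}
    for te in tes:
        tes_by_chrom.setdefault(te.interval.chrom, []).append(te)
    for gene in genes:
        win500 = _tss_window(gene, 500, 500, config.chrom_length)
        win1kb = _tss_window(gene, 1_000, 0, config.chrom_length)
        for te in tes_by_chrom.get(gene.interval.chrom, []):
            if te.interval.overlaps(win500):
                te_tss500.add(gene.gene_id)
            if te.interval.overlaps(win1kb) or te.interval.overlaps(gene.interval):
                te_1kb.add(gene.gene_id)

    island_pool = [g.gene_id for g in genes]
    n_islands = int(round(config.chh_island_frac * n))
    chh_island_genes = sorted(
        str(x) for x in rng.permutation(np.array(island_pool))[:n_islands]
    )

    truth = {
        "te_tss500_genes": sorted(te_tss500),
        "te_within_1kb_genes": sorted(te_1kb),
        "cluster_genes": cluster_genes,
        "chh_island_genes": chh_island_genes,
        "sirna_host_counts": {
            g.gene_id: int(c)
            for g, c in zip(genes, np.bincount(host_idx, minlength=n))
            if c > 0
        },
    }
    return genes, tes, sirna, truth


def simulate_expression(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: dict,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two-genotype FPKM table with the injected TSS-proximal-TE effect.

    Per-gene log2 FPKM is drawn independently per genotype from a normal
    baseline; the mutant mean is shifted by ``te_effect_log2`` for genes
    with a TE in the TSS+/-500 window and by ``cluster_effect_log2`` for
    cluster members.  Zeros are injected at per-genotype rates.  The DE
    columns (log2fc = generated difference of the positive draws, fdr
    small iff an effect was injected) let downstream filters run without
    re-deriving differential expression.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(genes)
    flagged = np.array([g.gene_id in set(truth["te_tss500_genes"]) for g in genes])
    clustered_ids = {gid for cluster in truth["cluster_genes"] for gid in cluster}
    clustered = np.array([g.gene_id in clustered_ids for g in genes])

    wt_log2 = rng.normal(config.baseline_log2fpkm_mean, config.baseline_log2fpkm_sd, n)
    mut_shift = (
        config.te_effect_log2 * flagged + config.cluster_effect_log2 * clustered
    )
    mut_log2 = rng.normal(
        config.baseline_log2fpkm_mean + mut_shift, config.baseline_log2fpkm_sd, n
    )
    fpkm_wt = np.power(2.0, wt_log2)
    fpkm_mut = np.power(2.0, mut_log2)
    zero_wt = rng.random(n) < config.zero_rate_wt
    zero_mut = rng.random(n) < config.zero_rate_mut
    log2fc = mut_log2 - wt_log2
    fpkm_wt[zero_wt] = 0.0
    fpkm_mut[zero_mut] = 0.0

    effect = flagged | clustered
    fdr = np.where(effect, 10.0 ** rng.uniform(-6, -2, n), rng.uniform(0.05, 1.0, n))

    def status(fpkm: np.ndarray) -> np.ndarray:
        return np.where(fpkm >= 1.0, "OK", "LOWDATA")

    table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "fpkm_wt": fpkm_wt,
            "fpkm_mut": fpkm_mut,
            "status_wt": status(fpkm_wt),
            "status_mut": status(fpkm_mut),
            "log2fc": log2fc,
            "fdr": fdr,
            "biotype": [g.biotype for g in genes],
        }
    )
    truth["te_effect_genes"] = sorted(
        g.gene_id for g, f in zip(genes, flagged) if f
    )
    return table


def simulate_methylation(
    config: SimulationConfig,
    genes: list[GeneModel],
    tes: list[TEAnnotation],
    truth: dict,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-context cytosine-level tracks.

    CG and CHG run high inside TE bodies (means ``meth_cg_te`` /
    ``meth_chg_te``) over a low genomic background; CHH is background
    everywhere except sharp islands of level ``meth_chh_island`` at a
    fixed offset window inside the upstream flank of the truth-flagged
    island genes.  Positions are subsampled on strides — level tables,
    not per-cytosine calls.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genome = config.genome
    island_set = set(truth.get("chh_island_genes", []))
    tracks: dict[str, pd.DataFrame] = {}

    # merged TE spans per chromosome, to keep TE-body positions out of
    # the genomic background (TE bodies get their own high-level records)
    te_spans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(
            (te.interval.start, te.interval.end)
        )
    for chrom, items in by_chrom.items():
        items.sort()
        merged: list[tuple[int, int]] = []
        for s, e in items:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        te_spans[chrom] = (
            np.array([s for s, _ in merged]),
            np.array([e for _, e in merged]),
        )

    def _outside_tes(chrom: str, pos: np.ndarray) -> np.ndarray:
        if chrom not in te_spans:
            return pos
        starts, ends = te_spans[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        return pos[~inside]

    def background(exclude_te_bodies: bool) -> tuple[list[str], list[int], list[float]]:
        chroms_, poss_, levels_ = [], [], []
        for chrom, length in genome.items():
            pos = np.arange(25, length, 101)
            if exclude_te_bodies:
                pos = _outside_tes(chrom, pos)
            chroms_.extend([chrom] * len(pos))
            poss_.extend(pos.tolist())
            levels_.extend(
                np.clip(
                    rng.normal(config.meth_background, 0.02, len(pos)), 0.0, 1.0
                ).tolist()
                if config.meth_background > 0
                else [0.0] * len(pos)
            )
        return chroms_, poss_, levels_

    for context, te_level in (("CG", config.meth_cg_te), ("CHG", config.meth_chg_te)):
        chroms_, poss_, levels_ = background(exclude_te_bodies=te_level > 0)
        if te_level > 0:
            for te in tes:
                pos = np.arange(te.interval.start + 5, te.interval.end, 10)
                chroms_.extend([te.interval.chrom] * len(pos))
                poss_.extend(pos.tolist())
                levels_.extend(
                    np.clip(rng.normal(te_level, 0.03, len(pos)), 0.0, 1.0).tolist()
                )
        track = pd.DataFrame({"chrom": chroms_, "pos": poss_, "level": levels_})
        # later records (TE bodies) override the sparse background at ties
        track = track.drop_duplicates(["chrom", "pos"], keep="last")
        tracks[context] = track.sort_values(["chrom", "pos"]).reset_index(drop=True)

    chroms_, poss_, levels_ = background(exclude_te_bodies=False)
    lo_off, hi_off = config.island_offset
    if config.meth_chh_island > 0:
        for gene in genes:
            if gene.gene_id not in island_set:
                continue
            # strand-oriented offsets relative to TSS (negative = upstream)
            if gene.strand == "+":
                lo, hi = gene.tss + lo_off, gene.tss + hi_off
            else:
                lo, hi = gene.tss - hi_off, gene.tss - lo_off
            lo = max(0, lo)
            hi = min(genome[gene.interval.chrom], hi)
            pos = np.arange(lo, hi, 5)
            chroms_.extend([gene.interval.chrom] * len(pos))
            poss_.extend(pos.tolist())
            levels_.extend(
                np.clip(
                    rng.normal(config.meth_chh_island, 0.03, len(pos)), 0.0, 1.0
                ).tolist()
            )
    track = pd.DataFrame({"chrom": chroms_, "pos": poss_, "level": levels_})
    track = track.drop_duplicates(["chrom", "pos"], keep="last")
    tracks["CHH"] = track.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return tracks


def simulate_alignments(
    config: SimulationConfig,
    genome: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[GenomicInterval]], dict[str, float]]:
    """Fixed-length footprints realising the target >=2-read coverage.

    The genome is divided into footprint-length slots; for each genotype
    the number of slots needed to cover the target fraction is drawn
    without replacement and two identical footprints are stacked on each
    chosen slot, so the fraction of bases at depth >= 2 equals
    ``n_slots_chosen * L / genome_size`` exactly (within one slot of
    rounding).  Returns the footprints and the realised fractions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if genome is None:
        genome = config.genome
    L = config.footprint_length
    chroms = list(genome)
    slots_per_chrom = [genome[c] // L for c in chroms]
    total_slots = int(sum(slots_per_chrom))
    total_bases = int(sum(genome.values()))
    offsets = np.cumsum([0] + slots_per_chrom)

    result: dict[str, list[GenomicInterval]] = {}
    realized: dict[str, float] = {}
    for genotype, frac in (
        ("wt", config.transcribed_frac_wt),
        ("mut", config.transcribed_frac_mut),
    ):
        if frac == 0:
            result[genotype] = []
            realized[genotype] = 0.0
            continue
        n_seg = int(round(frac * total_bases / L))
        if n_seg > total_slots:
            raise ValueError(
                f"target fraction {frac} infeasible: needs {n_seg} slots, "
                f"have {total_slots}"
            )
        chosen = rng.choice(total_slots, size=n_seg, replace=False)
        footprints: list[GenomicInterval] = []
        for slot in np.sort(chosen):
            ci = int(np.searchsorted(offsets, slot, side="right") - 1)
            start = int((slot - offsets[ci]) * L)
            iv = GenomicInterval(chroms[ci], start, start + L)
            footprints.append(iv)
            footprints.append(iv)  # depth 2
        result[genotype] = footprints
        realized[genotype] = n_seg * L / total_bases
    return result, realized


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator pipeline under one seed."""
    rng = np.random.default_rng(config.seed)
    genes, tes, sirna, truth = simulate_annotation(config, rng)
    expression = simulate_expression(config, genes, truth, rng)
    methylation = simulate_methylation(config, genes, tes, truth, rng)
    alignments, realized = simulate_alignments(config, config.genome, rng)
    truth["realized_transcribed_frac"] = realized
    return SyntheticDataset(
        config=config,
        genome=config.genome,
        genes=genes,
        tes=tes,
        sirna=sirna,
        methylation=methylation,
        expression=expression,
        alignments=alignments,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset as BED / bedGraph / TSV / JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.tsv", "w") as fh:
        for chrom, length in ds.genome.items():
            fh.write(f"{chrom}\t{length}\n")
    write_bed(
        outdir / "genes.bed",
        [(g.interval, g.gene_id, 0.0) for g in ds.genes],
    )
    write_bed(
        outdir / "tes.bed",
        [(t.interval, f"{t.superfamily}:{t.family}", 0.0) for t in ds.tes],
    )
    write_bed(
        outdir / "sirna.bed",
        [(s.interval, s.locus_id, 0.0) for s in ds.sirna],
    )
    for genotype, footprints in ds.alignments.items():
        write_bed(
            outdir / f"alignments_{genotype}.bed",
            [(iv, ".", 0.0) for iv in footprints],
        )
    for context, track in ds.methylation.items():
        with open(outdir / f"meth_{context.lower()}.bedgraph", "w") as fh:
            for row in track.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.level:.4f}\n")
    ds.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    with open(outdir / "config.json", "w") as fh:
        cfg = asdict(ds.config)
        cfg["island_offset"] = list(cfg["island_offset"])
        json.dump(cfg, fh, indent=1)
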