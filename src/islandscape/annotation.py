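"""Gene models, annotation-source merging, and peak-to-gene assignment.

Two annotation sources ("refseq"-like and "ensembl"-like) are merged with
RefSeq precedence: every RefSeq gene is kept and an Ensembl gene is kept only
when it overlaps no RefSeq gene on the same chromosome (and, by default, the
same strand).  Called islands are then related to the merged gene set three
ways: promoter/gene-body overlap ("enriched genes"), genomic-feature
classification of the island midpoint, and signed distance from island
midpoint to the nearest TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import Genome
from .islands import Island

logger = logging.getLogger(__name__)


class FeatureClass(str, Enum):
    """Seven-way genomic feature partition for peak midpoints."""

    FIVE_PRIME_UTR = "five_prime_utr"
    THREE_PRIME_UTR = "three_prime_utr"
    EXON = "exon"
    FIRST_INTRON = "first_intron"
    LAST_INTRON = "last_intron"
    OTHER_INTRON = "other_intron"
    INTERGENIC = "intergenic"


#: precedence when a midpoint hits several features / genes (highest first)
_FEATURE_PRECEDENCE = [
    FeatureClass.FIVE_PRIME_UTR,
    FeatureClass.THREE_PRIME_UTR,
    FeatureClass.EXON,
    FeatureClass.FIRST_INTRON,
    FeatureClass.LAST_INTRON,
    FeatureClass.OTHER_INTRON,
]
_RANK = {f: i for i, f in enumerate(_FEATURE_PRECEDENCE)}


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: span, strand, exon structure, optional UTRs.

    ``tx_start < tx_end`` in genomic coordinates regardless of strand; the
    TSS/TES are derived boundary coordinates respecting strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    source: str = "refseq"
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e or s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        """5' boundary coordinate (txStart on +, txEnd on -)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


def gene_region(
    gene: GeneModel, kind: str, genome: Genome | None = None
) -> tuple[int, int]:
    """Interval used for enriched-gene overlap tests.

    ``promoter_1kb``/``promoter_2kb``: TSS +/- 1 or 2 kb; ``extended``: gene
    span widened by 5 kb on both sides.  Clipped at chromosome bounds.
    """
    if kind == "promoter_1kb":
        lo, hi = gene.tss - 1000, gene.tss + 1000
    elif kind == "promoter_2kb":
        lo, hi = gene.tss - 2000, gene.tss + 2000
    elif kind == "extended":
        lo, hi = gene.tx_start - 5000, gene.tx_end + 5000
    else:
        raise ValueError(f"unknown region kind {kind!r}")
    lo = max(lo, 0)
    if genome is not None:
        hi = min(hi, genome.chrom_lengths[gene.chrom])
    return lo, hi


def merge_annotations(
    refseq_genes: list[GeneModel],
    ensembl_genes: list[GeneModel],
    require_same_strand: bool = True,
) -> list[GeneModel]:
    """Non-redundant gene list with RefSeq precedence.

    Every RefSeq gene is retained; an Ensembl gene is retained iff its span
    overlaps no RefSeq gene on the same chromosome (and strand, by default).
    """
    for name, genes in (("refseq", refseq_genes), ("ensembl", ensembl_genes)):
        ids = [g.gene_id for g in genes]
        if len(ids) != len(set(ids)):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_ids in {name} source: {dups}")

    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in refseq_genes:
        key = (g.chrom, g.strand if require_same_strand else ".")
        trees.setdefault(key, IntervalTree())[g.tx_start : g.tx_end] = g.gene_id

    merged = list(refseq_genes)
    for g in ensembl_genes:
        key = (g.chrom, g.strand if require_same_strand else ".")
        tree = trees.get(key)
        if tree is None or not tree.overlap(g.tx_start, g.tx_end):
            merged.append(g)
    merged.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return merged


def enriched_genes(
    islands: list[Island],
    genes: list[GeneModel],
    region_kind: str = "promoter_2kb",
    genome: Genome | None = None,
) -> list[str]:
    """Genes whose chosen region overlaps (>= 1 bp) at least one island."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {i.chrom for i in islands}:
        sub = sorted((i for i in islands if i.chrom == chrom), key=lambda i: i.start)
        starts[chrom] = np.array([i.start for i in sub])
        ends[chrom] = np.array([i.end for i in sub])
    hits = []
    for gene in genes:
        if gene.chrom not in starts:
            continue
        lo, hi = gene_region(gene, region_kind, genome)
        # islands sorted & disjoint: the first island ending beyond lo is the
        # only candidate that can start before hi
        j = int(np.searchsorted(ends[gene.chrom], lo, side="right"))
        if j < len(starts[gene.chrom]) and starts[gene.chrom][j] < hi:
            hits.append(gene.gene_id)
    return sorted(hits)


def gene_set_comparison(genes_a: list[str], genes_b: list[str]) -> dict[str, int]:
    """Shared/unique accounting for two enriched-gene lists."""
    a, b = set(genes_a), set(genes_b)
    return {
        "total_a": len(a),
        "total_b": len(b),
        "shared": len(a & b),
        "unique_a": len(a - b),
        "unique_b": len(b - a),
    }


def _feature_within_gene(gene: GeneModel, pos: float) -> FeatureClass | None:
    """Feature of ``pos`` inside one gene body, or None if outside the span."""
    if not gene.tx_start <= pos < gene.tx_end:
        return None
    if gene.utr5 is not None and gene.utr5[0] <= pos < gene.utr5[1]:
        return FeatureClass.FIVE_PRIME_UTR
    if gene.utr3 is not None and gene.utr3[0] <= pos < gene.utr3[1]:
        return FeatureClass.THREE_PRIME_UTR
    for s, e in gene.exons:
        if s <= pos < e:
            return FeatureClass.EXON
    introns = gene.introns
    for i, (s, e) in enumerate(introns):
        if s <= pos < e:
            n = len(introns)
            order = i if gene.strand == "+" else n - 1 - i  # 5'-first index
            if n == 1 or order == 0:
                return FeatureClass.FIRST_INTRON
            if order == n - 1:
                return FeatureClass.LAST_INTRON
            return FeatureClass.OTHER_INTRON
    return None  # unreachable for a valid model


class GeneIndex:
    """Interval index over merged gene bodies for midpoint lookups."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = genes
        self._trees: dict[str, IntervalTree] = {}
        self._tss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._trees.setdefault(g.chrom, IntervalTree())[g.tx_start : g.tx_end] = g
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss[chrom] = (np.array([g.tss for g in gs_sorted]), gs_sorted)

    def overlapping(self, chrom: str, pos: float) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def tss_table(self, chrom: str) -> tuple[np.ndarray, list[GeneModel]] | None:
        return self._tss.get(chrom)


def classify_peak(island: Island, index: GeneIndex) -> FeatureClass:
    """Genomic feature of the island midpoint, with fixed precedence.

    Precedence across overlapping features/genes: 5'UTR > 3'UTR > exon >
    first intron > last intron > other intron; a midpoint inside no gene body
    is intergenic.  A single-intron gene's intron counts as first intron.
    """
    pos = island.midpoint
    best: FeatureClass | None = None
    for gene in index.overlapping(island.chrom, pos):
        feat = _feature_within_gene(gene, pos)
        if feat is not None and (best is None or _RANK[feat] < _RANK[best]):
            best = feat
    return best if best is not None else FeatureClass.INTERGENIC


def classify_peaks(islands: list[Island], genes: list[GeneModel]) -> pd.DataFrame:
    """Feature class per island plus the category fraction table."""
    index = GeneIndex(genes)
    rows = [
        {
            "chrom": i.chrom,
            "start": i.start,
            "end": i.end,
            "feature": classify_peak(i, index).value,
        }
        for i in islands
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature"])


def feature_fractions(classified: pd.DataFrame) -> pd.Series:
    """Fraction of islands per feature class (sums to 1 over a nonempty set)."""
    order = [f.value for f in FeatureClass]
    counts = classified["feature"].value_counts().reindex(order, fill_value=0)
    return counts / max(len(classified), 1)


def distance_to_tss(island: Island, index: GeneIndex) -> tuple[str, int] | None:
    """(gene_id, signed bp) from island midpoint to the nearest TSS.

    Negative distances are upstream of the TSS in the gene's own orientation.
    Ties on absolute distance break toward the lexicographically smallest
    gene_id.  Returns None (with a warning) for a chromosome without genes.
    """
    table = index.tss_table(island.chrom)
    if table is None:
        logger.warning("no genes on chromosome %s; island skipped", island.chrom)
        return None
    tss, genes = table
    mid = island.midpoint
    dist = np.abs(tss - mid)
    best = np.flatnonzero(dist == dist.min())
    gene = min((genes[i] for i in best), key=lambda g: g.gene_id)
    signed = mid - gene.tss if gene.strand == "+" else gene.tss - mid
    return gene.gene_id, int(round(signed))


def distances_to_tss(islands: list[Island], genes: list[GeneModel]) -> pd.DataFrame:
    index = GeneIndex(genes)
    rows = []
    for isl in islands:
        hit = distance_to_tss(isl, index)
        if hit is not None:
            rows.append({"chrom": isl.chrom, "midpoint": isl.midpoint,
                         "gene_id": hit[0], "distance": hit[1]})
    return pd.DataFrame(rows, columns=["chrom", "midpoint", "gene_id", "distance"])


def chromosome_distribution(islands: list[Island], genome: Genome) -> pd.DataFrame:
    """Per-chromosome island counts, percentages, and length-relative density."""
    counts = {c: 0 for c in genome.chroms}
    for isl in islands:
        if isl.chrom not in counts:
            raise ValueError(f"island on unknown chromosome {isl.chrom!r}")
        counts[isl.chrom] += 1
    total = sum(counts.values())
    rows = []
    for chrom in genome.chroms:
        frac_len = genome.chrom_lengths[chrom] / genome.total_length
        pct = 100.0 * counts[chrom] / total if total else 0.0
        rows.append(
            {
                "chrom": chrom,
                "n_islands": counts[chrom],
                "pct_islands": pct,
                "pct_length": 100.0 * frac_len,
                "relative_density": (pct / 100.0) / frac_len if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
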