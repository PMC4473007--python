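"""Annotation merging, enriched genes, feature classification, TSS distances."""

import numpy as np
import pytest

from islandscape import (
    FeatureClass,
    GeneModel,
    Genome,
    SimulationConfig,
    chromosome_distribution,
    classify_peak,
    classify_peaks,
    distance_to_tss,
    enriched_genes,
    feature_fractions,
    gene_region,
    gene_set_comparison,
    merge_annotations,
    simulate_annotation,
)
from islandscape.annotation import GeneIndex
from islandscape.islands import Island


def gene(gene_id, chrom="chr1", strand="+", start=10_000, end=20_000, exons=None,
         source="refseq", utr5=None, utr3=None):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tx_start=start, tx_end=end,
        exons=tuple(exons) if exons else ((start, end),), source=source,
        utr5=utr5, utr3=utr3,
    )


def _island(chrom, start, end):
    return Island(chrom, start, end, read_count=1, score=10.0, eligible_window_count=1)


class TestMergeAnnotations:
    def test_refseq_wins_on_identical_coordinates(self):
        ref = [gene("NM_1")]
        ens = [gene("ENS_1", source="ensembl")]
        merged = merge_annotations(ref, ens)
        assert [g.gene_id for g in merged] == ["NM_1"]

    def test_ensembl_only_chromosome_retained(self):
        ref = [gene("NM_1", chrom="chr1")]
        ens = [gene("ENS_2", chrom="chr2", source="ensembl")]
        merged = merge_annotations(ref, ens)
        assert {g.gene_id for g in merged} == {"NM_1", "ENS_2"}

    def test_strand_requirement_is_configurable(self):
        ref = [gene("NM_1", strand="+")]
        ens = [gene("ENS_1", strand="-", source="ensembl")]
        assert len(merge_annotations(ref, ens)) == 2
        assert len(merge_annotations(ref, ens, require_same_strand=False)) == 1

    def test_duplicate_ids_within_source_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene_ids"):
            merge_annotations([gene("NM_1"), gene("NM_1", start=30_000, end=40_000)], [])

    def test_generator_overlap_fraction_accounting(self):
        # 150 master genes at overlap 0.5 -> 100 genes per source, merged 150
        config = SimulationConfig(
            n_chromosomes=4, chrom_length=1_000_000, n_genes=150,
            gene_length_range=(2000, 4000), overlap_fraction=0.5, seed=3,
        )
        refseq, ensembl, _ = simulate_annotation(config)
        assert len(refseq) == len(ensembl) == 100
        merged = merge_annotations(refseq, ensembl)
        assert len(merged) == 150

    def test_merged_never_larger_than_inputs(self):
        config = SimulationConfig(
            n_chromosomes=2, chrom_length=1_000_000, n_genes=60, seed=5,
            gene_length_range=(2000, 4000),
        )
        refseq, ensembl, _ = simulate_annotation(config)
        merged = merge_annotations(refseq, ensembl)
        assert len(merged) <= len(refseq) + len(ensembl)


class TestEnrichedGenes:
    def test_island_covering_promoter_enriches_gene(self):
        g = gene("NM_1", start=10_000, end=20_000, strand="+")
        hits = enriched_genes([_island("chr1", 8_000, 12_000)], [g], "promoter_2kb")
        assert hits == ["NM_1"]

    def test_island_one_bp_outside_region_misses(self):
        g = gene("NM_1", start=10_000, end=20_000, strand="+")
        # promoter_2kb = [8000, 12000); island ending exactly at 8000 does not overlap
        assert enriched_genes([_island("chr1", 7_000, 8_000)], [g], "promoter_2kb") == []
        assert enriched_genes([_island("chr1", 7_000, 8_001)], [g], "promoter_2kb") == ["NM_1"]

    def test_region_kinds_differ(self):
        g = gene("NM_1", start=10_000, end=20_000, strand="+")
        isl = [_island("chr1", 23_000, 23_500)]  # 3 kb past the gene end
        assert enriched_genes(isl, [g], "promoter_2kb") == []
        assert enriched_genes(isl, [g], "extended") == ["NM_1"]

    def test_unknown_region_kind_rejected(self):
        with pytest.raises(ValueError, match="region kind"):
            gene_region(gene("NM_1"), "promoter_10kb")

    def test_gene_set_accounting_identity(self):
        cmp_ = gene_set_comparison(["a", "b", "c"], ["b", "c", "d"])
        assert cmp_["shared"] + cmp_["unique_a"] == cmp_["total_a"] == 3
        assert cmp_["shared"] + cmp_["unique_b"] == cmp_["total_b"] == 3


class TestClassifyPeak:
    @pytest.fixture()
    def structured_gene(self):
        # + strand gene: exons [10000,12000), [14000,16000), [18000,20000)
        return gene(
            "NM_1", start=10_000, end=20_000,
            exons=[(10_000, 12_000), (14_000, 16_000), (18_000, 20_000)],
            utr5=(10_000, 10_200), utr3=(19_800, 20_000),
        )

    def test_midpoint_in_five_prime_utr(self, structured_gene):
        idx = GeneIndex([structured_gene])
        isl = _island("chr1", 10_000, 10_200)
        assert classify_peak(isl, idx) is FeatureClass.FIVE_PRIME_UTR

    def test_midpoint_in_exon_and_introns(self, structured_gene):
        idx = GeneIndex([structured_gene])
        assert classify_peak(_island("chr1", 14_500, 15_000), idx) is FeatureClass.EXON
        assert classify_peak(_island("chr1", 12_500, 13_000), idx) is FeatureClass.FIRST_INTRON
        assert classify_peak(_island("chr1", 16_500, 17_000), idx) is FeatureClass.LAST_INTRON

    def test_strand_flips_intron_order(self):
        g = gene(
            "NM_2", strand="-", start=10_000, end=20_000,
            exons=[(10_000, 12_000), (14_000, 16_000), (18_000, 20_000)],
        )
        idx = GeneIndex([g])
        # genomic-first intron is the 5'-last for a - strand gene
        assert classify_peak(_island("chr1", 12_500, 13_000), idx) is FeatureClass.LAST_INTRON
        assert classify_peak(_island("chr1", 16_500, 17_000), idx) is FeatureClass.FIRST_INTRON

    def test_single_intron_counts_as_first(self):
        g = gene("NM_3", exons=[(10_000, 12_000), (14_000, 20_000)])
        idx = GeneIndex([g])
        assert classify_peak(_island("chr1", 12_500, 13_500), idx) is FeatureClass.FIRST_INTRON

    def test_midpoint_between_genes_is_intergenic(self, structured_gene):
        idx = GeneIndex([structured_gene])
        assert classify_peak(_island("chr1", 30_000, 31_000), idx) is FeatureClass.INTERGENIC

    def test_fractions_partition_to_one(self, structured_gene):
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 50_000, size=1000)
        islands = [_island("chr1", int(s), int(s) + 400) for s in starts]
        classified = classify_peaks(islands, [structured_gene])
        assert feature_fractions(classified).sum() == pytest.approx(1.0)


class TestDistanceToTss:
    def test_upstream_of_plus_strand_is_negative(self):
        g = gene("NM_1", start=10_000, end=20_000, strand="+")
        idx = GeneIndex([g])
        # midpoint at 9500: 500 bp 5' of the TSS
        assert distance_to_tss(_island("chr1", 9_300, 9_700), idx) == ("NM_1", -500)

    def test_upstream_of_minus_strand_is_negative_after_flip(self):
        g = gene("NM_1", start=10_000, end=20_000, strand="-")  # TSS boundary at 20000
        idx = GeneIndex([g])
        assert distance_to_tss(_island("chr1", 20_300, 20_700), idx) == ("NM_1", -500)

    def test_tie_breaks_to_lexicographic_gene_id(self):
        a = gene("NM_A", start=10_000, end=12_000, strand="+")
        b = gene("NM_B", start=14_000, end=16_000, strand="+")
        idx = GeneIndex([a, b])
        # midpoint 12000 is equidistant (2000) from both TSSs
        gid, _ = distance_to_tss(_island("chr1", 11_800, 12_200), idx)
        assert gid == "NM_A"

    def test_chromosome_without_genes_warns_and_skips(self, caplog):
        idx = GeneIndex([gene("NM_1")])
        with caplog.at_level("WARNING"):
            assert distance_to_tss(_island("chr9", 0, 400), idx) is None


class TestChromosomeDistribution:
    GENOME = Genome({"chr1": 1_000_000, "chr2": 3_000_000})

    def test_all_islands_on_one_chromosome(self):
        islands = [_island("chr1", i * 1000, i * 1000 + 200) for i in range(5)]
        dist = chromosome_distribution(islands, self.GENOME)
        assert dist.set_index("chrom")["pct_islands"]["chr1"] == 100.0
        assert dist["pct_islands"].sum() == pytest.approx(100.0)

    def test_uniform_islands_have_unit_relative_density(self):
        rng = np.random.default_rng(0)
        islands = []
        for _ in range(4000):
            chrom = "chr1" if rng.random() < 0.25 else "chr2"
            s = int(rng.integers(0, self.GENOME.chrom_lengths[chrom] - 200))
            islands.append(_island(chrom, s, s + 200))
        dist = chromosome_distribution(islands, self.GENOME).set_index("chrom")
        for chrom in ("chr1", "chr2"):
            p = self.GENOME.chrom_lengths[chrom] / self.GENOME.total_length
            se = np.sqrt(p * (1 - p) / 4000) / p
            assert abs(dist["relative_density"][chrom] - 1.0) < 3 * se

    def test_empty_island_list_gives_zeros(self):
        dist = chromosome_distribution([], self.GENOME)
        assert (dist["n_islands"] == 0).all()

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            chromosome_distribution([_island("chrX", 0, 200)], self.GENOME)
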