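import numpy as np
import pandas as pd
import pytest

from islandscape import (
    Genome,
    SimulationConfig,
    deduplicate,
    drop_multimappers,
    extend_reads,
    merge_annotations,
    simulate_all,
    summarize_windows,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-condition simulation shared by read-level tests."""
    config = SimulationConfig(
        n_chromosomes=2,
        chrom_length=1_000_000,
        n_genes=40,
        n_background_reads=5_000,
        enrichment_reads_per_active_gene=60.0,
        duplicate_fraction=0.3,
        multimap_fraction=0.2,
        seed=11,
    )
    return simulate_all(config)


@pytest.fixture(scope="session")
def merged_genes(small_sim):
    return merge_annotations(small_sim.refseq, small_sim.ensembl)


@pytest.fixture(scope="session")
def filtered_fragments(small_sim):
    reads = deduplicate(drop_multimappers(small_sim.reads["tender"]))
    return extend_reads(reads, small_sim.config.fragment_length, small_sim.genome)


def make_track(counts, window_size=200, chrom="chr1", total=None):
    """Build a WindowTrack directly from a count vector (test helper)."""
    counts = np.asarray(counts)
    genome = Genome({chrom: len(counts) * window_size})
    from islandscape.reads import WindowTrack

    return WindowTrack(
        window_size=window_size,
        counts={chrom: counts},
        genome=genome,
        total_mapped_reads=int(total if total is not None else counts.sum()),
    )


def reads_frame(rows):
    """rows: (chrom, start, strand[, multimap]) tuples with read length 25."""
    columns = ["chrom", "start", "end", "strand", "multimap"]
    if not rows:
        return pd.DataFrame(columns=columns)
    recs = []
    for row in rows:
        chrom, start, strand = row[:3]
        mm = row[3] if len(row) > 3 else False
        recs.append(
            {"chrom": chrom, "start": start, "end": start + 25, "strand": strand,
             "multimap": mm}
        )
    return pd.DataFrame(recs)
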