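"""Plain-text readers/writers for the formats the pipeline exchanges.

Reads travel as BED6 (name column = read id, score column = multimap flag),
gene models as BED12 (thickStart/thickEnd carry the UTR boundaries) or as a
flat GFF3-like TSV that round-trips every GeneModel field, window tracks as
bedGraph, islands as a BED6+ TSV with a read_count column, expression as a
probe TSV, and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .islands import Island
from .reads import WindowTrack

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_reads_bed6(reads: pd.DataFrame, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["end"],
            "name": reads["name"]
            if "name" in reads.columns
            else [f"read{i}" for i in range(len(reads))],
            "score": reads["multimap"].astype(int) if "multimap" in reads.columns else 0,
            "strand": reads["strand"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    return pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "strand": df["strand"].astype(str),
            "multimap": df["score"].astype(bool),
            "name": df["name"].astype(str),
        }
    )


def write_genes_bed12(genes: list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        # thick region = span minus the planted terminal UTRs (CDS analogue)
        thick_start = g.utr5[1] if (g.strand == "+" and g.utr5) else g.tx_start
        thick_end = g.utr3[0] if (g.strand == "+" and g.utr3) else g.tx_end
        if g.strand == "-":
            thick_start = g.utr3[1] if g.utr3 else g.tx_start
            thick_end = g.utr5[0] if g.utr5 else g.tx_end
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - g.tx_start) for s, _ in g.exons)
        rows.append(
            [g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
             thick_start, thick_end, 0, len(g.exons), sizes, starts]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_genes_tsv(genes: list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "source": g.source,
                "chrom": g.chrom,
                "start": g.tx_start,
                "end": g.tx_end,
                "strand": g.strand,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
                "utr5": f"{g.utr5[0]}-{g.utr5[1]}" if g.utr5 else ".",
                "utr3": f"{g.utr3[0]}-{g.utr3[1]}" if g.utr3 else ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_span(text: str) -> tuple[int, int] | None:
    if text in (".", "", None) or pd.isna(text):
        return None
    a, b = text.split("-")
    return int(a), int(b)


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"utr5": str, "utr3": str})
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.start),
                tx_end=int(row.end),
                exons=tuple(zip(starts, ends)),
                source=str(row.source),
                utr5=_parse_span(row.utr5),
                utr3=_parse_span(row.utr3),
            )
        )
    return genes


def write_bedgraph(track: WindowTrack, path: str | Path) -> None:
    """Write non-zero windows as bedGraph (values rounded to 4 decimals)."""
    with open(path, "w") as fh:
        for chrom, counts in track.counts.items():
            chrom_len = track.genome.chrom_lengths[chrom]
            nz = np.flatnonzero(counts)
            for i in nz:
                start = int(i) * track.window_size
                end = min(start + track.window_size, chrom_len)
                v = counts[i]
                text = str(int(v)) if not track.normalized else f"{v:.4f}"
                fh.write(f"{chrom}\t{start}\t{end}\t{text}\n")


ISLAND_COLUMNS = ["chrom", "start", "end", "name", "score", "read_count"]


def write_islands(islands: list[Island], path: str | Path) -> None:
    rows = [
        [i.chrom, i.start, i.end, f"island_{n + 1}", round(i.score, 4), i.read_count]
        for n, i in enumerate(islands)
    ]
    pd.DataFrame(rows, columns=ISLAND_COLUMNS).to_csv(path, sep="\t", index=False)


def read_islands(path: str | Path) -> list[Island]:
    df = pd.read_csv(path, sep="\t")
    return [
        Island(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            read_count=float(r.read_count),
            score=float(r.score),
            eligible_window_count=0,
        )
        for r in df.itertuples(index=False)
    ]


def write_expression_tsv(probe_table: pd.DataFrame, path: str | Path) -> None:
    probe_table.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
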