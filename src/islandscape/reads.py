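"""Read filtering and fixed-width window summarization.

Aligned single-end reads are held in a pandas DataFrame with columns
``chrom, start, end, strand, multimap`` (0-based half-open coordinates;
``multimap`` is a boolean flag carried over from the aligner).  The pipeline
order used downstream is: drop multi-mappers, remove position duplicates,
extend each read to the estimated fragment length, then count extended
fragments in non-overlapping windows (200 bp by default) and optionally
rescale the track to reads-per-million.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import Genome

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand", "multimap"]


def _check_read_frame(reads: pd.DataFrame) -> None:
    missing = [c for c in ("chrom", "start", "end", "strand") if c not in reads.columns]
    if missing:
        raise ValueError(f"read table is missing columns: {missing}")


@dataclass
class WindowTrack:
    """Per-chromosome vectors of read (fragment) counts in fixed windows.

    ``total_mapped_reads`` is the per-million normalization denominator: the
    number of filtered, uniquely mapped reads in the sample.  ``counts`` are
    raw non-negative integers until :func:`normalize_per_million` is applied,
    after which ``normalized`` is set and ``scale`` records the factor.
    """

    window_size: int
    counts: dict[str, np.ndarray]
    genome: Genome
    total_mapped_reads: int
    normalized: bool = False
    scale: float = 1.0

    def __post_init__(self) -> None:
        expected = self.genome.windows_per_chrom(self.window_size)
        for chrom, vec in self.counts.items():
            if chrom not in expected:
                raise ValueError(f"track chromosome {chrom!r} absent from genome")
            if len(vec) != expected[chrom]:
                raise ValueError(
                    f"{chrom}: count vector length {len(vec)} != "
                    f"ceil(chrom_length / window_size) = {expected[chrom]}"
                )

    @property
    def total_summarized(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    @property
    def n_windows(self) -> int:
        return sum(len(v) for v in self.counts.values())


def deduplicate(reads: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one read per (chrom, start, strand) key.

    Library amplification produces exact positional copies; only one is
    informative.  The surviving record's multimap flag is the logical AND of
    the copies' flags (copies of one template share mapping status), which
    makes deduplication commute with multi-mapper removal.
    """
    _check_read_frame(reads)
    if reads.empty:
        return reads.copy()
    df = reads.sort_values(["chrom", "start", "strand"], kind="mergesort")
    key = ["chrom", "start", "strand"]
    if "multimap" in df.columns:
        flags = df.groupby(key, sort=True)["multimap"].all()
        first = df.drop_duplicates(key).set_index(key)
        first["multimap"] = flags
        out = first.reset_index()
    else:
        out = df.drop_duplicates(key)
    return out.reset_index(drop=True)[list(reads.columns)]


def drop_multimappers(reads: pd.DataFrame) -> pd.DataFrame:
    """Retain only uniquely aligned reads (multimap flag false)."""
    _check_read_frame(reads)
    if "multimap" not in reads.columns:
        raise ValueError("read table has no 'multimap' column")
    out = reads.loc[~reads["multimap"].astype(bool)].reset_index(drop=True)
    if len(reads) and out.empty:
        logger.warning("all %d reads were multi-mapping; empty read set returned", len(reads))
    return out


def extend_reads(reads: pd.DataFrame, fragment_length: int, genome: Genome) -> pd.DataFrame:
    """Extend each read to the estimated fragment length in its 3' direction.

    A + strand read becomes ``[start, start + L)``, a - strand read
    ``[end - L, end)``, clipped to chromosome bounds.  Returns a DataFrame
    with columns ``chrom, start, end``.
    """
    _check_read_frame(reads)
    if reads.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    lengths = (reads["end"] - reads["start"]).to_numpy()
    if fragment_length < lengths.max():
        raise ValueError(
            f"fragment_length {fragment_length} shorter than read length {lengths.max()}"
        )
    start = reads["start"].to_numpy(dtype=np.int64)
    end = reads["end"].to_numpy(dtype=np.int64)
    plus = (reads["strand"] == "+").to_numpy()
    new_start = np.where(plus, start, end - fragment_length)
    new_end = np.where(plus, start + fragment_length, end)
    chrom_len = reads["chrom"].map(genome.chrom_lengths).to_numpy(dtype=np.int64)
    new_start = np.clip(new_start, 0, None)
    new_end = np.minimum(new_end, chrom_len)
    return pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "start": new_start, "end": new_end})


def summarize_windows(
    intervals: pd.DataFrame,
    genome: Genome,
    window_size: int = 200,
    method: str = "midpoint",
) -> WindowTrack:
    """Count intervals in non-overlapping fixed-width windows.

    ``method='midpoint'`` (default) assigns each interval once, to the window
    containing its midpoint, so window counts are conserved read counts.
    ``method='coverage'`` instead accumulates covered base pairs per window
    divided by the window size (fractional values; not used by the island
    caller).
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    if method not in ("midpoint", "coverage"):
        raise ValueError(f"unknown summarization method {method!r}")
    n_win = genome.windows_per_chrom(window_size)
    counts: dict[str, np.ndarray] = {}
    dtype = np.int64 if method == "midpoint" else np.float64
    for chrom in genome.chroms:
        counts[chrom] = np.zeros(n_win[chrom], dtype=dtype)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        if chrom not in counts:
            raise ValueError(f"interval chromosome {chrom!r} absent from genome")
        start = grp["start"].to_numpy(dtype=np.int64)
        end = grp["end"].to_numpy(dtype=np.int64)
        if method == "midpoint":
            mid = (start + end) // 2
            idx = np.minimum(mid // window_size, n_win[chrom] - 1)
            counts[chrom] += np.bincount(idx, minlength=n_win[chrom])
        else:
            cov = np.zeros(genome.chrom_lengths[chrom] + 1, dtype=np.float64)
            np.add.at(cov, start, 1.0)
            np.add.at(cov, end, -1.0)
            perbp = np.cumsum(cov[:-1])
            pad = n_win[chrom] * window_size - len(perbp)
            if pad:
                perbp = np.concatenate([perbp, np.zeros(pad)])
            counts[chrom] += perbp.reshape(n_win[chrom], window_size).sum(axis=1) / window_size
    return WindowTrack(
        window_size=window_size,
        counts=counts,
        genome=genome,
        total_mapped_reads=len(intervals),
    )


def normalize_per_million(track: WindowTrack) -> WindowTrack:
    """Rescale window counts to reads per million mapped reads of the sample."""
    if track.normalized:
        raise ValueError("track is already normalized; refusing to normalize twice")
    if track.total_mapped_reads <= 0:
        raise ValueError("cannot normalize a track with total_mapped_reads = 0")
    scale = 1e6 / track.total_mapped_reads
    counts = {c: v.astype(np.float64) * scale for c, v in track.counts.items()}
    return replace(track, counts=counts, normalized=True, scale=scale)
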