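"""Genome geometry shared by every stage.

Coordinate convention (used everywhere in this package): 0-based, half-open
intervals ``[start, end)``.  A transcription start site (TSS) is stored as the
half-open *boundary* coordinate of the 5' end — ``txStart`` for + strand
genes, ``txEnd`` for - strand genes — which keeps strand-symmetric arithmetic
exact (mirroring the genome maps a TSS boundary onto a TSS boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome name -> length (bp) table."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def windows_per_chrom(self, window_size: int) -> dict[str, int]:
        if window_size <= 0:
            raise ValueError(f"window_size must be positive, got {window_size}")
        return {c: math.ceil(n / window_size) for c, n in self.chrom_lengths.items()}

    def n_windows(self, window_size: int) -> int:
        return sum(self.windows_per_chrom(window_size).values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths
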