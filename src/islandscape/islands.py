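"""SICER-style island (broad peak) calling from a window track.

The model: under the null, reads fall uniformly over the mappable genome, so
the count in a window of size ``W`` is Poisson with genome-average rate

    lambda = N_reads * W / (effective_genome_fraction * genome_length).

A window is *eligible* when its count reaches the smallest integer ``c`` with
``P[Poisson(lambda) >= c] < p_window`` (default 0.20).  Eligible windows
separated by at most ``gap_size`` bp of ineligible windows are clustered into
an island; the island's span is trimmed to its first/last eligible window.
Each eligible window contributes a score ``-ln P[Poisson(lambda) >= count]``
and the island score is the sum over its eligible windows.  Significance is
controlled by an E-value: the score threshold ``s*`` is the smallest score at
which the expected number of random-background islands scoring >= s* is at
most E.

That null expectation is computed exactly for the gapped island definition:
with per-window eligibility probability ``q`` and gap allowance ``g`` windows,
an island starts at an eligible window preceded by more than ``g`` ineligible
windows (rate ``q (1-q)^(g+1)`` per window), continues with probability
``r = 1 - (1-q)^(g+1)`` per additional eligible window, and its score is a
geometric mixture of k-fold convolutions of the single-window score
distribution, evaluated by a dynamic program on a discretized score grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .reads import WindowTrack

logger = logging.getLogger(__name__)

#: smallest probability mass retained when truncating count / length tails
_TAIL_EPS = 1e-12


@dataclass(frozen=True)
class IslandCallerParams:
    """Island caller parameters (defaults follow common broad-mark practice)."""

    window_size: int = 200
    gap_size: int = 400
    e_value: float = 100.0
    fragment_length: int = 190
    effective_genome_fraction: float = 0.74
    window_pvalue: float = 0.20
    score_step: float = 0.1

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.gap_size < 0 or self.gap_size % self.window_size != 0:
            raise ValueError(
                f"gap_size ({self.gap_size}) must be a non-negative multiple of "
                f"window_size ({self.window_size})"
            )
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must be in (0, 1]")
        if not 0 < self.window_pvalue < 1:
            raise ValueError("window_pvalue must be in (0, 1)")
        if self.score_step <= 0:
            raise ValueError("score_step must be positive")

    @property
    def gap_windows(self) -> int:
        return self.gap_size // self.window_size


@dataclass
class Island:
    """A called enriched domain ("peak")."""

    chrom: str
    start: int
    end: int
    read_count: float
    score: float
    eligible_window_count: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class PeakComparison:
    """Two-condition shared/unique peak accounting (>=1 bp overlap)."""

    total_a: int
    total_b: int
    shared_a: int
    shared_b: int
    unique_a: int
    unique_b: int
    pairings: list[tuple[Island, Island]] = field(default_factory=list)


def background_rate(track: WindowTrack, params: IslandCallerParams) -> float:
    """Genome-average Poisson rate per window under the uniform-background null."""
    if track.normalized:
        raise ValueError("background rate must be estimated from a raw (unnormalized) track")
    total = track.total_summarized
    if total <= 0:
        raise ValueError("cannot estimate a background rate from an empty track")
    lam = total * track.window_size / (
        params.effective_genome_fraction * track.genome.total_length
    )
    return float(lam)


def eligibility_threshold(lam: float, p_window: float) -> int:
    """Smallest integer count c with P[Poisson(lam) >= c] < p_window."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    c = 1
    while poisson.sf(c - 1, lam) >= p_window:
        c += 1
    return c


def window_score(count: np.ndarray | int, lam: float) -> np.ndarray | float:
    """-ln P[Poisson(lam) >= count]; the per-window evidence against background."""
    return -poisson.logsf(np.asarray(count) - 1, lam)


def eligible_windows(
    track: WindowTrack, lam: float, p_window: float = 0.20
) -> dict[str, np.ndarray]:
    """Boolean eligibility mask per chromosome."""
    if not 0 < p_window < 1:
        raise ValueError("p_window must be in (0, 1)")
    c = eligibility_threshold(lam, p_window)
    return {chrom: counts >= c for chrom, counts in track.counts.items()}


def aggregate_islands(
    mask: dict[str, np.ndarray],
    track: WindowTrack,
    params: IslandCallerParams,
    lam: float,
) -> list[Island]:
    """Cluster eligible windows into candidate islands.

    Runs of eligible windows separated by at most ``gap_windows`` ineligible
    windows merge into one island.  The reported span is trimmed to the
    first/last eligible window; ``read_count`` sums every window in that span
    (including sub-threshold gap windows) while the score sums only eligible
    windows.
    """
    g = params.gap_windows
    W = track.window_size
    out: list[Island] = []
    for chrom, m in mask.items():
        counts = track.counts[chrom]
        idx = np.flatnonzero(m)
        if idx.size == 0:
            continue
        # split where the run of ineligible windows between neighbours exceeds g
        breaks = np.flatnonzero(np.diff(idx) > g + 1)
        chrom_len = track.genome.chrom_lengths[chrom]
        for grp in np.split(idx, breaks + 1):
            w0, w1 = int(grp[0]), int(grp[-1])
            score = float(np.sum(window_score(counts[grp], lam)))
            out.append(
                Island(
                    chrom=chrom,
                    start=w0 * W,
                    end=min((w1 + 1) * W, chrom_len),
                    read_count=float(counts[w0 : w1 + 1].sum()),
                    score=score,
                    eligible_window_count=int(grp.size),
                )
            )
    out.sort(key=lambda i: (i.chrom, i.start))
    return out


def _single_window_score_pmf(
    lam: float, threshold: int, step: float
) -> tuple[np.ndarray, float]:
    """Discretized score pmf of one eligible window; returns (pmf, q)."""
    q = float(poisson.sf(threshold - 1, lam))
    if q <= 0:
        raise ValueError("eligibility probability is zero; no islands are possible")
    counts = [threshold]
    while poisson.sf(counts[-1], lam) > _TAIL_EPS * q:
        counts.append(counts[-1] + 1)
    counts = np.array(counts)
    mass = poisson.pmf(counts, lam)
    # fold the truncated far tail into the last count so the pmf sums to q
    mass[-1] += poisson.sf(counts[-1], lam)
    scores = window_score(counts, lam)
    # ceil binning: DP island scores dominate true scores, so the expected
    # null count at the chosen threshold is guaranteed <= E (discretization
    # can only push the threshold up, never let the E-value overshoot)
    bins = np.ceil(scores / step).astype(int)
    pmf = np.zeros(bins.max() + 1)
    np.add.at(pmf, bins, mass / q)
    return pmf, q


def score_threshold(
    params: IslandCallerParams, lam: float, genome_windows: int
) -> float:
    """Score threshold s* with expected null island count at/above s* <= E.

    The island-score null distribution is built by dynamic programming on a
    grid of ``score_step`` units (see module docstring); the threshold search
    is monotone in E and resolves grid ties toward the higher (more
    conservative) threshold implied by rounding.
    """
    step = params.score_step
    g = params.gap_windows
    f, q = _single_window_score_pmf(lam, eligibility_threshold(lam, params.window_pvalue), step)
    end_prob = (1.0 - q) ** (g + 1)          # island terminates after a window
    cont = 1.0 - end_prob                    # another eligible window joins
    island_rate = q * end_prob               # islands started per window
    expected_islands = genome_windows * island_rate
    if expected_islands <= params.e_value:
        # even counting every island the expectation is within budget
        return float(np.flatnonzero(f)[0] * step)

    k_max = int(math.ceil(math.log(_TAIL_EPS) / math.log(cont))) + 1 if cont > 0 else 1
    if k_max > 200_000:
        raise RuntimeError(
            "null island-score recursion did not converge "
            f"(continuation probability {cont:.6f} too close to 1 for score_step "
            f"{step}); increase score_step or window_pvalue"
        )
    dist = np.zeros(len(f) * k_max)
    conv = f.copy()
    weight = end_prob
    for _ in range(k_max):
        dist[: len(conv)] += weight * conv
        weight *= cont
        if weight < _TAIL_EPS:
            break
        conv = np.convolve(conv, f)
    tail = np.cumsum(dist[::-1])[::-1]
    expected = expected_islands * tail
    ok = np.flatnonzero(expected <= params.e_value)
    return float(ok[0] * step)


def call_islands(track: WindowTrack, params: IslandCallerParams) -> list[Island]:
    """Full caller: background rate -> eligibility -> clustering -> E-value filter."""
    if track.total_summarized <= 0:
        return []
    lam = background_rate(track, params)
    mask = eligible_windows(track, lam, params.window_pvalue)
    candidates = aggregate_islands(mask, track, params, lam)
    if not candidates:
        return []
    s_star = score_threshold(params, lam, track.n_windows)
    called = [isl for isl in candidates if isl.score >= s_star - 1e-12]
    logger.info(
        "called %d islands of %d candidates (lambda=%.4f, threshold=%.2f)",
        len(called), len(candidates), lam, s_star,
    )
    return called


def _overlap_flags(a: list[Island], b: list[Island]) -> tuple[np.ndarray, list[tuple[Island, Island]]]:
    """For each island in a: does it overlap any island in b (>= 1 bp)?"""
    flags = np.zeros(len(a), dtype=bool)
    pairs: list[tuple[Island, Island]] = []
    by_chrom: dict[str, list[tuple[int, Island]]] = {}
    for j, isl in enumerate(b):
        by_chrom.setdefault(isl.chrom, []).append((j, isl))
    for i, isl in enumerate(a):
        for _, other in by_chrom.get(isl.chrom, []):
            if other.start < isl.end and isl.start < other.end:
                flags[i] = True
                pairs.append((isl, other))
    return flags, pairs


def compare_conditions(islands_a: list[Island], islands_b: list[Island]) -> PeakComparison:
    """Shared/unique peak accounting between two conditions.

    An island is shared when it overlaps (>= 1 bp) any island of the other
    condition; shared counts need not match between conditions because one
    broad island can overlap several narrow ones.
    """
    flags_a, pairs = _overlap_flags(islands_a, islands_b)
    flags_b, _ = _overlap_flags(islands_b, islands_a)
    shared_a = int(flags_a.sum())
    shared_b = int(flags_b.sum())
    return PeakComparison(
        total_a=len(islands_a),
        total_b=len(islands_b),
        shared_a=shared_a,
        shared_b=shared_b,
        unique_a=len(islands_a) - shared_a,
        unique_b=len(islands_b) - shared_b,
        pairings=pairs,
    )
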