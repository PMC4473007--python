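"""Independent brute-force references used to check the island caller.

Deliberately implemented by a different route than the production code:
eligibility by direct Poisson-tail evaluation per window, island formation by
transitive closure over a pairwise proximity graph (networkx connected
components) instead of a linear scan.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy.stats import poisson


def brute_force_eligibility(counts, lam, p_window=0.20):
    """Per-window eligibility: count has tail probability below p_window."""
    out = []
    for n in counts:
        out.append(n >= 1 and float(poisson.sf(int(n) - 1, lam)) < p_window)
    return out


def brute_force_islands(counts, lam, window_size, gap_size, p_window=0.20):
    """All candidate islands of one chromosome as (start_w, end_w, read_count, score).

    start_w/end_w are inclusive window indices of the first/last eligible
    window of the island.
    """
    counts = list(counts)
    eligible = [i for i, e in enumerate(brute_force_eligibility(counts, lam, p_window)) if e]
    g = gap_size // window_size
    graph = nx.Graph()
    graph.add_nodes_from(eligible)
    for i in eligible:
        for j in eligible:
            if i < j and j - i <= g + 1:
                graph.add_edge(i, j)
    islands = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        w0, w1 = comp[0], comp[-1]
        score = sum(-float(poisson.logsf(counts[i] - 1, lam)) for i in comp)
        islands.append((w0, w1, float(sum(counts[w0 : w1 + 1])), score))
    islands.sort()
    return islands


def monte_carlo_null_island_count(lam, n_windows, threshold, gap_windows, p_window,
                                  n_reps, seed):
    """Empirical mean count of iid-Poisson background islands scoring >= threshold."""
    rng = np.random.default_rng(seed)
    c = 1
    while poisson.sf(c - 1, lam) >= p_window:
        c += 1
    totals = []
    for _ in range(n_reps):
        cnt = rng.poisson(lam, n_windows)
        idx = np.flatnonzero(cnt >= c)
        if idx.size == 0:
            totals.append(0)
            continue
        breaks = np.flatnonzero(np.diff(idx) > gap_windows + 1)
        n = 0
        for grp in np.split(idx, breaks + 1):
            if -poisson.logsf(cnt[grp] - 1, lam).sum() >= threshold - 1e-12:
                n += 1
        totals.append(n)
    return float(np.mean(totals)), float(np.std(totals, ddof=1) / math.sqrt(n_reps))
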