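"""Probe-level expression to gene-level values and expression categories.

A gene's expression is the arithmetic mean of its probes' (log-scale) values.
Genes are then stratified either into ten equal-count deciles by rank (cat1 =
lowest ... cat10 = highest) or into four classes: silent (at/below a floor)
plus equal-count low/medium/high tertiles of the remaining genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def probes_to_genes(
    probe_table: pd.DataFrame, known_genes: list[str] | None = None
) -> pd.DataFrame:
    """Average probe values per gene.

    ``probe_table`` needs columns ``probe_id, gene_id, value``.  Genes with no
    probe are simply absent from the result.  If ``known_genes`` is given,
    probes mapping outside it raise an error listing the offenders.
    """
    for col in ("probe_id", "gene_id", "value"):
        if col not in probe_table.columns:
            raise ValueError(f"probe table is missing column {col!r}")
    if probe_table["probe_id"].duplicated().any():
        raise ValueError("probe_ids must be unique (each probe maps to at most one gene)")
    if known_genes is not None:
        unknown = sorted(set(probe_table["gene_id"]) - set(known_genes))
        if unknown:
            raise ValueError(f"probes map to unknown genes: {unknown}")
    out = (
        probe_table.groupby("gene_id", sort=True)["value"]
        .mean()
        .reset_index()
    )
    return out


def _ranked(gene_table: pd.DataFrame) -> pd.DataFrame:
    # deterministic total order: by value, then gene_id
    return gene_table.sort_values(["value", "gene_id"], kind="mergesort").reset_index(drop=True)


def assign_categories(
    gene_table: pd.DataFrame,
    scheme: str = "deciles",
    silent_floor: float | None = None,
    silent_percentile: float = 0.25,
) -> pd.DataFrame:
    """Attach an expression category column to a gene-level table.

    ``scheme='deciles'``: ranks split into 10 near-equal groups (cat1..cat10,
    sizes differing by at most one).  ``scheme='four'``: genes at/below the
    silent floor are 'silent' (floor defaults to the ``silent_percentile``
    quantile of values) and the rest split into equal-count low/medium/high.
    Categories are rank-based, hence invariant under any strictly monotone
    transform of the values.
    """
    if gene_table.empty:
        raise ValueError("gene table is empty")
    df = _ranked(gene_table)
    if scheme == "deciles":
        if len(df) < 10:
            raise ValueError("decile scheme needs at least 10 genes")
        parts = np.array_split(np.arange(len(df)), 10)
        decile = np.empty(len(df), dtype=int)
        for d, idx in enumerate(parts, start=1):
            decile[idx] = d
        df["decile"] = decile
    elif scheme == "four":
        if silent_floor is None:
            silent_floor = float(df["value"].quantile(silent_percentile))
        silent = df["value"].to_numpy() <= silent_floor
        if silent.all():
            raise ValueError("all genes are silent under the four-category scheme")
        df["category4"] = "silent"
        rest = np.flatnonzero(~silent)  # already rank-ordered
        labels = ["low", "medium", "high"]
        for lab, idx in zip(labels, np.array_split(rest, 3)):
            df.loc[idx, "category4"] = lab
    else:
        raise ValueError(f"unknown categorization scheme {scheme!r}")
    return df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
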