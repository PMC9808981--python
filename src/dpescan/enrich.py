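"""Exon-to-gene mapping and hypergeometric over-representation analysis.

Gene-set enrichment of a signature gene list is tested against user-supplied
GMT collections with a one-sided hypergeometric upper-tail p-value (the
classical ORA statistic), followed by BH-FDR across sets.  The default
universe is every gene in the exon catalog.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .dpe_stats import bh_adjust
from .types import ExonCatalog, GeneSet


def map_exons_to_genes(exons: Iterable[str], catalog: ExonCatalog) -> set[str]:
    """Distinct gene ids of the given exon ids (errors on unknown exons)."""
    exons = list(exons)
    if not exons:
        return set()
    return catalog.genes_of(exons)


def ora_test(
    gene_list: set[str], sets: list[GeneSet], universe: set[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For a list of n genes drawn from a universe of N genes of which K belong
    to the set, the p-value is P(X >= k) with k the observed overlap.
    Sets are intersected with the universe before testing.  Returns a table
    sorted by p with BH-FDR across sets.
    """
    if not universe:
        raise ValueError("empty gene universe")
    stray = gene_list - universe
    if stray:
        raise ValueError(f"gene list contains genes outside the universe: {sorted(stray)[:10]}")
    N = len(universe)
    n = len(gene_list)
    rows = []
    for gs in sets:
        members = gs.members & universe
        if not members:
            continue
        overlap = gene_list & members
        k, K = len(overlap), len(members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "set_name": gs.name,
                "overlap": k,
                "set_size": K,
                "list_size": n,
                "universe_size": N,
                "p_value": min(p, 1.0),
                "genes": ",".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(rows, columns=[
        "set_name", "overlap", "set_size", "list_size", "universe_size", "p_value", "genes",
    ])
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = []
    return df
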