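"""Hypergeometric over-representation of target-gene sets against pathways.

A generic stand-in for web-based enrichment services: upper-tail
hypergeometric p per term, BH correction across tested terms, and log10
reporting (count, percent of query, Log10(P), Log10(q)). The universe is the
supplied background gene table, not the genome.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    terms: Mapping[str, set],
    descriptions: Mapping[str, str] | None = None,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Over-representation of ``query`` within ``universe`` against ``terms``.

    For each term with overlap >= ``min_overlap``: p = P(X >= overlap) for X
    hypergeometric(|universe|, |term ∩ universe|, |query|). Results are BH-
    corrected across tested terms and sorted by ascending p.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    descriptions = descriptions or {}
    big_m = len(universe)
    big_n = len(query)
    rows = []
    for term_id in sorted(terms):
        term = set(terms[term_id]) & universe
        count = len(term & query)
        if count < min_overlap or not term:
            continue
        p = float(stats.hypergeom.sf(count - 1, big_m, len(term), big_n))
        rows.append(
            {
                "term_id": term_id,
                "description": descriptions.get(term_id, term_id),
                "count": count,
                "percent": round(100.0 * count / big_n, 2),
                "pvalue": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "description", "count", "percent",
                     "pvalue", "qvalue", "log10_p", "log10_q"]
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    tiny = np.finfo(float).tiny
    out["log10_p"] = np.log10(np.maximum(out["pvalue"], tiny))
    out["log10_q"] = np.log10(np.maximum(out["qvalue"], tiny))
    return out.sort_values(["pvalue", "term_id"]).reset_index(drop=True)


def targets_of_region_mirnas(
    region_mirnas: Iterable[str],
    edges: pd.DataFrame,
    down_genes: Iterable[str],
) -> set[str]:
    """Union of predicted targets of in-region miRNAs, restricted to the
    supplied down-regulated gene set."""
    region_mirnas = set(region_mirnas)
    down_genes = set(down_genes)
    if not len(edges):
        return set()
    mirna_edges = edges[edges["relation"].isin(("miRNA-gene", "miRNA-TF"))]
    hit = mirna_edges[mirna_edges["source"].isin(region_mirnas)]
    return set(hit["target"]) & down_genes
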