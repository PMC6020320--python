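"""Hypergeometric over-representation of gene sets in module gene lists.

The background is the set of genes that entered the network (all expressed
genes in the group), not the genome; each candidate set is intersected with
the background before testing, and BH correction is applied across sets
within each module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from ._stats import bh_fdr

__all__ = ["EnrichmentResult", "hypergeom_overrep", "enrich_modules"]

log = logging.getLogger(__name__)

MIN_SET_SIZE = 3  # sets smaller than this after background intersection are skipped


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int  # k
    set_size_in_background: int  # K
    query_size: int  # n
    background_size: int  # N
    p_value: float
    q_value: float = float("nan")


def hypergeom_overrep(query_genes, gene_set, background_genes, set_name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric test, p = P(X >= k | N, K, n)."""
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    members = set(gene_set) & background
    k = len(query & members)
    N, K, n = len(background), len(members), len(query)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        set_name=set_name,
        overlap=k,
        set_size_in_background=K,
        query_size=n,
        background_size=N,
        p_value=min(p, 1.0),
    )


def enrich_modules(
    module_genes: dict[str, list[str]],
    gene_sets: dict[str, set[str]],
    background_genes,
    fdr: float = 0.05,
    min_set_size: int = MIN_SET_SIZE,
) -> pd.DataFrame:
    """Test every set against every module; BH across sets within module.

    Returns the full table with a ``significant`` flag at ``q <= fdr``.
    """
    background = set(background_genes)
    rows = []
    for module, genes in module_genes.items():
        results = []
        for name, members in gene_sets.items():
            if len(set(members) & background) < min_set_size:
                log.info("skipping set %s (< %d genes in background)", name, min_set_size)
                continue
            results.append(hypergeom_overrep(genes, members, background, set_name=name))
        if not results:
            continue
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            rows.append(
                {
                    "module": module,
                    "set_name": r.set_name,
                    "overlap": r.overlap,
                    "set_size": r.set_size_in_background,
                    "query_size": r.query_size,
                    "background_size": r.background_size,
                    "p_value": r.p_value,
                    "q_value": float(qv),
                    "significant": bool(qv <= fdr),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "module", "set_name", "overlap", "set_size", "query_size",
            "background_size", "p_value", "q_value", "significant",
        ],
    )
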