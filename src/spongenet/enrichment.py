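"""Generic over-representation analysis of gene lists.

Each gene set from a GMT collection is tested for overlap with a query
list by the hypergeometric upper tail against a declared gene universe;
p-values are Benjamini–Hochberg adjusted within the collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io_core import SpongenetError


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    adj_p_value: float


def hypergeom_tail(overlap: int, universe: int, set_size: int,
                   query_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, query_size)."""
    return float(min(1.0, stats.hypergeom.sf(overlap - 1, universe,
                                             set_size, query_size)))


def ora(query: set[str], universe: set[str],
        collections: dict[str, set[str]], min_set: int = 5,
        max_set: int = 5000) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each collection set.

    Sets are intersected with the universe first; sets whose effective
    size falls outside [min_set, max_set] are skipped.  Results are BH
    adjusted across all tested sets and sorted by adjusted p.
    """
    if not query:
        raise SpongenetError("empty query gene list")
    stray = query - universe
    if stray:
        raise SpongenetError(f"query genes outside universe: {sorted(stray)[:5]}")
    if not collections:
        return []
    n_u = len(universe)
    n_q = len(query)
    tested = []
    for name in sorted(collections):
        members = collections[name] & universe
        if not min_set <= len(members) <= max_set:
            continue
        overlap = len(members & query)
        p = hypergeom_tail(overlap, n_u, len(members), n_q)
        tested.append((name, overlap, len(members), p))
    if not tested:
        return []
    adj = benjamini_hochberg([t[3] for t in tested])
    results = [EnrichmentResult(name, overlap, size, n_q, n_u, p, float(a))
               for (name, overlap, size, p), a in zip(tested, adj)]
    results.sort(key=lambda r: (r.adj_p_value, r.p_value, r.set_name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"set_name": [r.set_name for r in results],
         "overlap": [r.overlap_count for r in results],
         "set_size": [r.set_size for r in results],
         "query_size": [r.query_size for r in results],
         "universe_size": [r.universe_size for r in results],
         "p": [r.p_value for r in results],
         "adj_p": [r.adj_p_value for r in results]})
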