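"""Network topology: power-law fitting, SC-cutoff scanning, Markov
clustering, and hub extraction.

The degree distribution of a putative scale-free network is fitted as
P(k) = a * k^b by least squares on (log10 k, log10 P(k)) over observed
degrees — the convention of Cytoscape's Network Analyzer, whose R^2 is
the coefficient of determination of that log-log regression.  The SC
cutoff for the sponge network is chosen as the grid value maximising
that R^2 (ties resolved toward the larger, i.e. stricter, cutoff).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (ExpressionMatrix, InteractionSet, SpongenetError,
                      logger)
from .sponge_network import SpongeEdge, infer_sponge_network


@dataclass
class PowerLawFit:
    coefficient_a: float
    exponent_b: float
    r_squared: float
    histogram: dict[int, int] = field(default_factory=dict)


@dataclass
class SpongeModule:
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


def degree_histogram(edges: list[tuple[str, str]]) -> dict[int, int]:
    deg = Counter()
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    hist = Counter(deg.values())
    return dict(sorted(hist.items()))


def fit_power_law(degrees: list[int] | dict[int, int]) -> PowerLawFit:
    """Least-squares log10-log10 fit of node count against degree.

    ``degrees`` is either the multiset of node degrees or a prebuilt
    histogram {degree: node count}.  At least 3 distinct positive degrees
    are required; fewer is a degenerate distribution (hard error).
    """
    hist = (dict(degrees) if isinstance(degrees, dict)
            else dict(Counter(degrees)))
    hist = {k: v for k, v in sorted(hist.items()) if k >= 1 and v > 0}
    if len(hist) < 3:
        raise SpongenetError("degenerate degree distribution: "
                             f"{len(hist)} distinct degrees (need >= 3)")
    x = np.log10(np.array(list(hist.keys()), dtype=float))
    y = np.log10(np.array(list(hist.values()), dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawFit(float(10 ** intercept), float(slope), float(r2), hist)


def sc_grid_values(low: float, high: float, step: float) -> list[float]:
    n = int(round((high - low) / step)) + 1
    return [round(low + i * step, 10) for i in range(n)]


def scan_sc_cutoff(expr_by_class: dict[str, ExpressionMatrix],
                   mirna_expr: ExpressionMatrix,
                   targets: InteractionSet,
                   grid: tuple[float, float, float] = (0.1, 0.3, 0.05),
                   p_share_max: float = 0.05,
                   p_corr_max: float = 0.05,
                   min_shared: int = 1
                   ) -> tuple[pd.DataFrame, float, dict[float, list[SpongeEdge]]]:
    """Sponge networks across an SC-cutoff grid, scored by power-law R^2.

    Returns the scan table (cutoff, edge count, a, b, R^2), the selected
    cutoff (argmax R^2, ties to the larger cutoff), and the per-cutoff
    edge lists.  Degenerate networks get NaN R^2 and are skipped by the
    argmax; all cutoffs degenerate is a hard error.
    """
    cutoffs = sc_grid_values(*grid)
    # infer once at the loosest cutoff, then threshold on SC
    base = infer_sponge_network(expr_by_class, mirna_expr, targets,
                                p_share_max, p_corr_max,
                                sc_min=min(cutoffs), min_shared=min_shared)
    rows = []
    networks: dict[float, list[SpongeEdge]] = {}
    best: tuple[float, float] | None = None
    for c in cutoffs:
        edges = [e for e in base if e.sc >= c]
        networks[c] = edges
        try:
            fit = fit_power_law(degree_histogram([(e.rna_i, e.rna_j)
                                                  for e in edges]))
            a, b, r2 = fit.coefficient_a, fit.exponent_b, fit.r_squared
        except SpongenetError:
            a = b = r2 = float("nan")
        rows.append({"sc_cutoff": c, "n_edges": len(edges), "a": a, "b": b,
                     "r_squared": r2})
        if not math.isnan(r2) and (best is None or r2 >= best[1]):
            best = (c, r2)
    if best is None:
        raise SpongenetError("all SC cutoffs give degenerate networks")
    return pd.DataFrame(rows), best[0], networks


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(edges: list[tuple[str, str, float]], inflation: float = 2.0,
                min_size: int = 3, self_loops: float = 1.0,
                prune: float = 1e-5, tol: float = 1e-6,
                max_iter: int = 100) -> list[SpongeModule]:
    """Deterministic Markov clustering of an undirected weighted graph.

    The column-stochastic transition matrix (with self-loops) is
    alternately squared (expansion) and elementwise powered and
    renormalised (inflation), pruning entries below ``prune``, until the
    L-infinity change drops under ``tol`` or ``max_iter`` sweeps.
    Clusters are read off the attractor rows; a node attracted by two
    clusters goes to the larger one (ties lexicographic).  Modules below
    ``min_size`` are dropped.
    """
    if inflation <= 1:
        raise SpongenetError("inflation must exceed 1")
    nodes = sorted({v for e in edges for v in e[:2]})
    if not nodes:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b, w in edges:
        i, j = idx[a], idx[b]
        M[i, j] = M[j, i] = max(M[i, j], float(w))
    np.fill_diagonal(M, self_loops)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        new = M @ M                    # expansion
        new = new ** inflation         # inflation
        new[new < prune] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if np.abs(new - M).max() < tol:
            M = new
            converged = True
            break
        M = new
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)
    # attractors have positive mass on their own column
    attractors = [i for i in range(n) if M[i, i] > tol]
    raw: list[set[int]] = []
    for a in attractors:
        members = {j for j in range(n) if M[a, j] > tol} | {a}
        merged = False
        for c in raw:
            if c & members:
                c |= members
                merged = True
                break
        if merged:
            # merging can chain clusters together
            changed = True
            while changed:
                changed = False
                for x in range(len(raw)):
                    for y in range(x + 1, len(raw)):
                        if raw[x] & raw[y]:
                            raw[x] |= raw[y]
                            del raw[y]
                            changed = True
                            break
                    if changed:
                        break
        else:
            raw.append(set(members))
    clustered = set().union(*raw) if raw else set()
    for j in range(n):                 # orphans join their strongest attractor
        if j not in clustered:
            masses = [(M[a, j], a) for a in attractors]
            if masses and max(masses)[0] > 0:
                a = max(masses)[1]
                for c in raw:
                    if a in c:
                        c.add(j)
                        break
            else:
                raw.append({j})
    modules = [SpongeModule(frozenset(nodes[i] for i in c)) for c in raw]
    modules = [m for m in modules if m.size >= min_size]
    modules.sort(key=lambda m: (-m.size, tuple(sorted(m.members))))
    return modules


def select_hubs(edges: list[tuple[str, str]], fraction: float = 0.2,
                node_filter: set[str] | None = None) -> list[str]:
    """Top-``fraction`` of eligible nodes by degree (count = ceiling).

    Ordering is (degree descending, id ascending); ``node_filter``
    restricts eligibility, e.g. to the miRNA side of a bipartite network.
    """
    if not 0 < fraction <= 1:
        raise SpongenetError("fraction must be in (0, 1]")
    deg = Counter()
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    eligible = sorted(v for v in deg if node_filter is None or v in node_filter)
    if not eligible:
        return []
    count = math.ceil(fraction * len(eligible))
    ranked = sorted(eligible, key=lambda v: (-deg[v], v))
    return ranked[:count]
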