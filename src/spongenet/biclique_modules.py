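"""Maximal biclique enumeration on the bipartite miRNA-target network.

A co-regulation module is a biclique: a miRNA set whose every member is
connected to every member of a target set.  Maximal bicliques of a
bipartite graph are exactly the maximal cliques of the auxiliary graph
obtained by completing each side internally, so enumeration is delegated
to the well-tested Bron-Kerbosch implementation in networkx and results
are reported deterministically (size-descending, then lexicographic).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .io_core import InteractionSet


@dataclass
class BicliqueModule:
    mirna_set: frozenset[str]
    target_set: frozenset[str]

    @property
    def size(self) -> tuple[int, int]:
        return (len(self.mirna_set), len(self.target_set))

    def sort_key(self):
        return (-len(self.mirna_set) * len(self.target_set),
                -len(self.mirna_set),
                tuple(sorted(self.mirna_set)), tuple(sorted(self.target_set)))


def enumerate_maximal_bicliques(network: InteractionSet) -> list[BicliqueModule]:
    """All maximal bicliques with both sides non-empty, each exactly once."""
    left = sorted(network.mirnas())
    right = sorted(network.targets())
    if not left or not right:
        return []
    g = nx.Graph()
    # prefix node names: a miRNA and a target may share an identifier
    lmap = {m: ("L", m) for m in left}
    rmap = {t: ("R", t) for t in right}
    g.add_nodes_from(lmap.values())
    g.add_nodes_from(rmap.values())
    for m, t, _ in network.pairs:
        g.add_edge(lmap[m], rmap[t])
    for side in (lmap, rmap):                  # complete each side internally
        nodes = list(side.values())
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                g.add_edge(nodes[i], nodes[j])
    modules = []
    for clique in nx.find_cliques(g):
        ms = frozenset(name for tag, name in clique if tag == "L")
        ts = frozenset(name for tag, name in clique if tag == "R")
        if ms and ts:
            modules.append(BicliqueModule(ms, ts))
    modules.sort(key=BicliqueModule.sort_key)
    return modules


def filter_modules(modules: list[BicliqueModule], min_left: int,
                   min_right: int) -> list[BicliqueModule]:
    """Keep modules with at least ``min_left`` miRNAs and ``min_right``
    targets (the published minimum is 3 and 3)."""
    return [m for m in modules
            if len(m.mirna_set) >= min_left and len(m.target_set) >= min_right]


def top_modules(modules: list[BicliqueModule], n: int) -> list[BicliqueModule]:
    """Largest n modules by |miRNAs| x |targets|, ties by miRNA-side size
    then lexicographic membership."""
    return sorted(modules, key=BicliqueModule.sort_key)[:n]
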