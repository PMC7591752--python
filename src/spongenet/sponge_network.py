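"""miRNA-sponge (ceRNA) interaction inference by sensitivity correlation.

Two RNAs that soak up the same miRNAs compete for them, which couples
their expression.  A candidate pair (lncRNA-lncRNA, lncRNA-mRNA or
mRNA-mRNA) is called a sponge interaction when three constraints hold:

1. the pair shares significantly many miRNA regulators (hypergeometric
   upper-tail test against the miRNA universe);
2. the pair is significantly positively correlated (one-sided t test on
   the Pearson correlation);
3. the sensitivity correlation

       SC = rho_ij - rho_ij|n

   — the drop in Pearson correlation after partialling out the n shared
   miRNAs — is at least a cutoff (0.25 by default, or chosen by the
   degree-distribution scan in :mod:`spongenet.graph_topology`).

Partial correlation conditions jointly on all shared miRNAs via the
precision matrix of the (n+2) x (n+2) correlation matrix, with a
pseudoinverse for rank-deficient conditioning sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (ExpressionMatrix, InteractionSet, SpongenetError,
                      logger)

PAIR_CLASSES = ("lncRNA-lncRNA", "lncRNA-mRNA", "mRNA-mRNA")


@dataclass
class SpongeEdge:
    rna_i: str
    rna_j: str
    pair_class: str
    n_shared: int
    p_share: float
    rho_ij: float
    rho_ij_given_n: float
    sc: float
    truncated_conditioning: bool = False

    def __post_init__(self) -> None:
        if self.rna_i > self.rna_j:
            raise SpongenetError("edge endpoints must be stored sorted")


def shared_mirna_test(regulators_i: set[str], regulators_j: set[str],
                      universe_size: int) -> tuple[int, float]:
    """Overlap count and hypergeometric tail P(X >= overlap).

    ``universe_size`` is the number of miRNAs that could regulate either
    RNA; empty regulator sets give (0, 1.0).
    """
    if universe_size < max(len(regulators_i), len(regulators_j)):
        raise SpongenetError("universe smaller than a regulator set")
    n_shared = len(regulators_i & regulators_j)
    if not regulators_i or not regulators_j:
        return 0, 1.0
    p = float(stats.hypergeom.sf(n_shared - 1, universe_size,
                                 len(regulators_i), len(regulators_j)))
    return n_shared, min(p, 1.0)


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        Z: np.ndarray | None) -> float:
    """Pearson correlation of x and y given the rows of Z.

    Computed from the precision matrix of the joint correlation matrix;
    a Moore-Penrose pseudoinverse handles rank-deficient conditioning.
    """
    if Z is None or Z.shape[0] == 0:
        return float(np.corrcoef(x, y)[0, 1])
    data = np.vstack([x, y, Z])
    R = np.corrcoef(data)
    prec = np.linalg.pinv(R)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom == 0:
        return 0.0
    return float(np.clip(-prec[0, 1] / denom, -1.0, 1.0))


def sensitivity_correlation(x_i: np.ndarray, x_j: np.ndarray,
                            Z: np.ndarray | None
                            ) -> tuple[float, float, float, bool]:
    """(rho_ij, rho_ij|n, SC, truncated) for one RNA pair.

    With m samples and n conditioning miRNAs, a full-rank conditioning
    needs m >= n + 3; beyond that the conditioning set is truncated to
    the m - 3 miRNAs most correlated with the pair (product of absolute
    correlations with x_i and x_j), and the edge is flagged.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.std() == 0 or x_j.std() == 0:
        raise SpongenetError("constant expression vector: correlation undefined")
    m = len(x_i)
    truncated = False
    if Z is not None and Z.shape[0] > 0:
        Z = np.asarray(Z, dtype=float)
        keep = Z.std(axis=1) > 0
        Z = Z[keep]
        limit = m - 3
        if Z.shape[0] > limit:
            strength = (np.abs(np.corrcoef(np.vstack([x_i, Z]))[0, 1:]) *
                        np.abs(np.corrcoef(np.vstack([x_j, Z]))[0, 1:]))
            order = np.argsort(-strength)[:max(limit, 0)]
            Z = Z[np.sort(order)]
            truncated = True
            logger.warning("conditioning set truncated to %d miRNAs", Z.shape[0])
    rho = float(np.corrcoef(x_i, x_j)[0, 1])
    if Z is None or Z.shape[0] == 0:
        return rho, rho, 0.0, truncated
    rho_part = partial_correlation(x_i, x_j, Z)
    return rho, rho_part, rho - rho_part, truncated


def positive_correlation_p(rho: float, m: int) -> float:
    """One-sided p-value for H1: rho > 0 via the t transform."""
    if m < 3 or abs(rho) >= 1.0:
        return 0.0 if rho > 0 else 1.0
    t = rho * np.sqrt((m - 2) / (1.0 - rho * rho))
    return float(stats.t.sf(t, m - 2))


def _pair_class(cls_i: str, cls_j: str) -> str:
    order = {"lncRNA": 0, "mRNA": 1}
    a, b = sorted((cls_i, cls_j), key=order.get)
    return f"{a}-{b}"


def candidate_pairs(targets: InteractionSet,
                    gene_classes: dict[str, str],
                    min_shared: int = 1) -> list[tuple[str, str, set[str]]]:
    """Unordered RNA pairs sharing >= ``min_shared`` miRNA regulators."""
    regs = targets.regulators_of()
    genes = sorted(g for g in regs if g in gene_classes)
    out = []
    for gi, gj in itertools.combinations(genes, 2):
        shared = regs[gi] & regs[gj]
        if len(shared) >= min_shared:
            out.append((gi, gj, shared))
    return out


def infer_sponge_network(expr_by_class: dict[str, ExpressionMatrix],
                         mirna_expr: ExpressionMatrix,
                         targets: InteractionSet,
                         p_share_max: float = 0.05,
                         p_corr_max: float = 0.05,
                         sc_min: float = 0.25,
                         min_shared: int = 1) -> list[SpongeEdge]:
    """Apply the three sponge constraints to every candidate pair.

    ``expr_by_class`` maps ``lncRNA``/``mRNA`` to aligned expression
    matrices; ``targets`` supplies the miRNA regulator sets (putative
    interactions by default).  Emitted edges satisfy
    ``p_share < p_share_max``, ``rho > 0`` with one-sided
    ``p < p_corr_max`` and ``SC >= sc_min``.
    """
    gene_classes: dict[str, str] = {}
    rows: dict[str, np.ndarray] = {}
    for cls, em in expr_by_class.items():
        vals = em.values
        for i, g in enumerate(em.gene_ids):
            gene_classes[g] = cls
            rows[g] = vals[i]
    mirna_rows = {g: mirna_expr.values[i]
                  for i, g in enumerate(mirna_expr.gene_ids)}
    universe = len(mirna_expr.gene_ids)
    regs = targets.regulators_of()
    cands = candidate_pairs(targets, gene_classes, min_shared)
    if not cands:
        logger.warning("no candidate sponge pairs share any miRNA regulator")
        return []
    m = next(iter(rows.values())).shape[0]
    edges: list[SpongeEdge] = []
    for gi, gj, shared in cands:
        reg_i = {r for r in regs[gi] if r in mirna_rows}
        reg_j = {r for r in regs[gj] if r in mirna_rows}
        n_shared, p_share = shared_mirna_test(reg_i, reg_j, universe)
        if n_shared < max(min_shared, 1) or p_share >= p_share_max:
            continue
        x_i, x_j = rows[gi], rows[gj]
        if x_i.std() == 0 or x_j.std() == 0:
            logger.warning("skipping pair (%s, %s): constant expression", gi, gj)
            continue
        Z = np.vstack([mirna_rows[r] for r in sorted(reg_i & reg_j)])
        rho, rho_part, sc, trunc = sensitivity_correlation(x_i, x_j, Z)
        if rho <= 0 or positive_correlation_p(rho, m) >= p_corr_max:
            continue
        if sc < sc_min:
            continue
        a, b = sorted((gi, gj))
        edges.append(SpongeEdge(a, b, _pair_class(gene_classes[gi],
                                                  gene_classes[gj]),
                                n_shared, p_share, rho, rho_part, sc, trunc))
    edges.sort(key=lambda e: (e.rna_i, e.rna_j))
    return edges


def sponge_table(edges: list[SpongeEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {"rna_i": [e.rna_i for e in edges],
         "rna_j": [e.rna_j for e in edges],
         "pair_class": [e.pair_class for e in edges],
         "n_shared": [e.n_shared for e in edges],
         "p_share": [e.p_share for e in edges],
         "rho": [e.rho_ij for e in edges],
         "rho_partial": [e.rho_ij_given_n for e in edges],
         "sc": [e.sc for e in edges]})
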