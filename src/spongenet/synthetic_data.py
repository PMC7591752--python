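"""Seeded linear-Gaussian generator of matched expression data with
planted regulation, sponge, and differential-expression structure.

The model: miRNA expressions are iid standard normal across samples; a
regulated target is a linear combination of its miRNA regulators (with
negative loadings — miRNAs repress) plus Gaussian noise, scaled so every
gene has unit variance around a positive baseline.  Under this model the
population Pearson correlation of a miRNA-target pair equals the loading,
and a planted sponge pair (two targets sharing a dedicated miRNA set)
has population sensitivity correlation equal to its shared variance —
both available in closed form, which is what makes recovery testable.

Putative interaction tables mix the true regulations with decoy pairs
(default 10 decoys per true pair) so that validation counts and the
hypergeometric sharing test are non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (ExpressionMatrix, InteractionSet, SpongenetError,
                      write_expression, write_gmt, write_interactions,
                      write_labels)


@dataclass
class SyntheticConfig:
    n_mirna: int = 150
    n_lncrna: int = 50
    n_mrna: int = 150
    m_case: int = 150
    m_control: int = 150
    beta: float = -0.4                 # loading (= population corr) of an ordinary regulation
    noise_sd: float | None = None      # None: residual completes unit variance
    n_sponge_pairs: int = 12
    sponge_sc: float = 0.5             # population SC of planted sponge pairs
    shared_mirnas_per_pair: int = 8
    n_diff_per_class: int = 10
    delta: float = 0.8                 # case-group shift of differential genes
    decoy_ratio: float = 10.0
    baseline_low: float = 4.0
    baseline_high: float = 12.0

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_lncrna, self.n_mrna) <= 0:
            raise SpongenetError("all gene counts must be positive")
        if self.m_case + self.m_control < 20:
            raise SpongenetError("need at least 20 samples in total")


@dataclass
class SyntheticTruth:
    regulation: InteractionSet
    sponge_pairs: list[tuple[str, str, float]]      # (rna_a < rna_b, population SC)
    differential: dict[str, float]                  # gene -> case shift
    rng_seed: int
    optimal_sc_cutoff: float | None = None          # for cutoff-scan fixtures


@dataclass
class SyntheticDataset:
    mirna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mrna: ExpressionMatrix
    putative: dict[str, InteractionSet]             # per target class
    truth: SyntheticTruth
    config: SyntheticConfig
    genesets: dict[str, set[str]] = field(default_factory=dict)

    def expr_by_class(self) -> dict[str, ExpressionMatrix]:
        return {"lncRNA": self.lncrna, "mRNA": self.mrna}

    def putative_union(self) -> InteractionSet:
        return self.putative["lncRNA"].union(self.putative["mRNA"])


def _sample_ids(cfg: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    cases = [f"case_{i:04d}" for i in range(cfg.m_case)]
    controls = [f"ctrl_{i:04d}" for i in range(cfg.m_control)]
    labels = {**{s: "case" for s in cases}, **{s: "control" for s in controls}}
    return cases + controls, labels


def _allocate_loadings(edge_list: list[tuple[int, int, float]], n_nodes: int,
                       budget: float = 0.85, sweeps: int = 200
                       ) -> list[tuple[int, int, float, float]]:
    """Per-endpoint loadings l_u, l_v with l_u*l_v = sc for every edge and
    sum of squared loadings <= budget at every node.

    Iterative proportional rebalancing; infeasible demands (a node whose
    edges cannot all fit, e.g. sc close to 1 on a hub) raise a hard error
    reporting the attainable bound.
    """
    lu = [float(np.sqrt(sc)) for _, _, sc in edge_list]
    lv = [float(np.sqrt(sc)) for _, _, sc in edge_list]
    for _ in range(sweeps):
        worst = 0.0
        for node in range(n_nodes):
            s = sum(lu[k] ** 2 for k, (u, _, _) in enumerate(edge_list) if u == node)
            s += sum(lv[k] ** 2 for k, (_, v, _) in enumerate(edge_list) if v == node)
            worst = max(worst, s)
            if s > budget:
                f = float(np.sqrt(budget / s)) * 0.999
                for k, (u, v, _) in enumerate(edge_list):
                    if u == node:
                        lu[k] *= f
                        lv[k] /= f
                    elif v == node:
                        lv[k] *= f
                        lu[k] /= f
        if worst <= budget:
            break
    else:
        raise SpongenetError(
            "infeasible sponge SC demands: a node needs summed shared "
            f"variance {worst:.3f} but at most {budget} is attainable")
    return [(u, v, lu[k], lv[k]) for k, (u, v, _) in enumerate(edge_list)]


def generate(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Build a full matched dataset with planted structure.

    Layout of the planted structure:

    * the first ``2 * n_sponge_pairs`` lncRNA/mRNA slots host the sponge
      pair members (pair classes cycle lncRNA-lncRNA, lncRNA-mRNA,
      mRNA-mRNA); each pair loads on its own dedicated block of
      ``shared_mirnas_per_pair`` miRNAs with loading -sqrt(sc/s);
    * every remaining target gets one ordinary miRNA regulator with
      loading ``beta`` (round-robin over the non-dedicated miRNAs);
    * ``n_diff_per_class`` unregulated genes per class are shifted by
      ``delta`` in the case group.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    if not -1 < cfg.beta < 1:
        raise SpongenetError("beta must lie in (-1, 1): it is a correlation "
                             "under the unit-variance model")
    s = cfg.shared_mirnas_per_pair
    if cfg.n_sponge_pairs > 0:
        if not 0 <= cfg.sponge_sc < 0.95:
            raise SpongenetError(
                f"infeasible sponge SC {cfg.sponge_sc}: attainable range is "
                "[0, 0.95) under the unit-variance linear model")
        if cfg.n_sponge_pairs * s > cfg.n_mirna:
            raise SpongenetError("not enough miRNAs for dedicated shared sets")

    mirna_ids = [f"miR-{i:04d}" for i in range(cfg.n_mirna)]
    lnc_ids = [f"LNC{i:04d}" for i in range(cfg.n_lncrna)]
    mrna_ids = [f"GENE{i:04d}" for i in range(cfg.n_mrna)]
    target_ids = lnc_ids + mrna_ids
    t_class = {**{g: "lncRNA" for g in lnc_ids}, **{g: "mRNA" for g in mrna_ids}}
    samples, labels = _sample_ids(cfg)
    m = len(samples)

    Z = rng.standard_normal((cfg.n_mirna, m))
    q = len(target_ids)
    loadings = np.zeros((q, cfg.n_mirna))
    t_index = {g: i for i, g in enumerate(target_ids)}

    # --- sponge pairs on dedicated miRNA blocks -------------------------
    # topology mixes a 3-star, a 2-edge path and disjoint pairs so the
    # sponge network has several distinct degrees (a power-law fit needs
    # at least three); star edges carry a slightly lower SC because a
    # degree-3 node cannot host three full-strength shared components.
    sponge_pairs: list[tuple[str, str, float]] = []
    used_targets: set[str] = set()
    if cfg.n_sponge_pairs > 0:
        pools = {"lncRNA": list(lnc_ids), "mRNA": list(mrna_ids)}
        cycle = ["lncRNA", "mRNA"]

        def take(i: int) -> str:
            pool = pools[cycle[i % 2]] or pools[cycle[(i + 1) % 2]]
            if not pool:
                raise SpongenetError("not enough targets for sponge pairs")
            g = pool.pop(0)
            used_targets.add(g)
            return g

        edge_spec: list[tuple[str, str, float]] = []
        ticket = 0
        if cfg.n_sponge_pairs >= 6:
            hub = take(ticket); ticket += 1
            for _ in range(3):
                p_ = take(ticket); ticket += 1
                edge_spec.append((hub, p_, 0.8 * cfg.sponge_sc))
            p1, p2, p3 = take(ticket), take(ticket + 1), take(ticket + 2)
            ticket += 3
            edge_spec.append((p1, p2, cfg.sponge_sc))
            edge_spec.append((p2, p3, cfg.sponge_sc))
        while len(edge_spec) < cfg.n_sponge_pairs:
            a_, b_ = take(ticket), take(ticket + 1)
            ticket += 2
            edge_spec.append((a_, b_, cfg.sponge_sc))
        alloc = _allocate_loadings(
            [(t_index[a_], t_index[b_], sc) for a_, b_, sc in edge_spec], q)
        for k, ((ia, ib, la, lb), (a_, b_, sc)) in enumerate(zip(alloc, edge_spec)):
            block = list(range(k * s, (k + 1) * s))
            loadings[ia, block] = -la / np.sqrt(s)
            loadings[ib, block] = -lb / np.sqrt(s)
            a_, b_ = sorted((a_, b_))
            sponge_pairs.append((a_, b_, float(sc)))

    # --- reserve differential genes: unregulated, shifted in cases ------
    diff_mirnas = [g for g in mirna_ids[cfg.n_sponge_pairs * s:]
                   ][-cfg.n_diff_per_class:] if cfg.n_diff_per_class else []
    diff_targets = []
    for ids in (lnc_ids, mrna_ids):
        free = [g for g in ids if g not in used_targets]
        diff_targets.extend(free[-cfg.n_diff_per_class:]
                            if cfg.n_diff_per_class else [])
    reserved = set(diff_mirnas) | set(diff_targets)

    # --- ordinary one-regulator targets ---------------------------------
    ordinary_mirnas = [i for i in range(cfg.n_sponge_pairs * s, cfg.n_mirna)
                       if mirna_ids[i] not in reserved]
    if not ordinary_mirnas:
        ordinary_mirnas = [i for i in range(cfg.n_mirna)
                           if mirna_ids[i] not in reserved] or list(range(cfg.n_mirna))
    j = 0
    for g in target_ids:
        if g in used_targets or g in reserved or cfg.beta == 0:
            continue
        loadings[t_index[g], ordinary_mirnas[j % len(ordinary_mirnas)]] = cfg.beta
        j += 1

    # --- expression values ----------------------------------------------
    explained = (loadings ** 2).sum(axis=1)
    if cfg.noise_sd is None:
        if (explained >= 1).any():
            raise SpongenetError("loadings leave no room for noise; lower "
                                 "beta or sponge_sc (explained variance "
                                 f"up to {explained.max():.3f}, bound 1)")
        sigma = np.sqrt(1.0 - explained)
    else:
        sigma = np.full(q, float(cfg.noise_sd))
    T = loadings @ Z + sigma[:, None] * rng.standard_normal((q, m))

    base_m = rng.uniform(cfg.baseline_low, cfg.baseline_high, cfg.n_mirna)
    base_t = rng.uniform(cfg.baseline_low, cfg.baseline_high, q)
    Zb = Z + base_m[:, None]
    Tb = T + base_t[:, None]

    # --- differential genes ----------------------------------------------
    differential: dict[str, float] = {}
    case_mask = np.array([labels[s_] == "case" for s_ in samples])
    for g in diff_mirnas:
        differential[g] = cfg.delta
        Zb[mirna_ids.index(g)] += cfg.delta * case_mask
    for g in diff_targets:
        differential[g] = cfg.delta
        Tb[t_index[g]] += cfg.delta * case_mask

    # --- interaction tables ----------------------------------------------
    truth_pairs = {(mirna_ids[k], g, t_class[g])
                   for i, g in enumerate(target_ids)
                   for k in np.flatnonzero(loadings[i])}
    n_decoys = int(round(cfg.decoy_ratio * len(truth_pairs)))
    all_possible = [(mi, g) for mi in mirna_ids for g in target_ids
                    if (mi, g, t_class[g]) not in truth_pairs]
    pick = rng.choice(len(all_possible), size=min(n_decoys, len(all_possible)),
                      replace=False)
    decoy_pairs = {(all_possible[i][0], all_possible[i][1],
                    t_class[all_possible[i][1]]) for i in pick}
    putative = {}
    for cls in ("lncRNA", "mRNA"):
        putative[cls] = InteractionSet(
            {p for p in truth_pairs | decoy_pairs if p[2] == cls},
            provenance=f"synthetic putative {cls}")

    truth = SyntheticTruth(
        regulation=InteractionSet(truth_pairs, provenance="synthetic truth"),
        sponge_pairs=sorted(sponge_pairs),
        differential=differential,
        rng_seed=seed)

    def _em(ids, mat, cls):
        df = pd.DataFrame(mat, index=ids, columns=samples)
        return ExpressionMatrix(df, cls, dict(labels))

    genesets = _genesets(rng, sponge_pairs, mrna_ids)
    return SyntheticDataset(_em(mirna_ids, Zb, "miRNA"),
                            _em(lnc_ids, Tb[: cfg.n_lncrna], "lncRNA"),
                            _em(mrna_ids, Tb[cfg.n_lncrna:], "mRNA"),
                            putative, truth, cfg, genesets)


def _genesets(rng: np.random.Generator, sponge_pairs, mrna_ids,
              n_random: int = 12, set_size: int = 15) -> dict[str, set[str]]:
    """A small GMT-style collection: one set holding the sponge-pair
    members (planted signal) plus random mRNA sets."""
    sets: dict[str, set[str]] = {}
    members = {g for a, b, _ in sponge_pairs for g in (a, b)}
    if members:
        sets["planted_sponge_members"] = members
    for i in range(n_random):
        chosen = rng.choice(len(mrna_ids), size=min(set_size, len(mrna_ids)),
                            replace=False)
        sets[f"random_set_{i:02d}"] = {mrna_ids[j] for j in chosen}
    return sets


# ---------------------------------------------------------------------------
# special-purpose fixtures
# ---------------------------------------------------------------------------

def cutoff_scan_dataset(seed: int, m_samples: int = 20000,
                        mirnas_per_edge: int = 3) -> SyntheticDataset:
    """A sponge network whose power-law fit is best at SC cutoff 0.25.

    Three edge tiers by planted SC: a strong tier (SC 0.45) of six
    disjoint edges, a backbone tier (SC 0.275) completing an exactly
    log-log-collinear degree histogram {1:16, 2:4, 4:1}, and a noise tier
    (SC 0.175) forming a random graph on extra nodes.  At cutoffs 0.10
    and 0.15 the noise edges spoil the fit; at 0.20 and 0.25 the full
    backbone gives R^2 = 1 (the tie resolves to the stricter 0.25); at
    0.30 only the strong tier survives, whose single distinct degree is a
    degenerate distribution, so 0.25 is the scan's optimum.
    """
    rng = np.random.default_rng(seed)
    nodes: list[str] = []

    def new_node(tag: str) -> str:
        nodes.append(f"{tag}{len(nodes):03d}")
        return nodes[-1]

    edges: list[tuple[str, str, float]] = []
    center = new_node("GENE")
    for _ in range(4):
        mid = new_node("LNC")
        leaf = new_node("GENE")
        edges.append((center, mid, 0.275))
        edges.append((mid, leaf, 0.275))
    for _ in range(6):
        a, b = new_node("GENE"), new_node("LNC")
        edges.append((a, b, 0.45))
    noise_nodes = [new_node("GENE") for _ in range(14)]
    perm = rng.permutation(len(noise_nodes))
    for i in range(0, len(noise_nodes) - 1, 2):
        a, b = noise_nodes[perm[i]], noise_nodes[perm[i + 1]]
        edges.append((*sorted((a, b)), 0.175))
    extra = rng.choice(len(noise_nodes), size=(4, 2))
    for a_i, b_i in extra:
        a, b = noise_nodes[a_i], noise_nodes[b_i]
        if a != b and not any({a, b} == {u, v} for u, v, _ in edges):
            edges.append((*sorted((a, b)), 0.175))

    idx = {g: i for i, g in enumerate(nodes)}
    alloc = _allocate_loadings([(idx[u], idx[v], sc) for u, v, sc in edges],
                               len(nodes))
    # inert extra miRNAs keep the sharing universe large enough that a
    # degree-4 hub's 12 putative regulators still test as significant
    n_mirna = mirnas_per_edge * len(edges) + 120
    Z = rng.standard_normal((n_mirna, m_samples))
    mirna_ids = [f"miR-{i:04d}" for i in range(n_mirna)]
    loadings = np.zeros((len(nodes), n_mirna))
    truth_pairs = set()
    sponge_pairs = []
    for k, ((ui, vi, lu, lv), (u, v, sc)) in enumerate(zip(alloc, edges)):
        block = list(range(k * mirnas_per_edge, (k + 1) * mirnas_per_edge))
        per = 1.0 / np.sqrt(mirnas_per_edge)
        loadings[ui, block] = -lu * per
        loadings[vi, block] = -lv * per
        for g, gi in ((u, ui), (v, vi)):
            cls = "lncRNA" if g.startswith("LNC") else "mRNA"
            truth_pairs.update((mirna_ids[b], g, cls) for b in block)
        sponge_pairs.append((*sorted((u, v)), float(sc)))
    explained = (loadings ** 2).sum(axis=1)
    sigma = np.sqrt(1.0 - explained)
    T = loadings @ Z + sigma[:, None] * rng.standard_normal((len(nodes), m_samples))

    half = m_samples // 2
    cfg = SyntheticConfig(n_mirna=n_mirna,
                          n_lncrna=sum(g.startswith("LNC") for g in nodes),
                          n_mrna=sum(g.startswith("GENE") for g in nodes),
                          m_case=half, m_control=m_samples - half,
                          n_sponge_pairs=len(edges), sponge_sc=0.0,
                          shared_mirnas_per_pair=0, n_diff_per_class=0,
                          decoy_ratio=0.0)
    samples, labels = _sample_ids(cfg)

    def _em(ids, mat, cls):
        return ExpressionMatrix(pd.DataFrame(mat, index=ids, columns=samples),
                                cls, dict(labels))

    lnc_ids = [g for g in nodes if g.startswith("LNC")]
    mrna_ids2 = [g for g in nodes if g.startswith("GENE")]
    order = {g: i for i, g in enumerate(nodes)}
    putative = {cls: InteractionSet({p for p in truth_pairs if p[2] == cls},
                                    provenance="scan fixture")
                for cls in ("lncRNA", "mRNA")}
    truth = SyntheticTruth(
        regulation=InteractionSet(truth_pairs, provenance="scan fixture"),
        sponge_pairs=sorted(sponge_pairs),
        differential={}, rng_seed=seed, optimal_sc_cutoff=0.25)
    return SyntheticDataset(
        _em(mirna_ids, Z + 8.0, "miRNA"),
        _em(lnc_ids, T[[order[g] for g in lnc_ids]] + 8.0, "lncRNA"),
        _em(mrna_ids2, T[[order[g] for g in mrna_ids2]] + 8.0, "mRNA"),
        putative, truth, cfg)


def promise_favoured_dataset(seed: int, n_mirna: int = 10, n_mrna: int = 30,
                             per_mirna: int = 5, m_samples: int = 60
                             ) -> SyntheticDataset:
    """A dataset on which the two-view competition scorer wins validation.

    Every miRNA has ``per_mirna`` true targets whose regulation is too
    weak for correlation or regression methods to separate from noise,
    but the putative candidate table lists exactly the true pairs, so a
    mask-restricted scorer recovers them all.
    """
    cfg = SyntheticConfig(n_mirna=n_mirna, n_lncrna=1, n_mrna=n_mrna,
                          m_case=m_samples // 2,
                          m_control=m_samples - m_samples // 2,
                          beta=-0.05, n_sponge_pairs=0, n_diff_per_class=0,
                          decoy_ratio=0.0)
    rng = np.random.default_rng(seed)
    ds = generate(replace(cfg, beta=0.0), seed)
    # rewire: per_mirna weak regulations per miRNA, putative = truth
    mrna_ids = ds.mrna.gene_ids
    mirna_ids = ds.mirna.gene_ids
    Z = ds.mirna.values - ds.mirna.values.mean(axis=1, keepdims=True)
    T = ds.mrna.values.copy()
    truth_pairs = set()
    for i, mi in enumerate(mirna_ids):
        chosen = rng.choice(len(mrna_ids), size=per_mirna, replace=False)
        for j in chosen:
            T[j] += cfg.beta * Z[i]
            truth_pairs.add((mi, mrna_ids[j], "mRNA"))
    mrna = ExpressionMatrix(pd.DataFrame(T, index=mrna_ids,
                                         columns=ds.mrna.sample_ids),
                            "mRNA", dict(ds.mrna.group_labels))
    putative = {"lncRNA": InteractionSet(set(), provenance="empty"),
                "mRNA": InteractionSet(truth_pairs, provenance="mask")}
    truth = SyntheticTruth(
        regulation=InteractionSet(truth_pairs, provenance="truth"),
        sponge_pairs=[], differential={}, rng_seed=seed)
    return SyntheticDataset(ds.mirna, ds.lncrna, mrna, putative, truth, cfg)


# ---------------------------------------------------------------------------
# presets and writing
# ---------------------------------------------------------------------------

PRESETS: dict[str, SyntheticConfig] = {
    # desk-scale preset exercising every pipeline stage
    "small": SyntheticConfig(),
    # shaped like the published study: 100/300/4000 genes, 104 + 82 samples
    "study-shaped": SyntheticConfig(n_mirna=100, n_lncrna=300, n_mrna=4000,
                                    m_case=104, m_control=82,
                                    n_sponge_pairs=10, shared_mirnas_per_pair=6),
}


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every on-disk artefact (expression, labels, interactions,
    ground truth, gene sets) and return the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_expr": outdir / "mirna_expression.tsv",
        "lncrna_expr": outdir / "lncrna_expression.tsv",
        "mrna_expr": outdir / "mrna_expression.tsv",
        "labels": outdir / "sample_labels.tsv",
        "putative_lncrna": outdir / "putative_mirna_lncrna.tsv",
        "putative_mrna": outdir / "putative_mirna_mrna.tsv",
        "ground_truth": outdir / "validated_interactions.tsv",
        "genesets": outdir / "genesets.gmt",
    }
    write_expression(ds.mirna, paths["mirna_expr"])
    write_expression(ds.lncrna, paths["lncrna_expr"])
    write_expression(ds.mrna, paths["mrna_expr"])
    write_labels(ds.mirna.group_labels, paths["labels"])
    write_interactions(ds.putative["lncRNA"], paths["putative_lncrna"])
    write_interactions(ds.putative["mRNA"], paths["putative_mrna"])
    write_interactions(ds.truth.regulation, paths["ground_truth"])
    write_gmt(ds.genesets, paths["genesets"])
    return paths
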