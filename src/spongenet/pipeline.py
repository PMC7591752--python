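"""End-to-end orchestration: differential selection, target scoring and
validation, network and module construction, sponge inference, hubs and
enrichment, with a reproducibility manifest.

Every stage output is a pure function of (inputs, config, seed): a rerun
with the same manifest inputs reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from . import biclique_modules as bm
from . import diffexpr as de
from . import enrichment as enr
from . import graph_topology as gt
from . import sponge_network as sn
from . import target_inference as ti
from .io_core import (ExpressionMatrix, InteractionSet, PipelineConfig,
                      SpongenetError, align_samples, file_checksum, logger,
                      read_expression, read_gmt, read_interactions,
                      write_edge_list, write_graphml)

try:
    __version__ = version("spongenet")
except PackageNotFoundError:          # running from a source tree
    __version__ = "0.0.0"


@dataclass
class RunResult:
    outdir: Path
    best_method: str
    validation: pd.DataFrame
    target_network: InteractionSet
    biclique_modules: list
    sc_scan: pd.DataFrame
    sc_cutoff: float
    sponge_edges: list
    sponge_modules: list
    hub_mirnas: list[str]
    hub_sponges: list[str]
    manifest: dict = field(default_factory=dict)


def default_small_run_config() -> PipelineConfig:
    """Configuration matched to the small synthetic preset: keep every
    gene at selection, validate at K in {5,10,15,20}, merge top-8
    targets per class, and scan the standard SC grid."""
    return PipelineConfig(
        top_counts={"miRNA": 150, "lncRNA": 50, "mRNA": 150},
        topk_list=[5, 10, 15, 20],
        network_k=8,
        ida_var_budget=250,
        ida_max_cond=2,
    )


def _score_all(methods: list[str], mirna: ExpressionMatrix,
               targets_by_class: dict[str, ExpressionMatrix],
               putative: dict[str, InteractionSet],
               config: PipelineConfig
               ) -> dict[str, dict[str, ti.ScoreMatrix]]:
    scored: dict[str, dict[str, ti.ScoreMatrix]] = {}
    for method in methods:
        scored[method] = {}
        for cls, expr in sorted(targets_by_class.items()):
            logger.info("scoring %s / %s (%d x %d)", method, cls,
                        len(mirna.gene_ids), len(expr.gene_ids))
            if method in ti.CORRELATION_METHODS:
                sm = ti.score_correlation(method, mirna, expr, config)
            elif method in ti.REGRESSION_METHODS:
                sm = ti.score_regression(method, mirna, expr, config)
            elif method == "ida":
                sm = ti.score_ida(mirna, expr, config.ida_alpha, config)
            elif method == "zscore":
                sm = ti.score_zscore(mirna, expr)
            elif method == "promise":
                sm, _ = ti.score_promise(mirna, expr, putative[cls])
            else:
                raise SpongenetError(f"unknown method {method!r}")
            scored[method][cls] = sm
    return scored


def run_all(config: PipelineConfig,
            mirna_expr_path: str | Path,
            lncrna_expr_path: str | Path,
            mrna_expr_path: str | Path,
            labels_path: str | Path,
            putative_lncrna_path: str | Path,
            putative_mrna_path: str | Path,
            ground_truth_path: str | Path,
            outdir: str | Path,
            gmt_path: str | Path | None = None,
            methods: list[str] | None = None) -> RunResult:
    """Execute the three-step protocol and write all stage outputs.

    Step 1: differential selection, 12-method scoring, validation against
    the ground truth, best-method network and biclique modules.
    Step 2: SC-cutoff scan, sponge network at the selected cutoff, MCL
    sponge modules.  Step 3: hubs and (if a GMT is given) enrichment.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    methods = list(methods) if methods else list(ti.ALL_METHODS)
    inputs = {
        "mirna_expr": str(mirna_expr_path), "lncrna_expr": str(lncrna_expr_path),
        "mrna_expr": str(mrna_expr_path), "labels": str(labels_path),
        "putative_lncrna": str(putative_lncrna_path),
        "putative_mrna": str(putative_mrna_path),
        "ground_truth": str(ground_truth_path),
    }
    manifest: dict = {
        "package_version": __version__,
        "seed": config.rng_seed,
        "config": {**asdict(config), "sc_grid": list(config.sc_grid)},
        "input_checksums": {k: file_checksum(v) for k, v in inputs.items()},
        "stages": {},
    }

    # --- read and align ---------------------------------------------------
    mirna = read_expression(mirna_expr_path, "miRNA", labels_path)
    lncrna = read_expression(lncrna_expr_path, "lncRNA", labels_path)
    mrna = read_expression(mrna_expr_path, "mRNA", labels_path)
    mirna, lncrna, mrna = align_samples(mirna, lncrna, mrna)
    putative = {
        "lncRNA": read_interactions(putative_lncrna_path, "lncRNA"),
        "mRNA": read_interactions(putative_mrna_path, "mRNA"),
    }
    truth = (read_interactions(ground_truth_path, "lncRNA")
             .union(read_interactions(ground_truth_path, "mRNA")))

    # --- stage 1: differential expression and selection -------------------
    selected: dict[str, ExpressionMatrix] = {}
    for expr in (mirna, lncrna, mrna):
        res = de.moderated_t(expr)
        de.results_table(res).to_csv(
            outdir / f"dea_{expr.gene_class.lower()}.tsv", sep="\t",
            index=False)
        want = config.top_counts.get(expr.gene_class, len(res))
        if want > len(res):
            logger.warning("top_count %d exceeds %d genes for %s; keeping all",
                           want, len(res), expr.gene_class)
            want = len(res)
        selected[expr.gene_class] = expr.subset_genes(de.select_top(res, want))
    mirna_sel = selected["miRNA"]
    targets_by_class = {"lncRNA": selected["lncRNA"], "mRNA": selected["mRNA"]}
    putative_sel = {
        cls: putative[cls].restrict(mirna_sel.gene_ids,
                                    targets_by_class[cls].gene_ids)
        for cls in targets_by_class}
    manifest["stages"]["selection"] = {
        cls: len(em.gene_ids) for cls, em in selected.items()}

    # --- stage 1: scoring, validation, best method ------------------------
    scored = _score_all(methods, mirna_sel, targets_by_class, putative_sel,
                        config)
    reports = [ti.rank_and_validate(scored[m], truth, k, config.rank_signed)
               for m in methods for k in config.topk_list]
    validation = ti.validation_table(reports)
    validation.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    best = ti.best_method(reports)
    manifest["stages"]["validation"] = {"best_method": best,
                                        "n_reports": len(reports)}

    network = ti.build_target_network(scored[best], config.network_k,
                                      config.rank_signed)
    edge_rows = sorted((m, t, 1.0) for m, t, _ in network.pairs)
    write_edge_list(edge_rows, outdir / "target_network.tsv",
                    header=("mirna", "target", "weight"))
    write_graphml(edge_rows, outdir / "target_network.graphml")
    manifest["stages"]["target_network"] = {"method": best,
                                            "n_edges": len(network)}

    # --- stage 1: biclique modules ----------------------------------------
    modules = bm.filter_modules(bm.enumerate_maximal_bicliques(network),
                                config.min_biclique_left,
                                config.min_biclique_right)
    with open(outdir / "biclique_modules.tsv", "w") as fh:
        fh.write("module_id\tmirnas\ttargets\n")
        for i, mod in enumerate(modules):
            fh.write(f"M{i:04d}\t{';'.join(sorted(mod.mirna_set))}\t"
                     f"{';'.join(sorted(mod.target_set))}\n")
    manifest["stages"]["bicliques"] = {"n_modules": len(modules)}

    # --- stage 2: SC scan and sponge network ------------------------------
    putative_all = putative_sel["lncRNA"].union(putative_sel["mRNA"])
    try:
        scan, chosen, networks = gt.scan_sc_cutoff(
            targets_by_class, mirna_sel, putative_all, config.sc_grid,
            config.p_share, config.p_corr, config.min_shared_mirnas)
    except SpongenetError:
        if config.sc_cutoff is None:
            raise
        logger.warning("SC scan degenerate at every cutoff; "
                       "using configured cutoff %.3f", config.sc_cutoff)
        scan, chosen, networks = pd.DataFrame(), config.sc_cutoff, {}
    scan.to_csv(outdir / "sc_scan.tsv", sep="\t", index=False)
    cutoff = config.sc_cutoff if config.sc_cutoff is not None else chosen
    sponge_edges = networks.get(cutoff)
    if sponge_edges is None:
        sponge_edges = sn.infer_sponge_network(
            targets_by_class, mirna_sel, putative_all, config.p_share,
            config.p_corr, cutoff, config.min_shared_mirnas)
    sn.sponge_table(sponge_edges).to_csv(outdir / "sponge_network.tsv",
                                         sep="\t", index=False)
    write_graphml([(e.rna_i, e.rna_j, e.sc) for e in sponge_edges],
                  outdir / "sponge_network.graphml")
    manifest["stages"]["sponge"] = {"sc_cutoff": cutoff,
                                    "n_edges": len(sponge_edges)}

    sponge_mods = gt.mcl_cluster([(e.rna_i, e.rna_j, e.sc)
                                  for e in sponge_edges],
                                 config.mcl_inflation,
                                 config.min_sponge_module_size)
    with open(outdir / "sponge_modules.tsv", "w") as fh:
        fh.write("module_id\tmembers\n")
        for i, mod in enumerate(sponge_mods):
            fh.write(f"S{i:04d}\t{';'.join(sorted(mod.members))}\n")
    manifest["stages"]["sponge_modules"] = {"n_modules": len(sponge_mods)}

    # --- stage 3: hubs and enrichment -------------------------------------
    target_edges = [(m, t) for m, t, _ in network.pairs]
    hub_mirnas = gt.select_hubs(target_edges, config.hub_fraction,
                                node_filter=set(mirna_sel.gene_ids))
    sponge_pairs = [(e.rna_i, e.rna_j) for e in sponge_edges]
    hub_sponges = gt.select_hubs(sponge_pairs, config.hub_fraction)
    for name, hubs in (("hubs_mirna", hub_mirnas), ("hubs_sponge", hub_sponges)):
        with open(outdir / f"{name}.tsv", "w") as fh:
            fh.write("node\n")
            fh.writelines(f"{h}\n" for h in hubs)
    manifest["stages"]["hubs"] = {"n_hub_mirnas": len(hub_mirnas),
                                  "n_hub_sponges": len(hub_sponges)}

    if gmt_path is not None:
        collections = read_gmt(gmt_path)
        universe = set(selected["lncRNA"].gene_ids) | set(selected["mRNA"].gene_ids)
        query = {g for mod in sponge_mods for g in mod.members} | set(hub_sponges)
        query &= universe
        if query:
            results = enr.ora(query, universe, collections,
                              config.min_set_size, config.max_set_size)
            enr.enrichment_table(results).to_csv(outdir / "enrichment.tsv",
                                                 sep="\t", index=False)
            manifest["stages"]["enrichment"] = {"n_tested": len(results)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(outdir, best, validation, network, modules, scan, cutoff,
                     sponge_edges, sponge_mods, hub_mirnas, hub_sponges,
                     manifest)
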