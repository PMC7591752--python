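# spongenet

Stepwise inference of miRNA-target and miRNA-sponge (ceRNA) networks
and modules from matched miRNA / lncRNA / mRNA expression profiles of a
two-group cohort.

MicroRNAs repress their targets post-transcriptionally, and transcripts
that share miRNA response elements — lncRNAs and mRNAs alike — compete
for the same miRNA pool, coupling their expression ("sponge" or ceRNA
crosstalk). `spongenet` reconstructs both layers from expression data:

1. **Differential selection.** Empirical-Bayes moderated t per gene
   class, BH adjustment, top-N selection (defaults 100 miRNAs, 300
   lncRNAs, 4000 mRNAs).
2. **miRNA-target network.** Twelve expression-based scorers (Pearson,
   Spearman, Kendall, distance correlation, Hoeffding's D, RDC, mutual
   information, Lasso, Elastic-net, IDA causal effects, knockdown
   z-score, and the ProMISe two-view competition model) are benchmarked
   by how many of their per-miRNA top-K predictions (K ∈ {50,100,150,200})
   appear in an experimentally validated ground-truth set; the best
   method's top-K targets are merged into the regulatory network, and
   maximal bicliques with ≥ 3 miRNAs and ≥ 3 targets become
   co-regulation modules.
3. **Sponge network.** A lncRNA/mRNA pair is a sponge interaction when
   it (i) shares significantly many miRNA regulators (hypergeometric,
   p < 0.05), (ii) is significantly positively correlated (one-sided,
   p < 0.05), and (iii) has sensitivity correlation

       SC = ρij − ρij|n  ≥  cutoff,

   the drop in Pearson correlation after partialling out the n shared
   miRNAs. The cutoff is chosen by scanning 0.10–0.30 (step 0.05) and
   keeping the network whose degree distribution best fits a power law
   P(k) = a·k^b (largest R² of the log-log least-squares fit). Markov
   clustering (inflation 2.0) yields sponge modules (≥ 3 members), and
   the top 20% of nodes by degree are reported as hub miRNAs / hub
   sponges. A generic hypergeometric ORA against GMT gene sets covers
   functional analysis.

A seeded linear-Gaussian generator produces matched datasets with
planted regulation, sponge pairs of known population SC, and
differential genes, so the whole pipeline is testable end to end
without downloads.

## Worked example

```python
from spongenet.synthetic_data import PRESETS, generate, write_dataset
from spongenet.pipeline import default_small_run_config, run_all

ds = generate(PRESETS["small"], seed=1)          # 150/50/150 genes, 300 samples
paths = write_dataset(ds, "demo_data")
cfg = default_small_run_config(); cfg.rng_seed = 1
res = run_all(cfg, paths["mirna_expr"], paths["lncrna_expr"],
              paths["mrna_expr"], paths["labels"],
              paths["putative_lncrna"], paths["putative_mrna"],
              paths["ground_truth"], "demo_out",
              gmt_path=paths["genesets"])
print(res.best_method, res.sc_cutoff, len(res.sponge_edges))
```

prints

```
lasso 0.15 18
```

lasso wins the validation benchmark on this dataset (1404 validated
interactions summed over K ∈ {5,10,15,20}, tied with elastic-net and
selected for predicting fewer pairs); the SC scan picks cutoff 0.15,
and the sponge network has 18 edges, containing all 12 planted sponge
pairs. `demo_out/` holds the per-stage tables: differential results,
the validation table, the merged target network (TSV + GraphML),
biclique modules, the SC scan, the sponge network and modules, hubs,
enrichment, and a manifest with config and input checksums — rerunning
with the same seed reproduces every file byte for byte.

The same pipeline is available from the shell:

```bash
spongenet simulate --preset small --seed 1 --out demo_data
spongenet run-all demo_data --small-preset-defaults --out demo_out
```

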