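# coexpnet

Chemical co-expression network analysis for multi-treatment RNA-seq
compendia: from a gene × sample count matrix with matched vehicle controls
to a directed co-expression network, size-ranked modules, hub/bottleneck
centrality, gene neighborhoods, gene-set over-representation, and a
leave-class-out network perturbation analysis with a random-removal null.

A synthetic-data generator with planted, class-specific co-expression
modules (and designated hub genes) makes every stage testable without any
external data.

## Pipeline

1. **simulate** — negative-binomial count compendium; each chemical class
   induces planted gene modules through a shared per-treatment latent
   factor; hubs respond most broadly and consistently (`coexpnet.simulate`).
2. **preprocess** — zero-count filter (genes zero in ≥ 25% of samples
   removed), median-of-ratios normalization, per-treatment NB-Wald
   differential expression vs matched vehicle controls (BH-adjusted within
   comparison), DE-based gene filter (padj < 0.05 in ≥ 3 comparisons),
   log2FC matrix, Ward (D2) treatment clustering (`coexpnet.preprocess`).
   A precomputed DE table can be ingested instead (`--de-table`).
3. **infer** — per-target random-forest regression importances over
   standardized log2FC profiles (1000 trees, √p candidate features per
   split by default; compiled with numba), thresholded into a directed
   edge list at an absolute weight (default 0.00858) or a target edge
   density (`coexpnet.inference`).
4. **analyze** — main weakly-connected component, greedy-modularity
   modules (min size 12, ids ranked by size), directed degree/betweenness
   centrality, direction-blind 1st/2nd-order neighborhoods
   (`coexpnet.graph`).
5. **enrich** — GMT-driven hypergeometric over-representation of module
   gene lists with BH correction (`coexpnet.enrichment`).
6. **perturb** — remove one chemical class's samples, re-infer, and compare
   per-gene-set mean co-expression against the average of ten
   random-removal networks (`coexpnet.perturb`).

## CLI

Each stage is a subcommand; `run-all` drives the whole pipeline from a YAML
config and writes a JSON manifest (parameters, seeds, checksums, per-stage
counts) for reproducibility:

```sh
coexpnet simulate --config sim.yaml --out simdir --seed 1
coexpnet preprocess --counts counts.tsv --samples samples.tsv --out prep
coexpnet infer --fc prep/fc_matrix.tsv --trees 1000 --seed 7 --threshold 0.00858 --out net
coexpnet analyze --edges net/edges.tsv --min-module-size 12 --seed-gene cyp1a --order 2 --out ana
coexpnet enrich --modules ana/modules.tsv --gmt sets.gmt --out enr
coexpnet perturb --counts counts.tsv --samples samples.tsv --gmt sets.gmt --class FRC --iterations 10 --seed 11 --out pert
coexpnet run-all --config run.yaml --set n_trees=500
```

Minimal `run.yaml`:

```yaml
counts: simdir/counts.tsv
samples: simdir/samples.tsv
gmt: sets.gmt            # optional; enrichment/perturbation skipped if absent
outdir: run
min_weight: 0.00858      # or: min_weight: null + top_density: 8.0
perturb_classes: [FRC, AHR2_Activator]
seed: 7
```

Edge lists are also written as Cytoscape SIF. Exit codes: 0 ok, 1 user
error, 2 internal error.

## File formats

- counts: TSV, rows = genes, columns = samples, first column `gene`
- sample sheet: TSV with `sample, treatment, control_for, class, replicate`;
  control groups have class `control` and empty `control_for`
- DE table: TSV with `gene, treatment, log2fc, p, padj`
- gene sets: standard GMT (name, description, members; tab-separated)
- networks: edge TSV (`regulator, target, weight`) and SIF
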