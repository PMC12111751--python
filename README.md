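# integromod

Integrative multi-omics discovery of disease-associated gene modules on
protein–protein interaction (PPI) networks.

`integromod` is for systems-biology analysts who have gene-level GWAS
association statistics, case/control DNA-methylation (450K-style beta
values) and/or case/control gene expression, and want to find dense,
disease-loaded subnetworks of the interactome. It implements the dense
module searching (DMS) family of greedy seed-and-expand algorithms in
two flavours:

* **node-weighted search** — per-gene evidence z-scores drive module
  growth with the score `Z_m = Σᵢ zᵢ / √k` over the `k` member genes;
* **edge-weighted search** — differential co-expression edge weights
  `w_e` (absolute Fisher-z difference of case vs control Pearson
  correlations) enter a composite score
  `Z_m = (Σᵢ zᵢ + λ Σₑ w_e) / √(k + λ² m)`,
  with `λ = Var(node weights)/Var(edge weights)` balancing the two
  evidence layers.

Around the search the package provides the full pipeline:

1. **Node weights** — gene p → z via `z = Φ⁻¹(1−p)` (with MHC exclusion,
   chr6:25.0–33.5 Mb); probe-level differential methylation on M-values
   aggregated per gene by Stouffer's method over the TSS1500 promoter
   window; variance-matched fusion of the two arms.
2. **Edge weights** — `z_edge = |atanh r₁ − atanh r₂| / √(1/(n₁−3) + 1/(n₂−3))`,
   significant at `z_edge > 1.96`.
3. **Search + normalisation** — one greedy module per seed gene
   (`d = 2`, `r = 0.1` defaults), permutation-normalised scores `Z_n`.
4. **Selection** — rank by `Z_n`, merge the top fraction (10 % default)
   and report scale-free fit diagnostics
   (`log p_k = −γ log k + c`, coefficient of determination R²).
5. **Downstream** — hypergeometric over-representation analysis with
   Benjamini–Hochberg FDR, and two-sample Mendelian randomization
   (IVW, MR-Egger, weighted median).
6. **Synthetic data** — generators for scale-free PPIs, planted gene
   modules, GWAS/methylation/expression/MR data with known ground truth,
   so every stage is testable without any external download.

## Worked example

Run the whole pipeline on a synthetic 300-gene study with an 8-gene
planted module (GWAS effect 3.0, Δβ = 0.2):

```sh
cat > config.yaml <<'YAML'
seed: 7
mode: node
simulate: true
simulate_params: {n_genes: 300, planted_size: 8}
search: {d: 2, r: 0.1, n_perm: 1000}
selection_fraction: 0.10
YAML
integromod run-all --config config.yaml --outdir demo
```

The log reports each stage with a content hash, ending with:

```
[select] 30 modules selected, median R2 = 0.887
```

and `demo/` contains `gene_scores.tsv`, `modules.json` (298 deduplicated
modules), `selected_modules.json`, `scale_free_profile.tsv` and
`mr_estimates.tsv`. Inspecting the result against the planted truth:

```
modules: 298  selected: 30
top module: G0159 ['G0159', 'G0197', 'G0224', 'G0003', 'G0021', 'G0044']  zm=7.264  zn=6.394
planted:   ['G0003', 'G0021', 'G0026', 'G0043', 'G0044', 'G0054', 'G0058', 'G0265']
selected genes: 41   planted recovered: 8
```

The top module alone catches 3 of the 8 planted genes (greedy growth
under `r = 0.1` stops near 6 genes), while the merged top-10 % selection
recovers the entire planted set among 41 genes. The median scale-free
index R² = 0.887 says the merged subnetwork's degree distribution is
close to a power law, the selection diagnostic used to pick the final
subnetwork size.

Individual stages are also available as subcommands
(`simulate`, `node-weights`, `edge-weights`, `search`, `select`,
`enrich`, `mr`, `compare`) — see `integromod <cmd> --help`.

## Layout

```
src/integromod/
  io_formats.py               file formats and in-memory containers
  synthetic_data.py           generators with planted ground truth
  node_weights.py             GWAS + methylation gene scores
  edge_weights.py             differential co-expression statistics
  module_search.py            greedy dense-module search + permutations
  module_selection.py         ranking, merging, scale-free selection
  enrichment.py               hypergeometric ORA with BH FDR
  mendelian_randomization.py  IVW / MR-Egger / weighted median
  cli.py                      subcommands and run-all orchestration
docs/methods.md               model and design notes
```
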