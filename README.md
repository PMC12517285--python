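# pathsem

Pathway-perturbation analysis for two-group gene expression studies:
permutation-based differential expression (SAM), topological pathway
ranking (SPIA), shortest-path module extraction with partial-correlation
pruning, and observed-variable structural equation models (SEM) fit by
maximum likelihood — including modification-index driven refinement and
two-group node/edge invariance testing with Brown's combined test.

## Workflow

1. **Input** — a gene × sample expression table (TSV/CSV, header of sample
   ids, first column gene ids; `log2(x+1)` applied automatically when the
   data look unlogged) and a two-column sample → group label file
   (binary groups, 0 = control).
2. **Differential expression** — two-class unpaired SAM: modified
   t-statistic `d = r/(s + s0)`, permutation-based expected order
   statistics, adjustable delta threshold, median-based FDR.
3. **Pathway ranking** — SPIA: hypergeometric over-representation p-value
   combined with a bootstrap p-value for the accumulated topological
   perturbation (`pG = c − c·ln c`), BH-adjusted.
4. **Module extraction** — pathway graphs as signed directed/bidirected
   gene graphs (SIF or GraphML); union of all shortest paths between DEG
   pairs, optional protein-superfamily merging of non-DEG nodes, and
   Fisher-z partial-correlation pruning of edges.
5. **SEM** — the pruned module becomes a linear model `y = By + ζ` with
   implied covariance `(I−B)⁻¹Ψ(I−B)⁻ᵀ`, fit by Fisher-scoring ML on
   standardized data (covariance divisor N, `χ² = N·F`). Fit indices
   (χ², RMSEA, SRMR, CFI, AIC, BIC), modification indices with expected
   parameter change, and iterative path addition.
6. **Group analysis** — base (pooled), node-effects (exogenous group
   variable into every node), and edge-effects (all parameters free per
   group) models; likelihood-ratio invariance tests, per-node group
   effects, per-edge coefficient differences, and Brown's method for
   combining dependent p-values.

A simulation module generates synthetic scenarios (pathway nodes from a
known SEM embedded in thousands of background genes with controlled
mean shifts) so the entire pipeline is testable offline with known ground
truth.

## CLI

All commands log to stderr and write TSV results under `--outdir`
(exit code 2 on validation errors):

```sh
# list and materialize synthetic scenarios
pathsem simulate
pathsem simulate --name perturbed-chain --seed 1 --outdir scratch/scenario

# SAM differential expression
pathsem deg --expression expr.tsv --labels labels.tsv \
    --delta 0.95 --n-perm 100 --seed 1 --outdir out/deg

# SPIA ranking over a directory of .sif / .graphml pathway graphs
pathsem enrich --expression expr.tsv --labels labels.tsv \
    --pathway-dir pathways/ --outdir out/enrich

# module extraction + pruning for one pathway
pathsem module --expression expr.tsv --labels labels.tsv \
    --pathway pathways/chain5.sif --alpha 0.05 --outdir out/module

# ML SEM fit with modification indices (optionally add paths and refit)
pathsem fit --expression expr.tsv --module out/module/module.sif \
    --outdir out/fit

# two-group invariance analysis
pathsem groups --expression expr.tsv --labels labels.tsv \
    --module out/module/module.sif --outdir out/groups
```

Pathway graphs use a 3-column SIF dialect:
`source <TAB> activation|inhibition|covariance <TAB> target`.

## Layout

```
src/pathsem/
  expression_io.py   matrix/label IO and log2 normalization
  sam.py             SAM statistics, s0 selection, permutation null, calls
  spia.py            over-representation + perturbation accumulation
  graphs.py          signed pathway graphs, modules, merging, pruning
  sem.py             SEM patterns, ML fitting, indices, modification indices
  groups.py          base/node/edge models, LRTs, Brown's method
  simulate.py        synthetic scenarios with ground truth
  cli.py             click command-line interface
```
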