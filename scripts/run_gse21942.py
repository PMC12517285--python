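#!/usr/bin/env python
"""End-to-end runner for the external GEO GSE21942 targets (t3-t5).

This script needs data that must be downloaded manually (no network access
is assumed):

1. Export the GSE21942 series expression table as a tab- or comma-delimited
   file: header row of the 27 sample ids, first column probe/gene ids
   (21,026 rows in the published export).
2. Write a two-column label file mapping each sample id to ``control``/``MS``
   (15 controls, 12 patients).
3. Supply a directory of pathway graphs in the 3-column SIF dialect
   (source, activation|inhibition|covariance, target), including a
   ``Chagas disease`` graph with gene identifiers matching the expression
   rows.

Usage:
    python scripts/run_gse21942.py \
        --expression gse21942_expr.tsv --labels gse21942_labels.tsv \
        --pathway-dir pathways/ --pathway-name "Chagas disease" \
        --outdir results/gse21942

Reports: t3 = number of parsed gene rows; t4 = chi-square of the initial ML
fit of the extracted, pruned module; t5 = its SRMR.  The published pipeline
dialect (probe collapsing, exact SPIA graph set, pruning order) is not fully
specified upstream, so t4/t5 are expected to be reproduced only
approximately.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from pathsem import expression_io as eio
from pathsem import graphs as pg
from pathsem import sam as sam_mod
from pathsem import sem as sem_mod


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--expression", required=True)
    parser.add_argument("--labels", required=True)
    parser.add_argument("--pathway-dir", required=True)
    parser.add_argument("--pathway-name", default="Chagas disease")
    parser.add_argument("--delta", type=float, default=0.95)
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--n-perm", type=int, default=100)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/gse21942"))
    args = parser.parse_args()

    matrix = eio.read_expression_matrix(args.expression)
    matrix = eio.normalize_log2(matrix, mode="auto")
    labels = eio.read_group_labels(args.labels)
    labels.validate_against(matrix)
    results = {"t3": {"value": matrix.n_genes, "n": matrix.n_samples}}

    sam_result = sam_mod.run_sam(
        matrix, labels,
        sam_mod.SamParams(delta=args.delta, n_perm=args.n_perm, seed=args.seed),
    )

    pdir = Path(args.pathway_dir)
    candidates = sorted(list(pdir.glob("*.sif")) + list(pdir.glob("*.graphml")))
    target = next(
        (f for f in candidates if args.pathway_name.lower().replace(" ", "")
         in f.stem.lower().replace(" ", "").replace("_", "")),
        None,
    )
    if target is None:
        raise SystemExit(f"no pathway file matching {args.pathway_name!r} in {pdir}")
    graph = pg.read_pathway_graph(target)
    annotated = pg.annotate_degs(graph, sam_result.deg_ids)
    module = pg.extract_perturbation_module(annotated, sam_result.deg_ids)
    module = pg.prune_by_partial_correlation(module, matrix, alpha=args.alpha)

    model = sem_mod.build_sem_model(module)
    fit = sem_mod.fit_ml(model, matrix)
    idx = sem_mod.fit_indices(fit)
    results["t4"] = {"value": round(idx.chisq, 2), "n": fit.n}
    results["t5"] = {"value": round(idx.srmr, 3), "n": fit.n}

    args.outdir.mkdir(parents=True, exist_ok=True)
    pg.write_pathway_graph(module, args.outdir / "module.sif")
    sem_mod.parameter_table(fit).to_csv(args.outdir / "parameters.tsv", sep="\t", index=False)
    with open(args.outdir / "external_targets.json", "w") as fh:
        json.dump(results, fh, indent=2)
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
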