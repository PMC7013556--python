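#!/usr/bin/env python
"""Topology-based pathway impact analysis of the differentiation changes.

Propagates DE log2 fold changes over the signed directed pathway graphs,
accumulates the perturbation tA, and combines the over-representation and
perturbation p-values into a single pathway score pG with BH adjustment.
"""

from pathlib import Path

import numpy as np

from _common import load_study, standard_args
from trophodiff import io
from trophodiff.impact import PathwayGraph, analyze_pathways


def main():
    args = standard_args(__doc__).parse_args()
    out = args.out or Path("results/07_impact")
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, de = load_study(args.data)

    frame = io.read_pathways_tsv(args.data / "pathways.tsv")
    pathways = [PathwayGraph.from_edges(pid, list(zip(g["source"],
                                                      g["target"], g["sign"])))
                for pid, g in frame.groupby("pathway_id")]
    delta = de.signed_max_log2fc.where(de.is_de, 0.0)
    results, table = analyze_pathways(pathways, delta, de.de_genes(),
                                      expr.genes, n_boot=2000,
                                      seed=np.random.default_rng(args.seed))
    table.to_csv(out / "pathway_impact.tsv", sep="\t")
    ok = table[table["status"] == "ok"]
    print(f"{len(table)} pathways ({len(table) - len(ok)} non-evaluable); "
          f"{int((ok['pG'] < 0.05).sum())} with pG < 0.05")
    top = ok.sort_values("pG").head(3)
    print(top[["n", "n_de", "tA", "pORA", "pAcc", "pG"]].to_string())
    best = next(r for r in results if r.pathway_id == ok["pG"].idxmin())
    best.gene_ranking().to_csv(out / "top_pathway_gene_perturbations.tsv",
                               sep="\t", index_label="gene")


if __name__ == "__main__":
    main()
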