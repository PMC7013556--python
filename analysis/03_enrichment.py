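#!/usr/bin/env python
"""Chromosomal and gene-set enrichment of the placental marker genes.

Tests each chromosome for PPE-gene enrichment (Fisher exact, across all
measured genes) and runs the GMT gene-set enrichment of the DE set with
coverage percentages.
"""

from pathlib import Path

from _common import load_study, standard_args
from trophodiff import io
from trophodiff.enrichment import chromosome_enrichment, gmt_enrichment


def main():
    args = standard_args(__doc__).parse_args()
    out = args.out or Path("results/03_enrichment")
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, de = load_study(args.data)

    chrom = chromosome_enrichment(ann["chromosome"],
                                  ann.index[ann["is_ppe"]])
    chrom.to_csv(out / "chromosome_enrichment.tsv", sep="\t")
    top = chrom["odds_ratio"].idxmax()
    print(f"PPE genes cluster on {top}: OR = "
          f"{chrom.at[top, 'odds_ratio']:.2f}, p = {chrom.at[top, 'p']:.2g}")

    gmt_path = args.data / "gene_sets.gmt"
    if gmt_path.exists():
        sets = io.read_gmt(gmt_path)
        enr = gmt_enrichment(de.de_genes(), expr.genes, sets)
        enr.to_csv(out / "gene_set_enrichment.tsv", sep="\t")
        sig = enr[enr["significant"]]
        print(f"{len(sig)}/{len(enr)} gene sets enriched at q < 0.2; "
              f"top coverage {enr['coverage'].max():.0f}% of the DE set")


if __name__ == "__main__":
    main()
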