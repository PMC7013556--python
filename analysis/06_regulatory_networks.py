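#!/usr/bin/env python
"""Transcription-regulator networks from co-expression and footprints.

Builds the |r| ≥ 0.9 co-expression network between DE TR genes and all DE
genes (connectivity = neighbour count, split by day-1 vs later DE timing),
then derives footprint-supported TF→target edges (motif in footprint in
promoter window), filters them at |r| > 0.6, and reports per-TF coverage of
the placental / non-placental module groups.
"""

from pathlib import Path

from _common import load_study, standard_args
from trophodiff import coexpression as cx, io, networks


def main():
    args = standard_args(__doc__).parse_args()
    out = args.out or Path("results/06_networks")
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, de = load_study(args.data)
    profiles = expr.day_means()

    net = networks.build_tr_coexpression_network(
        profiles, de.de_genes(), ann["is_tr"], r_min=0.9)
    net.edge_table().to_csv(out / "coexpression_edges.tsv", sep="\t",
                            index=False)
    conn = net.connectivity()
    conn.to_csv(out / "tr_connectivity.tsv", sep="\t", index_label="gene",
                header=["connectivity"])
    timing = networks.tr_timing(de, ann["is_tr"])
    print(f"{len(net.tr_genes)} DE TR genes; "
          f"{net.graph.number_of_edges()} edges at |r| >= 0.9; "
          f"median TR connectivity {conn.median():.0f}")
    print(f"{len(timing['day1'])} TR genes DE on day 1, "
          f"{len(timing['later'])} only later")

    fp = io.read_bed(args.data / "footprints.bed")
    motifs = io.read_bed(args.data / "motifs.bed")
    tss = io.read_bed(args.data / "tss.bed")
    raw = networks.footprint_edge_map(fp, motifs, tss)
    filtered = networks.attach_correlations(raw, profiles, min_abs_r=0.6)
    filtered.edges.to_csv(out / "footprint_edges.tsv", sep="\t", index=False)
    print(f"footprint map: {len(raw.edges)} TF->target edges, "
          f"{len(filtered.edges)} with |expression r| > 0.6 "
          f"({filtered.n_unmapped_tfs} TFs unmappable)")

    # coverage of module groups by footprint-supported TFs
    de_prof = profiles.loc[de.de_genes()]
    beta, _ = cx.pick_soft_power(de_prof)
    tom, kept = cx.tom_matrix(de_prof, beta)
    modules = cx.detect_modules(tom, kept, beta=beta)
    cx.classify_module_groups(modules, ann["is_ppe"])
    groups = {g: set(modules.group_genes(g))
              for g in sorted(set(modules.groups.values()))}
    if all(groups.values()) and len(raw.edges):
        cov = networks.module_coverage_report(raw, groups)
        cov.to_csv(out / "tf_module_coverage.tsv", sep="\t")
        both = cov["both_ge_4pct"].sum() if "both_ge_4pct" in cov else 0
        print(f"{both} TFs cover >= 4% of both module groups")


if __name__ == "__main__":
    main()
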