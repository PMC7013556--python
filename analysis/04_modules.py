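#!/usr/bin/env python
"""Co-expression modules among DE genes and their placental grouping.

Builds the weighted co-expression network from 8-day mean profiles (soft
power chosen by the scale-free criterion, with the conventional fallback),
clusters 1−TOM, labels modules M1.. by size, classifies them placental /
non-placental by PPE enrichment, and writes the module summary table and
the per-group |log2FC| trajectories whose contrast shows the fast
non-placental versus slow placental differentiation phases.
"""

from pathlib import Path

import pandas as pd

from _common import load_study, standard_args
from trophodiff import coexpression as cx
from trophodiff.pipeline import _module_table


def main():
    args = standard_args(__doc__).parse_args()
    out = args.out or Path("results/04_modules")
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, de = load_study(args.data)

    profiles = expr.day_means(genes=de.de_genes())
    beta, scan = cx.pick_soft_power(profiles)
    tom, kept = cx.tom_matrix(profiles, beta)
    modules = cx.detect_modules(tom, kept, beta=beta, power_scan=scan)
    cx.classify_module_groups(modules, ann["is_ppe"])

    table = _module_table(modules, ann, de)
    table.to_csv(out / "module_table.tsv", sep="\t")
    pd.DataFrame({"module": modules.labels,
                  "color": modules.labels.map(modules.colors),
                  "group": modules.labels.map(modules.groups).fillna("")}
                 ).to_csv(out / "modules.tsv", sep="\t", index_label="gene")
    per_mod, per_grp = cx.module_trajectories(modules, de.fc_day0)
    per_grp.to_csv(out / "group_trajectories.tsv", sep="\t")

    print(f"soft power {beta}; {len(modules.module_names)} modules "
          f"({(modules.labels == cx.UNASSIGNED).sum()} genes unassigned)")
    print(table[["n_genes", "n_ppe", "ppe_or", "group"]].to_string())
    if {"placental", "non-placental"} <= set(per_grp.index):
        rel = per_grp.div(per_grp.max(axis=1), axis=0)
        print("day-1 change relative to group maximum: "
              f"placental {rel.loc['placental', 1]:.0%}, "
              f"non-placental {rel.loc['non-placental', 1]:.0%} "
              "(slow vs fast differentiation programmes)")


if __name__ == "__main__":
    main()
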