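#!/usr/bin/env python
"""Differential expression over the differentiation time course.

Calls genes DE when some day shows |log2FC vs day 0| ≥ 1 with BH-adjusted
p < 0.1 in that comparison, summarises per-day up/down counts against both
baselines (day 0 and previous day), and compares the mean maximal fold
change of PPE genes with the rest of the DE set.
"""

from pathlib import Path

from _common import load_study, standard_args
from trophodiff.de import group_fc_comparison, summarize_time_course


def main():
    args = standard_args(__doc__).parse_args()
    out = args.out or Path("results/02_de")
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, de = load_study(args.data)

    de.to_frame().to_csv(out / "de_table.tsv", sep="\t", index_label="gene")
    counts = summarize_time_course(de.fc_day0, de.q_day0, de.fc_prev, de.q_prev)
    counts.to_csv(out / "timecourse_counts.tsv", sep="\t", index=False)

    n_de = int(de.is_de.sum())
    n_up = int((de.is_de & (de.signed_max_log2fc > 0)).sum())
    print(f"{n_de} DE genes of {len(de.genes)} ({n_up} up, {n_de - n_up} down)")
    day1 = counts.query("day == 1 and baseline == 'day0'")
    frac1 = (day1["n_up"].item() + day1["n_down"].item()) / max(n_de, 1)
    print(f"{frac1:.0%} of DE genes already change on day 1; "
          "per-day counts in timecourse_counts.tsv")

    ppe = ann["is_ppe"].reindex(de.de_genes()).fillna(False)
    if 2 <= ppe.sum() <= len(ppe) - 2:
        mean_in, mean_out, p = group_fc_comparison(
            de.max_abs_log2fc[de.de_genes()], ppe)
        print(f"PPE genes change more: mean max FC {mean_in:.1f}-fold vs "
              f"{mean_out:.1f}-fold for other DE genes (Welch p = {p:.2g})")


if __name__ == "__main__":
    main()
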