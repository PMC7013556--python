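#!/usr/bin/env python
"""Disease overlay: TR genes moving oppositely in differentiation vs disease.

Intersects the differentiation DE TR genes with the second-condition
(disease) DE table, classifies them concordant/discordant by fold-change
sign, and tests whether the discordant set is unusually tight in
co-expression space (mean pairwise |r| against a permutation null over DE
TR genes).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from _common import load_study, standard_args
from trophodiff import io, networks


def main():
    args = standard_args(__doc__).parse_args()
    out = args.out or Path("results/08_overlay")
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, de = load_study(args.data)

    disease = io.read_disease_table(args.data / "disease.tsv")
    overlay = networks.disease_overlay(de, ann["is_tr"], disease)
    overlay.table.to_csv(out / "disease_overlay.tsv", sep="\t")
    n_both = int(overlay.table["de_both"].sum())
    print(f"{len(overlay.table)} DE TR genes matched in the disease table; "
          f"{n_both} DE in both contexts; "
          f"{len(overlay.discordant)} discordant: {sorted(overlay.discordant)}")

    if len(overlay.discordant) >= 2:
        profiles = expr.day_means()
        de_tr = pd.Index([g for g in de.de_genes() if ann.at[g, "is_tr"]])
        stat, p = networks.discordance_tightness(
            profiles, overlay.discordant, de_tr, n_permutations=1000,
            seed=np.random.default_rng(args.seed))
        print(f"discordant-set tightness: mean pairwise |r| = {stat:.3f}, "
              f"permutation p = {p:.3g}")


if __name__ == "__main__":
    main()
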