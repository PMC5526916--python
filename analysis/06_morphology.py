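"""Morphology across true-type groups (Tables 6-10 analogues).

G-tests on qualitative traits, ANOVA/Tukey on seed weight, trait
correlations + PCA, and stepwise discriminant analysis with
leave-one-out cross-validation.
"""

import pandas as pd

from beandiv.io import TraitTable, QUANTITATIVE_TRAITS
from beandiv.morphology import (ContingencyTable, anova_tukey, lr_chisq,
                                quantitative_summary,
                                stepwise_discriminant)

if __name__ == "__main__":
    traits = TraitTable(pd.read_csv("results/data/traits.csv",
                                    index_col=0))
    cls = pd.read_csv("results/classification.csv", index_col=0)
    true_types = cls[cls["category"] == "TrueType"]["subtype"]
    members = [a for a in true_types.index if a in traits.data.index]
    labels = true_types.loc[members]
    print(f"{len(members)} true-type accessions in "
          f"{labels.nunique()} subtype groups")

    for trait in ("seed_shape", "seed_coat_color", "growth_habit"):
        tab = pd.crosstab(labels, traits.data.loc[members, trait])
        G, df, p = lr_chisq(ContingencyTable(
            list(tab.index), list(tab.columns), tab.to_numpy()))
        print(f"G-test {trait:16s} G = {G:7.2f}  df = {df:2d}  "
              f"p = {p:.3g}")

    w = {g: traits.data.loc[labels.index[labels == g],
                            "weight_100seed_g"].to_numpy()
         for g in labels.unique()}
    F, p, letters = anova_tukey(w)
    print(f"100-seed weight ANOVA: F = {F:.1f}, p = {p:.3g}, "
          f"Tukey letters {letters}")

    quant = traits.data.loc[members, QUANTITATIVE_TRAITS]
    corr, scores, loadings, pct = quantitative_summary(quant)
    corr.to_csv("results/trait_correlations.csv")
    print(f"PCA: first two axes {pct[0]:.1f}% + {pct[1]:.1f}% "
          f"= {pct[:2].sum():.1f}% of variance")

    model = stepwise_discriminant(quant, labels)
    sel = ", ".join(f"{t} (r2={r:.2f})"
                    for t, r in zip(model.selected, model.partial_r2))
    print(f"stepwise discriminant selected: {sel}")
    print(f"cross-validated error rate: {100 * model.cv_error:.1f}% "
          f"({100 * (1 - model.cv_error):.1f}% correctly classified)")
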