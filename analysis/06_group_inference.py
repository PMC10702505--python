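"""Nonparametric group comparisons and correlation map on the matched cohort.

Per imaging variable: Kruskal-Wallis across the four matched severity
groups, gated pairwise Mann-Whitney U tests with Bonferroni correction,
and a Pearson correlation heat map of imaging vs. pulmonary-function
variables on the imputed table.

Writes results/group_tests.csv, results/correlation_matrix.csv and
results/correlation_heatmap.png.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from cwpqct import CohortSpec, em_impute, generate_cohort, pearson_map, two_stage_match
from cwpqct.cohort import structural_columns
from cwpqct.inference import group_test_table

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

TEST_VARIABLES = ["theta_TriLUL", "wt_Trachea", "wt_Bronint", "cr_Bronint",
                  "dh_Trachea", "emphysema", "normal", "ggo",
                  "semi_consolidation", "consolidation", "fibrosis",
                  "bv1_tbv", "bv5_tbv", "bv10_tbv"]
CORR_VARIABLES = ["emphysema", "normal", "ggo", "semi_consolidation",
                  "consolidation", "fibrosis", "bv1_tbv", "bv5_tbv",
                  "bv10_tbv", "fev1_pp", "fvc_pp", "fev1_fvc"]


def main() -> None:
    df = generate_cohort(CohortSpec(seed=0))
    mdf = two_stage_match(df).frame(df)
    full = em_impute(mdf, columns=structural_columns(mdf)).table

    tests = group_test_table(full, TEST_VARIABLES)
    tests.to_csv(OUT / "group_tests.csv", index=False)
    kw = tests.groupby("variable", sort=False).first()
    sig = kw[kw.kw_p <= 0.05].index.tolist()
    print(f"Kruskal-Wallis significant at 0.05: {sig}")
    flat = kw[kw.kw_p > 0.05].index.tolist()
    print(f"not significant (post hocs gated): {flat}")
    extreme = tests[(tests.get("group_1") == 0) & (tests.get("group_2") == 4)]
    if not extreme.empty:
        print("Category 0 vs 4 (Bonferroni-adjusted):")
        for _, r in extreme.iterrows():
            print(f"  {r.variable:20s} p_adj {r.p_adjusted:.2e} {r.stars}")

    cm = pearson_map(full, CORR_VARIABLES)
    cm.r.to_csv(OUT / "correlation_matrix.csv")
    print(f"r(emphysema, FEV1/FVC) = {cm.r.loc['emphysema', 'fev1_fvc']:.3f}; "
          f"r(BV5/TBV, fibrosis) = {cm.r.loc['bv5_tbv', 'fibrosis']:.3f}")

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(cm.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(CORR_VARIABLES)), CORR_VARIABLES, rotation=90)
    ax.set_yticks(range(len(CORR_VARIABLES)), CORR_VARIABLES)
    fig.colorbar(im, label="Pearson r")
    fig.tight_layout()
    fig.savefig(OUT / "correlation_heatmap.png", dpi=150)
    print(f"wrote {OUT / 'group_tests.csv'}, correlation matrix and heat map")


if __name__ == "__main__":
    main()
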