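"""Propensity matching and EM imputation of the synthetic cohort.

Stage 1 matches Category 2 to Category 0 greedily within a caliper of
0.4 x the propensity-score SD; stage 2 matches the retained Category 0
set caliper-free against Categories 1 and 4.  Balance is assessed by
multi-group SMD before and after; missing structural variables of the
matched cohort are then completed by multivariate-normal EM.

Also reproduces the printed-table SMD worked examples that validate the
pairwise-average convention (0.085 / 0.171 / 0.111).

Writes results/cohort_matched_imputed.csv, results/smd_post_matching.csv
and results/match_audit.json.
"""

import json
from pathlib import Path

from cwpqct import (
    CohortSpec,
    counts_from_percentages,
    em_impute,
    generate_cohort,
    smd,
    smd_from_proportions,
    two_stage_match,
)
from cwpqct.cohort import structural_columns

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

CONFOUNDERS = ["age", "height", "smoking", "copd"]


def main() -> None:
    df = generate_cohort(CohortSpec(seed=0))
    mc = two_stage_match(df)
    print(f"matched group sizes: {mc.group_sizes} "
          f"(caliper {mc.meta['caliper']:.4f})")
    mdf = mc.frame(df)
    post = smd(mdf, variables=CONFOUNDERS)
    post.to_frame().to_csv(OUT / "smd_post_matching.csv", index=False)
    print("post-matching multi-group SMD:")
    print(post.to_frame().to_string(index=False, float_format=lambda x: f"{x:.3f}"))

    audit = {
        "caliper": mc.meta["caliper"],
        "covariates": mc.meta["covariates"],
        "stage2_control_pool": mc.meta["stage2_control_pool"],
        "group_sizes": {str(k): v for k, v in mc.group_sizes.items()},
        "stage_pairs": [len(s.pairs) for s in mc.stages],
        "stage_dropped": [len(s.dropped_treatment) for s in mc.stages],
    }
    (OUT / "match_audit.json").write_text(json.dumps(audit, indent=2) + "\n")

    res = em_impute(mdf, columns=structural_columns(mdf))
    print(f"EM imputation: {res.n_iter} iterations, converged={res.converged}, "
          f"log-likelihood {res.loglik[0]:.1f} -> {res.loglik[-1]:.1f}")
    res.table.to_csv(OUT / "cohort_matched_imputed.csv", index=False)

    # printed-table worked examples: the SMD convention check
    post_counts = counts_from_percentages([86.0, 88.4, 90.7, 90.7], [43] * 4)
    v1 = smd_from_proportions([c / 43 for c in post_counts])
    sizes = [110, 108, 54, 10, 98]
    v2 = smd_from_proportions([c / n for c, n in zip(
        counts_from_percentages([82.7, 81.5, 90.7, 90.0, 91.8], sizes), sizes)])
    v3 = smd_from_proportions([c / n for c, n in zip(
        counts_from_percentages([0.0, 0.9, 0.0, 0.0, 2.0], sizes), sizes)])
    print(f"printed-table SMDs: smoking matched {v1:.3f}, "
          f"smoking unmatched {v2:.3f}, female unmatched {v3:.3f}")


if __name__ == "__main__":
    main()
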