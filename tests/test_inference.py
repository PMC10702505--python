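"""Kruskal-Wallis / Mann-Whitney chain and Pearson correlation maps."""

import numpy as np
import pytest
from scipy import stats

from cwpqct import (
    CohortSpec,
    em_impute,
    generate_cohort,
    kruskal_wallis,
    pearson_map,
    posthoc_mwu,
    significance_stars,
    two_stage_match,
)
from cwpqct.cohort import structural_columns
from cwpqct.inference import group_test_table


def _brute_force_h(groups):
    """Independent oracle: H from explicit average-rank computation."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    rank_of = np.empty(len(pooled))
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        rank_of[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = rank_of[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def test_kw_identical_groups_h0_p1():
    h, p = kruskal_wallis([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
    assert h == 0.0 and p == 1.0


def test_kw_matches_brute_force_ranks():
    groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
    h, p = kruskal_wallis(groups)
    assert h == pytest.approx(_brute_force_h(groups), abs=1e-10)
    assert h == pytest.approx(7.2)  # exhaustive rank computation by hand
    assert p == pytest.approx(stats.chi2.sf(7.2, 2))


def test_kw_with_ties_matches_brute_force(rng):
    groups = [rng.integers(0, 5, 12).astype(float) for _ in range(3)]
    h, p = kruskal_wallis(groups)
    assert h == pytest.approx(_brute_force_h(groups), abs=1e-10)


def test_kw_empty_group_rejected():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0], []])


def test_kw_two_groups_monotone_with_mwu(rng):
    """For two groups, H is a monotone transform of |U - n1 n2 / 2|."""
    us, hs = [], []
    for shift in (0.0, 0.5, 1.0, 2.0):
        x = rng.normal(0, 1, 30)
        y = rng.normal(shift, 1, 30)
        u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        h, _ = kruskal_wallis([x, y])
        us.append(abs(u - 450.0))
        hs.append(h)
    assert np.argsort(us).tolist() == np.argsort(hs).tolist()


def test_posthoc_gated_when_kw_not_significant(rng):
    groups = {g: rng.normal(0, 1, 30) for g in range(4)}
    res = posthoc_mwu(groups, variable="flat")
    if res.p > 0.05:
        assert res.gated and res.pairs == []


def test_posthoc_exact_small_sample_oracle():
    """Disjoint {1..5} vs {6..10}: U = 0 and the exact two-sided p is
    2 / C(10,5) by direct enumeration of the extreme orderings."""
    res = posthoc_mwu({"a": [1, 2, 3, 4, 5], "b": [6, 7, 8, 9, 10]},
                      variable="sep", gate_p=1.0)
    pr = res.pairs[0]
    assert pr.u == 0.0
    from math import comb
    assert pr.p_raw == pytest.approx(2 / comb(10, 5))
    assert pr.p_adjusted == pytest.approx(min(1.0, pr.p_raw * 1))


def test_posthoc_bonferroni_cap_and_count():
    rng = np.random.default_rng(0)
    groups = {g: rng.normal(g * 2.0, 1, 20) for g in range(4)}
    res = posthoc_mwu(groups, variable="x")
    assert res.n_comparisons == 6
    for pr in res.pairs:
        assert pr.p_adjusted >= pr.p_raw
        assert pr.p_adjusted <= 1.0
        assert pr.p_adjusted == pytest.approx(min(1.0, pr.p_raw * 6))


def test_identical_pair_adjusted_p_is_one():
    vals = [1.0, 2.0, 3.0, 4.0]
    res = posthoc_mwu({"a": vals, "b": vals, "c": [10.0, 11, 12, 13]},
                      variable="x", gate_p=1.0)
    pair_ab = next(p for p in res.pairs if p.pair == ("a", "b"))
    assert pair_ab.p_adjusted == 1.0
    assert pair_ab.stars == "ns"


@pytest.mark.parametrize("p, mark", [
    (0.2, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***"),
    (0.00009, "****"), (0.05, "ns"),
])
def test_significance_stars_thresholds(p, mark):
    assert significance_stars(p) == mark


def test_pearson_trivial_lines():
    import pandas as pd
    x = np.arange(10.0)
    df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
    cm = pearson_map(df, ["x", "y", "z"])
    assert cm.r.loc["x", "y"] == pytest.approx(1.0)
    assert cm.r.loc["x", "z"] == pytest.approx(-1.0)
    assert np.allclose(np.diag(cm.r), 1.0)
    assert (cm.n.to_numpy() == 10).all()


def test_pearson_zero_variance_stored_missing():
    import pandas as pd
    df = pd.DataFrame({"x": np.arange(8.0), "c": np.ones(8)})
    cm = pearson_map(df, ["x", "c"])
    assert np.isnan(cm.r.loc["x", "c"])


def test_pearson_pairwise_complete_counts():
    import pandas as pd
    df = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan, 6],
                       "y": [2.0, 1, np.nan, 3, 5, 4]})
    cm = pearson_map(df, ["x", "y"])
    assert cm.n.loc["x", "y"] == 4


def test_cohort_effect_directions_in_correlation_map():
    """The imaging chain's documented directions appear in the matched,
    imputed cohort: emphysema vs FEV1/FVC negative, BV5/TBV vs fibrosis
    negative."""
    df = generate_cohort(CohortSpec(seed=0))
    mdf = two_stage_match(df).frame(df)
    full = em_impute(mdf, columns=structural_columns(mdf)).table
    cm = pearson_map(full, ["emphysema", "fev1_fvc", "bv5_tbv", "fibrosis"])
    assert cm.r.loc["emphysema", "fev1_fvc"] < 0
    assert cm.r.loc["bv5_tbv", "fibrosis"] < 0


def test_group_test_table_shape():
    df = generate_cohort(CohortSpec(seed=0))
    out = group_test_table(df[df.category.isin([0, 1, 2, 4])],
                           ["wt_Trachea", "dh_Trachea"])
    assert set(out.variable) == {"wt_Trachea", "dh_Trachea"}
    sig = out[out.variable == "wt_Trachea"]
    if not sig.gated.iloc[0]:
        assert len(sig) == 6  # all pairwise rows present
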