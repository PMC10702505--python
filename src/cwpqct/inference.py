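"""Nonparametric group comparison chain and correlation maps.

Per variable: a Kruskal-Wallis test across the matched severity groups;
if it rejects at p <= 0.05, pairwise Mann-Whitney U tests between all
group pairs with Bonferroni correction over the pairs tested for that
variable (6 pairs for four groups).  Pearson correlation matrices use
pairwise-complete observations on the post-imputation table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001."""
    if np.isnan(p):
        return "ns"
    for thr, mark in STAR_THRESHOLDS:
        if p < thr:
            return mark
    return "ns"


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    All-identical values across groups give H = 0, p = 1 rather than an
    error (a flat variable is simply not significant).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[~np.isnan(a)] for a in arrs]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrs)
    return float(h), float(p)


@dataclass
class PairResult:
    pair: tuple
    u: float
    p_raw: float
    p_adjusted: float
    stars: str


@dataclass
class GroupTestResult:
    variable: str
    h: float
    p: float
    gated: bool                      # True if the KW gate blocked post hocs
    pairs: list[PairResult] = field(default_factory=list)
    n_comparisons: int = 0

    def to_rows(self) -> list[dict]:
        base = {"variable": self.variable, "kw_h": self.h, "kw_p": self.p,
                "gated": self.gated}
        if not self.pairs:
            return [base]
        return [{**base, "group_1": pr.pair[0], "group_2": pr.pair[1],
                 "mwu_u": pr.u, "p_raw": pr.p_raw, "p_adjusted": pr.p_adjusted,
                 "stars": pr.stars} for pr in self.pairs]


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """MWU with exact p when both groups are small and tie-free."""
    small = len(x) <= 8 and len(y) <= 8
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def posthoc_mwu(groups: dict, variable: str = "", gate_p: float = 0.05) -> GroupTestResult:
    """KW gate, then pairwise Mann-Whitney U with Bonferroni adjustment.

    ``groups`` maps group name to values.  Pairwise tests run only when
    the Kruskal-Wallis p is at or below ``gate_p``; the Bonferroni
    multiplier is the number of pairwise comparisons performed for this
    variable, and adjusted p-values are capped at 1.
    """
    names = list(groups)
    arrs = {g: np.asarray(groups[g], dtype=float) for g in names}
    arrs = {g: a[~np.isnan(a)] for g, a in arrs.items()}
    h, p = kruskal_wallis(list(arrs.values()))
    if p > gate_p:
        return GroupTestResult(variable=variable, h=h, p=p, gated=True)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for g1, g2 in pairs:
        u, praw = _mwu(arrs[g1], arrs[g2])
        padj = min(1.0, praw * m)
        out.append(PairResult((g1, g2), u, praw, padj, significance_stars(padj)))
    return GroupTestResult(variable=variable, h=h, p=p, gated=False,
                           pairs=out, n_comparisons=m)


def group_test_table(df: pd.DataFrame, variables: list[str],
                     group_col: str = "category", gate_p: float = 0.05) -> pd.DataFrame:
    """Run the KW + post-hoc chain for each variable; one row per pair."""
    rows = []
    for v in variables:
        groups = {g: sub[v].to_numpy() for g, sub in df.groupby(group_col)}
        res = posthoc_mwu(groups, variable=v, gate_p=gate_p)
        rows.extend(res.to_rows())
    return pd.DataFrame(rows)


@dataclass
class CorrelationMap:
    variables: list[str]
    r: pd.DataFrame                  # Pearson r, pairwise-complete
    n: pd.DataFrame                  # pairwise-complete sample sizes

    def check(self) -> None:
        m = self.r.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True), "correlation matrix not symmetric"
        finite = np.isfinite(m)
        assert (np.abs(m[finite]) <= 1 + 1e-12).all(), "|r| exceeds 1"


def pearson_map(table: pd.DataFrame, variables: list[str],
                min_pairs: int = 3) -> CorrelationMap:
    """Pairwise-complete Pearson correlation matrix.

    Pairs with fewer than ``min_pairs`` complete observations, or with a
    zero-variance variable, are stored as missing.  The diagonal is 1 for
    any variable with positive variance.
    """
    sub = table[variables].astype(float)
    r = sub.corr(method="pearson", min_periods=min_pairs)
    notna = sub.notna().astype(int)
    n = notna.T @ notna
    cm = CorrelationMap(variables=list(variables), r=r,
                        n=pd.DataFrame(n, index=variables, columns=variables))
    cm.check()
    return cm
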