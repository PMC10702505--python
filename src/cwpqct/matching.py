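"""Propensity-score matching, balance assessment and EM imputation.

The cohort-preparation chain: logistic propensity scores on the four
confounders (age, height, smoking, COPD), greedy one-to-one nearest-score
matching (optionally within a caliper of 0.4 x the score SD), pairwise
standardized mean differences averaged over all group pairs as the
multi-group balance measure (|SMD| < 0.1 = well balanced), and
multivariate-normal expectation-maximization to impute structural
variables lost to opacity-obscured airway segmentation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_COVARIATES = ("age", "height", "smoking", "copd")
BALANCE_THRESHOLD = 0.1


# ----------------------------------------------------------------- SMD

def smd_continuous(x1: np.ndarray, x2: np.ndarray) -> float:
    """|m1 - m2| / sqrt((s1^2 + s2^2) / 2) with sample (ddof=1) variances."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("continuous SMD needs at least 2 observations per group")
    num = abs(x1.mean() - x2.mean())
    den = np.sqrt((x1.var(ddof=1) + x2.var(ddof=1)) / 2.0)
    if num == 0.0 and den == 0.0:
        return 0.0
    return float(num / den)


def smd_binary(p1: float, p2: float) -> float:
    """|p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2); 0/0 defined as 0.

    Degenerate proportions (0 vs 1) have zero pooled variance with a
    nonzero difference: the SMD is infinite.
    """
    num = abs(p1 - p2)
    den = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / den)


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return set(u).issubset({0.0, 1.0})


@dataclass
class SMDTable:
    """Per-variable multi-group SMD (mean of all pairwise SMDs) and pairwise detail."""

    variables: list[str]
    group_names: list
    multi: dict[str, float]
    pairwise: dict[str, dict[tuple, float]]
    summary_mode: str = "mean"

    @property
    def balanced(self) -> dict[str, bool]:
        return {v: abs(s) < BALANCE_THRESHOLD for v, s in self.multi.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variables,
            "smd": [self.multi[v] for v in self.variables],
            "balanced": [self.balanced[v] for v in self.variables],
        })


def smd(groups: dict | pd.DataFrame, variables: list[str] | None = None,
        group_col: str = "category", summary: str = "mean") -> SMDTable:
    """Multi-group standardized mean differences.

    ``groups`` is either a mapping ``{group name: DataFrame}`` or a single
    DataFrame with a ``group_col``.  Binary variables (values in {0, 1})
    use the proportion-based pooled variance; continuous variables the
    sample-variance form.  The multi-group summary is the arithmetic mean
    of all pairwise SMDs (``summary="max"`` is available).
    """
    if isinstance(groups, pd.DataFrame):
        groups = {g: sub for g, sub in groups.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    if variables is None:
        variables = [c for c in next(iter(groups.values())).columns
                     if c not in (group_col, "id")]
    multi: dict[str, float] = {}
    pairwise: dict[str, dict[tuple, float]] = {}
    for v in variables:
        vals = {g: np.asarray(groups[g][v], dtype=float) for g in names}
        binary = all(_is_binary(x) for x in vals.values())
        pw = {}
        for g1, g2 in itertools.combinations(names, 2):
            if binary:
                pw[(g1, g2)] = smd_binary(float(np.nanmean(vals[g1])),
                                          float(np.nanmean(vals[g2])))
            else:
                pw[(g1, g2)] = smd_continuous(vals[g1][~np.isnan(vals[g1])],
                                              vals[g2][~np.isnan(vals[g2])])
        pairwise[v] = pw
        agg = np.mean if summary == "mean" else np.max
        multi[v] = float(agg(list(pw.values())))
    return SMDTable(variables=list(variables), group_names=names,
                    multi=multi, pairwise=pairwise, summary_mode=summary)


def smd_from_proportions(proportions, sizes=None, summary: str = "mean") -> float:
    """Multi-group binary SMD straight from per-group proportions.

    The worked-example entry point: group percentages printed in a cohort
    table are converted to proportions and averaged over all pairs.
    ``sizes`` is accepted for symmetry but the binary SMD depends only on
    the proportions.
    """
    ps = [float(p) for p in proportions]
    pairs = [smd_binary(a, b) for a, b in itertools.combinations(ps, 2)]
    agg = np.mean if summary == "mean" else np.max
    return float(agg(pairs))


def counts_from_percentages(percentages, sizes) -> list[int]:
    """Recover integer event counts from printed group percentages."""
    return [int(round(pct / 100.0 * n)) for pct, n in zip(percentages, sizes)]


# ----------------------------------------------------- propensity model

@dataclass
class PropensityModel:
    covariates: list[str]
    coefficients: pd.Series          # includes the intercept
    scores: pd.Series                # id -> P(treatment), in (0, 1)
    treatment_ids: list
    control_ids: list
    caliper: float | None = None

    def caliper_from_sd(self, factor: float = 0.4) -> float:
        """Caliper width = factor x SD of the pooled estimated scores."""
        return float(factor * self.scores.std(ddof=1))


def fit_propensity(cohort: pd.DataFrame, treatment_category: int,
                   control_category: int,
                   covariates=DEFAULT_COVARIATES,
                   group_col: str = "category") -> PropensityModel:
    """Logistic propensity model of treatment membership on the confounders."""
    sub = cohort[cohort[group_col].isin([treatment_category, control_category])]
    if (sub[group_col] == treatment_category).sum() == 0 or \
       (sub[group_col] == control_category).sum() == 0:
        raise ValueError("both categories must be nonempty")
    y = (sub[group_col] == treatment_category).astype(float).to_numpy()
    X = sm.add_constant(sub[list(covariates)].astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(
            "propensity model failed (likely perfect separation of the "
            "confounders); match exactly without a caliper instead") from exc
    if not np.all(np.isfinite(res.params)):
        raise ValueError("propensity coefficients diverged (perfect separation); "
                         "match exactly without a caliper instead")
    scores = pd.Series(res.predict(X), index=sub["id"].to_numpy())
    return PropensityModel(
        covariates=list(covariates),
        coefficients=pd.Series(res.params.to_numpy(), index=X.columns),
        scores=scores,
        treatment_ids=sub.loc[sub[group_col] == treatment_category, "id"].tolist(),
        control_ids=sub.loc[sub[group_col] == control_category, "id"].tolist(),
    )


# ------------------------------------------------------ greedy matching

@dataclass
class MatchResult:
    pairs: list[tuple]               # (treatment id, control id)
    dropped_treatment: list          # refused by the caliper / pool exhausted
    caliper: float | None


def greedy_match(scores_treatment: pd.Series, scores_control: pd.Series,
                 caliper: float | None = None) -> MatchResult:
    """Greedy one-to-one nearest-score matching.

    Treatment subjects are processed in descending score order (ties by id
    ascending); each takes the unused control with the smallest absolute
    score difference.  With a caliper, a nearest difference beyond it
    drops the treatment subject; controls are never reused.
    """
    order = sorted(scores_treatment.items(), key=lambda kv: (-kv[1], kv[0]))
    available = dict(sorted(scores_control.items(), key=lambda kv: kv[0]))
    pairs, dropped = [], []
    for tid, ts in order:
        if not available:
            dropped.append(tid)
            continue
        cid = min(available, key=lambda k: (abs(available[k] - ts), k))
        diff = abs(available[cid] - ts)
        if caliper is not None and diff > caliper:
            dropped.append(tid)
            continue
        pairs.append((tid, cid))
        del available[cid]
    return MatchResult(pairs=pairs, dropped_treatment=dropped, caliper=caliper)


@dataclass
class MatchedCohort:
    retained: dict[int, list]        # category -> retained subject ids
    stages: list[MatchResult]
    meta: dict = field(default_factory=dict)

    @property
    def group_sizes(self) -> dict[int, int]:
        return {c: len(ids) for c, ids in self.retained.items()}

    def frame(self, cohort: pd.DataFrame) -> pd.DataFrame:
        keep = [i for ids in self.retained.values() for i in ids]
        return cohort[cohort["id"].isin(keep)].reset_index(drop=True)


def two_stage_match(cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                    caliper_factor: float = 0.4,
                    group_col: str = "category") -> MatchedCohort:
    """The two-stage matching design over categories 0, 1, 2 and 4.

    Stage 1: the smallest group (Category 2) is the treatment group and
    Category 0 (the largest) the control group, matched greedily within a
    caliper of ``caliper_factor`` x the SD of the pooled scores.  Stage 2:
    the stage-1-retained Category 0 subjects become the treatment side and
    are matched caliper-free against Category 1 and against Category 4.
    Category 3 is excluded by configuration (its sample size is too small
    to match).  All four retained groups end up the same size.
    """
    for c in (0, 1, 2, 4):
        if (cohort[group_col] == c).sum() == 0:
            raise ValueError(f"category {c} is empty")

    model1 = fit_propensity(cohort, treatment_category=2, control_category=0,
                            covariates=covariates, group_col=group_col)
    caliper = model1.caliper_from_sd(caliper_factor)
    model1.caliper = caliper
    s_t = model1.scores.loc[model1.treatment_ids]
    s_c = model1.scores.loc[model1.control_ids]
    stage1 = greedy_match(s_t, s_c, caliper=caliper)
    if not stage1.pairs:
        raise ValueError("stage 1 matching emptied the treatment group")
    cat2_ids = [t for t, _ in stage1.pairs]
    cat0_ids = [c for _, c in stage1.pairs]

    retained = {2: cat2_ids, 0: cat0_ids}
    stages = [stage1]
    cat0_pool = cohort[cohort["id"].isin(cat0_ids)]
    for ctrl_cat in (1, 4):
        model = fit_propensity(
            pd.concat([cat0_pool, cohort[cohort[group_col] == ctrl_cat]]),
            treatment_category=0, control_category=ctrl_cat,
            covariates=covariates, group_col=group_col)
        s_t = model.scores.loc[model.treatment_ids]
        s_c = model.scores.loc[model.control_ids]
        res = greedy_match(s_t, s_c, caliper=None)
        if not res.pairs:
            raise ValueError(f"stage 2 matching emptied category {ctrl_cat}")
        retained[ctrl_cat] = [c for _, c in res.pairs]
        stages.append(res)

    sizes = {len(v) for v in retained.values()}
    if len(sizes) != 1:
        # stage 2 is caliper-free and every control pool is at least as
        # large as the treatment side, so this indicates a logic error
        raise AssertionError(f"matched groups are unequal: { {k: len(v) for k, v in retained.items()} }")
    return MatchedCohort(
        retained=retained, stages=stages,
        meta={"caliper": caliper, "caliper_factor": caliper_factor,
              "covariates": list(covariates),
              "stage2_control_pool": "full categories 1 and 4; treatment side "
                                     "is the stage-1-retained category 0 set"})


# ------------------------------------------------------- EM imputation

@dataclass
class EMResult:
    table: pd.DataFrame
    n_iter: int
    converged: bool
    loglik: list[float]
    ridge_used: bool


def em_impute(table: pd.DataFrame, columns: list[str] | None = None,
              tolerance: float = 1e-6, max_iter: int = 500,
              ridge: float = 1e-8) -> EMResult:
    """Multivariate-normal EM imputation of missing entries.

    The E-step replaces missing entries with their conditional expectation
    given the observed entries under the current (mu, Sigma); the M-step
    re-estimates (mu, Sigma) from the completed sufficient statistics
    (including the conditional covariance of the missing block, so the
    observed-data log-likelihood is non-decreasing).  Observed entries are
    never altered.  Iteration stops when the largest parameter change
    falls below ``tolerance`` or at ``max_iter`` (then the result carries
    ``converged=False``).  A singular covariance is ridge-regularized.
    """
    cols = columns if columns is not None else list(table.columns)
    X = table[cols].to_numpy(dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    col_missing = miss.mean(axis=0)
    if (col_missing >= 0.5).any():
        bad = [c for c, m in zip(cols, col_missing) if m >= 0.5]
        raise ValueError(f"missingness >= 50% in columns {bad}")
    if not miss.any():
        out = table.copy()
        return EMResult(out, 0, True, [], False)

    mu = np.nanmean(X, axis=0)
    Xf = np.where(miss, mu, X)
    sigma = np.cov(Xf, rowvar=False, ddof=0)
    sigma = np.atleast_2d(sigma)
    ridge_used = False

    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)
    patterns = {k: np.array(v) for k, v in patterns.items()}

    logliks: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # guard against singular covariance
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            sigma = sigma + max(ridge, 1e-6 * np.trace(sigma) / p) * np.eye(p)
            ridge_used = True

        Ex = X.copy()
        Exx_corr = np.zeros((p, p))
        ll = 0.0
        for key, rows in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            o = ~m
            xo = X[np.ix_(rows, np.flatnonzero(o))]
            mu_o, mu_m = mu[o], mu[m]
            S_oo = sigma[np.ix_(o, o)]
            ll += _gauss_loglik(xo, mu_o, S_oo)
            if m.any():
                S_mo = sigma[np.ix_(m, o)]
                S_mm = sigma[np.ix_(m, m)]
                K = np.linalg.solve(S_oo, S_mo.T).T       # regression weights
                cond_mean = mu_m + (xo - mu_o) @ K.T
                Ex[np.ix_(rows, np.flatnonzero(m))] = cond_mean
                C = S_mm - K @ S_mo.T                     # conditional covariance
                Exx_corr[np.ix_(np.flatnonzero(m), np.flatnonzero(m))] += len(rows) * C
        logliks.append(ll)
        if len(logliks) >= 2:
            assert logliks[-1] >= logliks[-2] - 1e-6 * abs(logliks[-2]) - 1e-8, \
                "EM observed-data log-likelihood decreased"

        mu_new = Ex.mean(axis=0)
        diff = Ex - mu_new
        sigma_new = (diff.T @ diff + Exx_corr) / n
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", RuntimeWarning)

    completed = table.copy()
    filled = np.where(miss, _final_estep(X, miss, patterns, mu, sigma), X)
    completed[cols] = filled
    return EMResult(completed, n_iter, converged, logliks, ridge_used)


def _final_estep(X, miss, patterns, mu, sigma):
    Ex = X.copy()
    for key, rows in patterns.items():
        m = np.frombuffer(key, dtype=bool)
        if not m.any():
            continue
        o = ~m
        xo = X[np.ix_(rows, np.flatnonzero(o))]
        S_oo = sigma[np.ix_(o, o)]
        S_mo = sigma[np.ix_(m, o)]
        K = np.linalg.solve(S_oo, S_mo.T).T
        Ex[np.ix_(rows, np.flatnonzero(m))] = mu[m] + (xo - mu[o]) @ K.T
    return Ex


def _gauss_loglik(xo: np.ndarray, mu_o: np.ndarray, S_oo: np.ndarray) -> float:
    k = len(mu_o)
    if k == 0:
        return 0.0
    sign, logdet = np.linalg.slogdet(S_oo)
    diff = xo - mu_o
    maha = np.einsum("ij,ij->i", diff @ np.linalg.inv(S_oo), diff)
    return float(-0.5 * (len(xo) * (k * np.log(2 * np.pi) + logdet) + maha.sum()))
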