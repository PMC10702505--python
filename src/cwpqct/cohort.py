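"""Synthetic pneumoconiosis cohorts with category-dependent confounding.

Subjects carry an ILO severity category (0-4), demographics, pulmonary
function, per-branch airway structural variables, parenchymal HU-class
fractions and vessel volume ratios.  The default parameters reproduce the
confounding structure of the study population this pipeline targets:
higher categories are older, shorter, more often smokers and COPD
patients, so pre-matching standardized mean differences exceed the 0.1
balance threshold and a propensity-matching stage is required.

Imaging effects run through a per-subject latent severity score so the
documented effect directions emerge jointly: thicker tracheal/Bronint
walls, a narrower TriLUL bifurcation angle and lower Bronint circularity
with severity; more emphysema/consolidation/fibrosis and less normal lung
(GGO flat); a smaller small-vessel volume share (BVx/TBV) in Category 4;
and FEV1/FVC falling with the emphysema fraction.  Structural variables
are missing at random conditional on category, more often in the higher
categories where opacities obscure airway segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = (0, 1, 2, 3, 4)

#: structural columns that never go missing in the generator would defeat
#: the imputation stage; all of these are eligible for missingness.
STRUCTURAL_PREFIXES = ("theta_", "dh_", "wt_", "cr_")

THETA_BRANCHES = ("Trachea", "LMB", "RMB", "Bronint",
                  "TriLUL", "TriLLB", "TriRUL", "TriRLL")
SECTION_BRANCHES = THETA_BRANCHES + ("sRUL", "sRML", "sRLL", "sLUL", "sLLL")

IMAGING_COLUMNS = [f"theta_{b}" for b in THETA_BRANCHES] + \
    [f"{m}_{b}" for b in SECTION_BRANCHES for m in ("dh", "wt", "cr")]

PARENCHYMA_COLUMNS = ("emphysema", "normal", "ggo",
                      "semi_consolidation", "consolidation", "fibrosis")
VESSEL_COLUMNS = ("bv1_tbv", "bv5_tbv", "bv10_tbv")


@dataclass
class CategoryParams:
    n: int
    age: tuple[float, float]       # mean, SD (years)
    height: tuple[float, float]    # mean, SD (cm)
    smoking_p: float
    copd_p: float
    female_p: float
    bmi: tuple[float, float]
    fev1_pp: tuple[float, float]   # FEV1 % predicted
    fvc_pp: tuple[float, float]
    fev1_fvc: tuple[float, float]  # FEV1/FVC %
    missing_rate: float            # per structural variable


def _default_categories() -> dict[int, CategoryParams]:
    # demographics and PFTs per severity category of the target population
    tab = {
        0: ((110), (67.1, 7.7), (166.4, 6.0), 0.827, 0.418, 0.000,
            (24.3, 3.4), (83.5, 16.1), (81.2, 13.8), (72.3, 10.2), 0.02),
        1: ((108), (72.3, 7.5), (164.1, 5.8), 0.815, 0.602, 0.009,
            (23.7, 3.0), (74.1, 20.0), (71.5, 17.6), (69.5, 11.3), 0.04),
        2: ((54), (73.8, 6.7), (164.8, 5.9), 0.907, 0.796, 0.000,
            (23.7, 2.8), (63.5, 19.5), (65.4, 15.7), (65.7, 14.2), 0.06),
        3: ((10), (72.2, 8.8), (163.4, 5.9), 0.900, 1.000, 0.000,
            (24.3, 1.9), (64.8, 21.5), (63.8, 10.1), (67.3, 18.4), 0.08),
        4: ((98), (75.0, 7.2), (164.4, 5.9), 0.918, 0.854, 0.020,
            (22.7, 2.9), (56.9, 20.9), (61.9, 17.9), (60.5, 14.0), 0.10),
    }
    return {c: CategoryParams(*v) for c, v in tab.items()}


@dataclass
class CohortSpec:
    categories: dict[int, CategoryParams] = field(default_factory=_default_categories)
    effect_scale: float = 1.0   # scales every imaging effect slope; 0 = null cohort
    seed: int = 0

    def validate(self) -> None:
        for c, p in self.categories.items():
            if c not in CATEGORIES:
                raise ValueError(f"unknown category {c}")
            if p.n <= 0:
                raise ValueError(f"category {c} has zero subjects requested")
            for pr in (p.smoking_p, p.copd_p, p.female_p):
                if not 0.0 <= pr <= 1.0:
                    raise ValueError(f"category {c}: probability {pr} outside [0,1]")
            if not 0.0 <= p.missing_rate < 1.0:
                raise ValueError(f"category {c}: missingness rate outside [0,1)")


def null_cohort_spec(n_per_category: int = 50, seed: int = 0,
                     categories=(0, 1, 2, 4)) -> CohortSpec:
    """Identical distributions in every category and zero effect slopes."""
    base = _default_categories()[0]
    cats = {}
    for c in categories:
        cats[c] = CategoryParams(n_per_category, base.age, base.height,
                                 base.smoking_p, base.copd_p, base.female_p,
                                 base.bmi, base.fev1_pp, base.fvc_pp,
                                 base.fev1_fvc, base.missing_rate)
    return CohortSpec(categories=cats, effect_scale=0.0, seed=seed)


# baseline level and per-severity slope for each imaging variable family
_WT_BASE = {"Trachea": 1.9, "LMB": 1.5, "RMB": 1.5, "Bronint": 1.3,
            "TriLUL": 1.1, "TriLLB": 1.1, "TriRUL": 1.1, "TriRLL": 1.1,
            "sRUL": 0.9, "sRML": 0.9, "sRLL": 0.9, "sLUL": 0.9, "sLLL": 0.9}
_DH_BASE = {"Trachea": 16.5, "LMB": 11.0, "RMB": 12.0, "Bronint": 9.5,
            "TriLUL": 7.5, "TriLLB": 7.8, "TriRUL": 7.5, "TriRLL": 7.6,
            "sRUL": 5.0, "sRML": 4.8, "sRLL": 5.2, "sLUL": 5.0, "sLLL": 5.1}
_THETA_BASE = {"Trachea": 72.0, "LMB": 65.0, "RMB": 68.0, "Bronint": 62.0,
               "TriLUL": 78.0, "TriLLB": 60.0, "TriRUL": 61.0, "TriRLL": 59.0}
# effect slopes per unit latent severity for the variables the disease moves
_WT_SLOPE = {"Trachea": 0.09, "Bronint": 0.08}
_THETA_SLOPE = {"TriLUL": -2.2, "Bronint": -1.0}
_CR_SLOPE = {"Bronint": -0.016}


def _shift_prob(p: float, logit_shift: np.ndarray) -> np.ndarray:
    """Per-subject probability with a centred logit shift; mean stays ~p."""
    if p <= 0.0 or p >= 1.0:
        return np.full_like(np.asarray(logit_shift, dtype=float), p)
    base = np.log(p / (1 - p))
    return 1.0 / (1.0 + np.exp(-(base + logit_shift)))


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """One row per subject; deterministic for a fixed seed.

    The random stream is consumed category by category in ascending order,
    one variable block at a time, so a given (spec, seed) pair always
    yields the same table.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    es = spec.effect_scale

    frames = []
    next_id = 0
    for c in sorted(spec.categories):
        p = spec.categories[c]
        n = p.n
        # confounders are mutually correlated within category, as in real
        # occupational cohorts (older miners smoke more and carry more COPD,
        # later birth cohorts are shorter): the correlation keeps a single
        # propensity score nearly sufficient for all four confounders.
        # Dependent terms are centred so the configured marginals hold.
        age = rng.normal(*p.age, size=n)
        z_age = (age - p.age[0]) / max(p.age[1], 1e-9)
        smoking = (rng.random(n) < _shift_prob(p.smoking_p, 0.55 * z_age)).astype(int)
        copd_logit_shift = 0.9 * z_age + 0.9 * (smoking - p.smoking_p)
        copd = (rng.random(n) < _shift_prob(p.copd_p, copd_logit_shift)).astype(int)
        h_slope = 0.35 * p.height[1]
        h_sd = float(np.sqrt(max(p.height[1] ** 2 - h_slope ** 2, 1.0)))
        height = p.height[0] - h_slope * z_age + rng.normal(0.0, h_sd, size=n)
        df = pd.DataFrame({
            "id": np.arange(next_id, next_id + n),
            "category": c,
            "age": age,
            "height": height,
            "female": (rng.random(n) < p.female_p).astype(int),
            "smoking": smoking,
            "copd": copd,
            "bmi": rng.normal(*p.bmi, size=n),
        })
        next_id += n

        # latent severity: category level plus subject-level variation
        sev = c + rng.normal(0.0, 0.8, size=n)

        for b in THETA_BRANCHES:
            df[f"theta_{b}"] = (_THETA_BASE[b] + es * _THETA_SLOPE.get(b, 0.0) * sev
                                + rng.normal(0.0, 5.0, size=n))
        for b in SECTION_BRANCHES:
            df[f"dh_{b}"] = _DH_BASE[b] + rng.normal(0.0, 1.2, size=n)
            df[f"wt_{b}"] = np.maximum(
                _WT_BASE[b] + es * _WT_SLOPE.get(b, 0.0) * sev
                + rng.normal(0.0, 0.18, size=n), 0.1)
            df[f"cr_{b}"] = np.clip(
                0.92 + es * _CR_SLOPE.get(b, 0.0) * sev
                + rng.normal(0.0, 0.03, size=n), 0.3, 1.0)

        # parenchymal fractions driven by the same latent severity
        emph = np.clip(0.05 + 0.022 * es * sev + rng.normal(0, 0.015, n), 0.001, 0.6)
        ggo = np.clip(0.040 + rng.normal(0, 0.010, n), 0.001, 0.3)
        semi = np.clip(0.030 + 0.010 * es * sev + rng.normal(0, 0.008, n), 0.001, 0.3)
        conso = np.clip(0.020 + 0.008 * es * sev + rng.normal(0, 0.006, n), 0.001, 0.3)
        fibr = np.clip(0.030 + 0.012 * es * sev + rng.normal(0, 0.008, n), 0.001, 0.4)
        normal = np.clip(1.0 - emph - ggo - semi - conso
                         - np.abs(rng.normal(0.01, 0.005, n)), 0.05, None)
        df["emphysema"], df["ggo"] = emph, ggo
        df["semi_consolidation"], df["consolidation"] = semi, conso
        df["fibrosis"], df["normal"] = fibr, normal

        # small-vessel share falls with severity and with dense abnormality
        bv5 = np.clip(0.52 - 0.018 * es * sev - 0.5 * es * (fibr - 0.03)
                      + rng.normal(0, 0.03, n), 0.05, 0.95)
        bv1 = np.clip(bv5 * (0.28 + rng.normal(0, 0.02, n)), 0.01, None)
        bv10 = np.clip(bv5 + 0.25 + rng.normal(0, 0.02, n), None, 1.0)
        df["bv1_tbv"], df["bv5_tbv"], df["bv10_tbv"] = bv1, bv5, bv10

        # pulmonary function tied to emphysema within category
        mean_emph = 0.05 + 0.022 * es * c
        df["fev1_pp"] = rng.normal(*p.fev1_pp, size=n)
        df["fvc_pp"] = rng.normal(*p.fvc_pp, size=n)
        df["fev1_fvc"] = (p.fev1_fvc[0] - 60.0 * es * (emph - mean_emph)
                          + rng.normal(0.0, 0.7 * p.fev1_fvc[1], size=n))

        # missingness: MAR conditional on category, structural columns only
        if p.missing_rate > 0:
            for col in IMAGING_COLUMNS:
                miss = rng.random(n) < p.missing_rate
                df.loc[miss, col] = np.nan
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    return out


def structural_columns(df: pd.DataFrame) -> list[str]:
    """The per-branch structural metric columns (the imputation targets)."""
    return [c for c in df.columns if c.startswith(STRUCTURAL_PREFIXES)]
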