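"""Clinical scoring and group statistics.

Cognitive test scores are standardised against age-banded norm tables
(z = (score - norm mean) / norm SD); mild cognitive impairment follows the
Level-II actuarial rule — a deficit of at least 1.5 SD below the
age-matched norm in at least two tests, regardless of domain.  Motor
lateralisation is the side with the higher UPDRS-III hemibody sum.

Two-group comparisons are gated by Shapiro-Wilk normality (Welch's t when
both groups look normal, Mann-Whitney U otherwise); three or more groups
use Kruskal-Wallis with pairwise rank tests under Bonferroni-Holm
correction; covariate-adjusted comparisons use a linear model with type-II
sums of squares and generalised eta-squared effect sizes
(SS_effect / (SS_effect + SS_error)).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormTable",
    "cognitive_z_scores",
    "classify_mci",
    "motor_lateralisation",
    "group_compare_auto",
    "multigroup_compare",
    "ancova_geta",
]


class NormTable:
    """Age-banded norms per cognitive test: columns test, age_min, age_max, mean, sd."""

    REQUIRED = ("test", "age_min", "age_max", "mean", "sd")

    def __init__(self, frame: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"norm table missing column {col!r}")
        if (frame["sd"] <= 0).any():
            raise ValueError("norm SD must be positive")
        self.frame = frame.reset_index(drop=True)

    def lookup(self, test: str, age: float) -> tuple[float, float]:
        hit = self.frame[
            (self.frame["test"] == test)
            & (self.frame["age_min"] <= age)
            & (age <= self.frame["age_max"])
        ]
        if hit.empty:
            raise KeyError(f"no norm row for test {test!r} at age {age}")
        row = hit.iloc[0]
        return float(row["mean"]), float(row["sd"])


def cognitive_z_scores(
    scores: dict[str, float], age: float, norms: NormTable
) -> tuple[dict[str, float], float]:
    """Per-test z-scores against age-matched norms, plus the composite.

    The composite cognition z is the unweighted mean of the available
    per-test z-scores; tests with missing (NaN) scores are skipped.
    """
    z: dict[str, float] = {}
    for test, score in scores.items():
        if score is None or (isinstance(score, float) and np.isnan(score)):
            continue
        mean, sd = norms.lookup(test, age)
        z[test] = (float(score) - mean) / sd
    if not z:
        raise ValueError("no scorable tests")
    composite = float(np.mean(list(z.values())))
    return z, composite


def classify_mci(
    per_test_z: dict[str, float] | list[float],
    *,
    threshold: float = 1.5,
    min_tests: int = 2,
) -> str:
    """Level-II rule: MCI iff >= min_tests tests fall >= threshold SD below norms.

    The boundary is inclusive (z <= -1.5 counts as a deficit).  Returns
    'MCI', 'NC', or 'unclassifiable' when fewer than min_tests tests are
    available.
    """
    z_vals = list(per_test_z.values()) if isinstance(per_test_z, dict) else list(per_test_z)
    z_vals = [z for z in z_vals if np.isfinite(z)]
    if len(z_vals) < min_tests:
        return "unclassifiable"
    deficits = sum(1 for z in z_vals if z <= -threshold)
    return "MCI" if deficits >= min_tests else "NC"


def motor_lateralisation(right_sum: float, left_sum: float) -> str:
    """Side with the higher UPDRS-III hemibody sum (more affected side)."""
    if not (np.isfinite(right_sum) and np.isfinite(left_sum)):
        return "unclassifiable"
    if right_sum > left_sum:
        return "right"
    if left_sum > right_sum:
        return "left"
    return "symmetric"


@dataclasses.dataclass
class GroupCompareReport:
    branch: str              # "welch" | "mannwhitney"
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float


def group_compare_auto(a, b, *, normality_alpha: float = 0.05) -> GroupCompareReport:
    """Welch's t or Mann-Whitney U, gated by Shapiro-Wilk in both groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0   # constant group: clearly non-normal, rank branch
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa > normality_alpha and pb > normality_alpha:
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupCompareReport("welch", float(res.statistic), float(res.pvalue), pa, pb)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupCompareReport("mannwhitney", float(res.statistic), float(res.pvalue), pa, pb)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="holm")[1]


@dataclasses.dataclass
class MultiGroupReport:
    h_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame   # group_a, group_b, u_stat, p_raw, p_holm


def multigroup_compare(groups: dict[str, np.ndarray]) -> MultiGroupReport:
    """Kruskal-Wallis omnibus plus pairwise rank tests with Holm correction."""
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    for name, vals in groups.items():
        if np.asarray(vals).size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
            u, praw = arrays[i].size * arrays[j].size / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            u, praw = float(res.statistic), float(res.pvalue)
        rows.append({"group_a": a, "group_b": b, "u_stat": u, "p_raw": praw})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    return MultiGroupReport(float(h), float(p), pairwise)


def ancova_geta(
    data: pd.DataFrame,
    value: str,
    group: str,
    covariates: list[str],
    *,
    condition_limit: float = 1e8,
) -> pd.DataFrame:
    """Group comparison adjusted for covariates, with generalised eta-squared.

    Fits ``value ~ group + covariates`` (no interactions), computes type-II
    sums of squares, and reports per-term F, p and
    eta2_g = SS_term / (SS_term + SS_error).
    """
    cols = [value, group] + covariates
    frame = data[cols].dropna().copy()
    if len(frame) <= len(covariates) + 3:
        raise ValueError("too few complete observations for the model")
    numeric = frame[covariates].to_numpy(dtype=float)
    if covariates:
        design = np.column_stack([np.ones(len(frame)), numeric])
        if np.linalg.cond(design) > condition_limit:
            raise ValueError("collinear covariates (condition number guard)")
    terms = " + ".join([f"C({group})"] + covariates)
    model = smf.ols(f"{value} ~ {terms}", data=frame).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    ss_error = float(anova.loc["Residual", "sum_sq"])
    rows = []
    for term in anova.index:
        if term == "Residual":
            continue
        ss = float(anova.loc[term, "sum_sq"])
        rows.append(
            {
                "term": term.replace(f"C({group})", group),
                "F": float(anova.loc[term, "F"]),
                "p": float(anova.loc[term, "PR(>F)"]),
                "eta2_g": ss / (ss + ss_error) if (ss + ss_error) > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
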