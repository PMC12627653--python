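"""Glucose-dynamics statistics on ROI time series.

Within-subject variation of the (normalised) metabolic signal is
summarised by the coefficient of variation, Vc(%) = sigma / xbar * 100,
and its reciprocal companion, the temporal signal-to-noise ratio
tSNR = mu_s / sigma_s.  Both use the sample (n-1) standard deviation, so
tSNR = 100 / Vc holds as an exact identity and is enforced as a
cross-check in the test-suite.

Group differences are assessed by a two-sided permutation test on the
absolute group-mean difference (exhaustive relabelling when feasible), the
rank effect size r = |Z| / sqrt(n) from the tie-corrected normal
approximation of the Mann-Whitney U, and associations with clinical
variables by Pearson (default) or Spearman correlation.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import RoiTimeSeries

__all__ = [
    "coefficient_of_variation",
    "tsnr",
    "permutation_group_test",
    "rank_effect_size_r",
    "correlate_with_clinical",
    "cov_table",
]

_MEAN_TOL = 1e-12
_EXHAUSTIVE_LIMIT = 20_000


def _values(ts) -> np.ndarray:
    if isinstance(ts, RoiTimeSeries):
        return ts.values
    return np.asarray(ts, dtype=float)


def coefficient_of_variation(ts) -> float:
    """Vc(%) = sample SD / mean * 100 of an ROI series."""
    x = _values(ts)
    if x.size < 2:
        raise ValueError("need at least 2 frames for a coefficient of variation")
    mean = x.mean()
    if mean <= _MEAN_TOL:
        raise ValueError("non-positive mean; CoV undefined")
    return float(x.std(ddof=1) / mean * 100.0)


def tsnr(ts) -> float:
    """Temporal SNR mu/sigma; NaN flags a zero-variance (undefined) series."""
    x = _values(ts)
    if x.size < 2:
        raise ValueError("need at least 2 frames for tSNR")
    sd = x.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float(x.mean() / sd)


def permutation_group_test(
    a, b, *, n_perm: int = 10_000, seed: int = 0, statistic: str = "mean_diff"
) -> tuple[float, float]:
    """Two-sided permutation test on the group mean difference.

    Exhaustive over all C(n_a+n_b, n_a) relabellings when that count is at
    most 20,000 (p = #{|stat| >= |observed|} / m, the identity labelling
    included), Monte-Carlo with the add-one correction otherwise.
    Returns (observed difference a-b, two-sided p).
    """
    if statistic != "mean_diff":
        raise ValueError("only the mean-difference statistic is implemented")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    observed = a.mean() - b.mean()
    obs_abs = abs(observed)
    if np.ptp(pooled) == 0:
        return float(observed), 1.0

    total_sum = pooled.sum()

    def diff_for(sum_a: float) -> float:
        return sum_a / n_a - (total_sum - sum_a) / (n - n_a)

    m_total = math.comb(n, n_a)
    if m_total <= _EXHAUSTIVE_LIMIT:
        count = 0
        for members in combinations(range(n), n_a):
            if abs(diff_for(pooled[list(members)].sum())) >= obs_abs - 1e-12:
                count += 1
        return float(observed), count / m_total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        members = rng.permutation(n)[:n_a]
        if abs(diff_for(pooled[members].sum())) >= obs_abs - 1e-12:
            count += 1
    return float(observed), (1 + count) / (n_perm + 1)


def rank_effect_size_r(a, b) -> float:
    """Rank effect size r = |Z| / sqrt(n) for the Mann-Whitney U.

    Z is the tie-corrected normal approximation (no continuity
    correction); r lies in [0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 values per group")
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    z = (u_a - mu) / math.sqrt(var)
    return float(abs(z) / math.sqrt(n))


def correlate_with_clinical(
    values: pd.Series | dict,
    clinical: pd.Series | dict,
    *,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlate a per-subject measure with a clinical variable.

    Inputs are keyed by subject id; pairs missing on either side (or
    non-finite) are dropped.  Returns (r, two-sided p, n used).
    """
    v = pd.Series(values, dtype=float)
    c = pd.Series(clinical, dtype=float)
    joined = pd.concat([v.rename("v"), c.rename("c")], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if joined["v"].nunique() < 2 or joined["c"].nunique() < 2:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r, p = stats.pearsonr(joined["v"], joined["c"])
    elif method == "spearman":
        r, p = stats.spearmanr(joined["v"], joined["c"])
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p), n


def cov_table(series: list[RoiTimeSeries]) -> pd.DataFrame:
    """One row per subject-region: Vc(%) and tSNR."""
    rows = []
    for ts in series:
        rows.append(
            {
                "subject": ts.subject,
                "region": ts.region,
                "vc_percent": coefficient_of_variation(ts),
                "tsnr": tsnr(ts),
                "normalization": ts.normalization,
                "n_frames": ts.values.size,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.duplicated(["subject", "region"]).any():
        raise ValueError("duplicate subject-region pair")
    return frame
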