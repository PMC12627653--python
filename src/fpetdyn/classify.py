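"""Group classification from extracted cluster uptake values.

A maximum-likelihood logistic model on per-subject mean normalised uptake
values (in-sample, as is conventional for small descriptive cohorts), with
the ROC built over the fitted probabilities and the AUC computed through
the rank (Mann-Whitney) identity with mid-rank tie handling.  Complete
separation is detected and flagged: the ranking — and hence the ROC/AUC —
remains valid, but coefficient magnitudes are not identifiable and a tiny
ridge penalty is engaged to stabilise them.  Cohen's d with the pooled
standard deviation quantifies per-cluster effect sizes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

__all__ = ["FeatureMatrix", "cohens_d", "rank_auc", "logistic_roc", "LogisticRocResult"]


@dataclasses.dataclass
class FeatureMatrix:
    """Subjects x cluster-mean-uptake features with binary group labels."""

    features: pd.DataFrame       # index: subject ids, columns: feature names
    labels: pd.Series            # 1 = positive class (e.g. PD), 0 = negative
    feature_kind: dict[str, str] = dataclasses.field(default_factory=dict)  # name -> hypo|hyper

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("missing cells in the feature matrix")
        labs = set(pd.unique(self.labels))
        if not labs <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(labs) < 2:
            raise ValueError("both classes must be present")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("feature and label indices differ")

    def subset(self, which: str) -> "FeatureMatrix":
        """Select 'all', 'hypo' or 'hyper' features."""
        if which == "all":
            return self
        cols = [c for c, k in self.feature_kind.items() if k == which]
        if not cols:
            raise ValueError(f"no features of kind {which!r}")
        return FeatureMatrix(self.features[cols], self.labels,
                             {c: self.feature_kind[c] for c in cols})


def cohens_d(a, b) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def rank_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney identity, mid-rank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclasses.dataclass
class LogisticRocResult:
    scores: pd.Series            # fitted P(positive class) per subject
    coefficients: pd.Series
    intercept: float
    roc: pd.DataFrame            # fpr, tpr, threshold
    auc: float
    separation: bool             # coefficients non-identifiable when True


def _perfectly_separated(scores: np.ndarray, labels: np.ndarray) -> bool:
    return scores[labels == 1].min() > scores[labels == 0].max()


def logistic_roc(matrix: FeatureMatrix, feature_subset: str = "all") -> LogisticRocResult:
    """In-sample logistic fit, ROC over fitted probabilities, rank-identity AUC."""
    sub = matrix.subset(feature_subset)
    X = sub.features.to_numpy(dtype=float)
    y = sub.labels.to_numpy(dtype=int)
    n, k = X.shape
    ridge = n <= k   # more features than subjects: engage the guard up front
    model = LogisticRegression(C=(1.0 / 1e-6 if ridge else np.inf),
                               solver="lbfgs", max_iter=5000)
    model.fit(X, y)
    probs = model.predict_proba(X)[:, 1]
    separated = _perfectly_separated(probs, y)
    if separated and not ridge:
        # ML estimates diverge under complete separation; refit with a tiny
        # ridge so the reported coefficients are finite (AUC is unaffected
        # by the penalty through the rank identity)
        model = LogisticRegression(C=1.0 / 1e-6, solver="lbfgs", max_iter=5000)
        model.fit(X, y)
        probs = model.predict_proba(X)[:, 1]
    fpr, tpr, thr = roc_curve(y, probs)
    auc = rank_auc(probs, y)
    return LogisticRocResult(
        scores=pd.Series(probs, index=sub.features.index, name="p_positive"),
        coefficients=pd.Series(model.coef_.ravel(), index=sub.features.columns),
        intercept=float(model.intercept_[0]),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        auc=auc,
        separation=bool(separated),
    )
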