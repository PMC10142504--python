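"""Cohort-level validation statistics.

Distribution gate (Lilliefors-style Kolmogorov-Smirnov), Mann-Whitney U
group comparisons of the imaging features, point-biserial Pearson
concordance between PP and the reference label, ROC/AUC with TP+mixed as
the positive class, and leave-one-out cross-validation with per-fold
refitting of the logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut
from statsmodels.stats.diagnostic import lilliefors

from .model import PSP, TP_MIXED, ProgressionClassifier

__all__ = [
    "ks_normality_gate",
    "mann_whitney",
    "concordance_pearson",
    "concordance_lin_ccc",
    "roc_auc",
    "ROCResult",
    "loocv",
    "LoocvResult",
]


def ks_normality_gate(values, alpha: float = 0.05) -> dict:
    """Advisory normality gate: Lilliefors KS test against a normal with
    the sample's own mean/SD.

    Returns {'distribution': 'gaussian'|'non_gaussian', 'p': float,
    'degenerate': bool}. A constant sample is flagged degenerate and
    reported non-Gaussian. The pipeline proceeds nonparametrically either
    way; the gate only documents the distributional character.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(values) == 0:
        return {"distribution": "non_gaussian", "p": 0.0, "degenerate": True}
    _, p = lilliefors(values, dist="norm")
    verdict = "non_gaussian" if p < alpha else "gaussian"
    return {"distribution": verdict, "p": float(p), "degenerate": False}


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U for group A).

    Exact enumeration when n_a + n_b <= 12 and the pooled sample is
    tie-free; the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def concordance_pearson(pp, truth_labels) -> tuple[float, float]:
    """Point-biserial Pearson r between PP and the 0/1 reference coding
    (PsP=0, TP+mixed=1), with the two-sided t-test p-value."""
    pp = np.asarray(pp, dtype=float)
    coded = _code_labels(truth_labels)
    if pp.size < 3:
        raise ValueError("need at least 3 cases")
    if np.ptp(pp) == 0 or np.ptp(coded) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(pp, coded)
    return float(r), float(p)


def concordance_lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (alternative reading of
    the concordance statistic; not the default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(), y.var()
    return float(2 * np.cov(x, y, bias=True)[0, 1] / (vx + vy + (x.mean() - y.mean()) ** 2))


def _code_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "ifb":
        return labels.astype(float)
    return (labels == TP_MIXED).astype(float)


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    positive_class: str = TP_MIXED


def roc_auc(scores, truth_labels, positive: str = TP_MIXED) -> ROCResult:
    """ROC curve and AUC with tumor progression as the positive class.

    AUC follows the Mann-Whitney pairwise formulation: the fraction of
    (positive, negative) pairs ranked concordantly, ties credited 1/2 —
    computed here from the trapezoidal area under the threshold-swept
    curve, which is algebraically identical.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(truth_labels)
    pos = y == positive
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(pos.astype(int), scores)
    if np.ptp(scores) == 0:
        auc = 0.5  # all ties: every pair credited 1/2
    else:
        auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thresholds)


@dataclass
class LoocvResult:
    held_out_labels: np.ndarray
    correct: np.ndarray
    accuracy: float
    fold_coefficients: np.ndarray
    n_flagged: int = 0
    flagged_folds: list = field(default_factory=list)


def loocv(X, y, refit: bool = True, ridge: float = 1e-4) -> LoocvResult:
    """Leave-one-out cross-validation of the logistic model.

    With ``refit`` the three-feature logistic model is re-estimated by
    maximum likelihood on each n-1 training fold (ridge fallback under
    separation) and the held-out case is classified at PP >= 0.5.
    ``refit=False`` degenerates to fixed-coefficient classification, whose
    accuracy equals the plain cohort concordance. Folds whose training set
    lacks a class are flagged and excluded from the accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 cases")
    held, correct, coefs, flagged = [], [], [], []
    for fold, (train, test) in enumerate(LeaveOneOut().split(X)):
        if refit and np.unique(y[train]).size < 2:
            flagged.append(fold)
            held.append(None)
            correct.append(False)
            coefs.append(np.full(4, np.nan))
            continue
        clf = ProgressionClassifier(
            coefficients=None if refit else ProgressionClassifier().coefficients,
            ridge=ridge,
        )
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])[0]
        held.append(pred)
        correct.append(pred == y[test][0])
        coefs.append(np.concatenate([clf.intercept_, clf.coef_.ravel()]))
    keep = [i for i in range(n) if i not in flagged]
    acc = float(np.mean([correct[i] for i in keep])) if keep else float("nan")
    return LoocvResult(
        held_out_labels=np.asarray(held, dtype=object),
        correct=np.asarray(correct, dtype=bool),
        accuracy=acc,
        fold_coefficients=np.asarray(coefs),
        n_flagged=len(flagged),
        flagged_folds=flagged,
    )
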