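"""The multiparametric predictive-probability model and cohort concordance.

The classifier is the published three-parameter logistic model

    PP = 1 / (1 + exp(-(b0 + b1*FA + b2*CL + b3*rCBVmax)))

with fixed coefficients b0 = -16.17, b1 = 194.01, b2 = -285.65, b3 = 1.21
estimated on a prior surgical cohort. PP is the predictive probability of
tumor progression; a lesion is called pseudoprogression (PsP) when
PP < 50% and tumor progression / mixed tumor (TP+mixed) when PP >= 50%
(the boundary is inclusive on the progression side).

`ProgressionClassifier` wraps this as a scikit-learn estimator: with
`coefficients` set (the default) `fit` only records the class labels and
prediction uses the fixed published model; with `coefficients=None` the
logistic model is refit by maximum likelihood (with a small ridge fallback
under separation), which is how leave-one-out cross-validation re-estimates
the model per fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "PSP",
    "TP_MIXED",
    "ModelCoefficients",
    "ProgressionClassifier",
    "ConfusionSummary",
    "predictive_probability",
    "classify",
    "summarize_cohort",
    "label_from_percent_malignant",
]

PSP = "PsP"
TP_MIXED = "TP+mixed"

#: percent malignant features at/above which histopathology is called TP+mixed
MALIGNANT_PERCENT_THRESHOLD = 25.0


@dataclass(frozen=True)
class ModelCoefficients:
    """Logistic coefficients (intercept, FA, CL, rCBVmax)."""

    beta0: float = -16.17
    beta1: float = 194.01
    beta2: float = -285.65
    beta3: float = 1.21

    def logit(self, fa, cl, rcbv_max) -> np.ndarray:
        return (
            self.beta0
            + self.beta1 * np.asarray(fa, dtype=float)
            + self.beta2 * np.asarray(cl, dtype=float)
            + self.beta3 * np.asarray(rcbv_max, dtype=float)
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelCoefficients":
        payload = json.loads(Path(path).read_text())
        return cls(
            beta0=float(payload["beta0"]),
            beta1=float(payload["beta1"]),
            beta2=float(payload["beta2"]),
            beta3=float(payload["beta3"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "beta0": self.beta0,
                    "beta1": self.beta1,
                    "beta2": self.beta2,
                    "beta3": self.beta3,
                    "features": ["fa_median", "cl_median", "rcbv_max"],
                },
                indent=2,
            )
        )


def predictive_probability(
    fa, cl, rcbv_max, coef: ModelCoefficients | None = None
) -> np.ndarray | float:
    """PP of tumor progression; numerically safe for |logit| up to ~700."""
    coef = coef or ModelCoefficients()
    feats = [np.asarray(v, dtype=float) for v in (fa, cl, rcbv_max)]
    if any(not np.all(np.isfinite(f)) for f in feats):
        raise ValueError("non-finite feature value")
    pp = expit(coef.logit(*feats))
    return float(pp) if np.isscalar(fa) else pp


def classify(pp, threshold: float = 0.5):
    """PsP if PP < threshold, TP+mixed if PP >= threshold (inclusive)."""
    arr = np.asarray(pp, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("predictive probability outside [0, 1]")
    labels = np.where(arr >= threshold, TP_MIXED, PSP)
    return str(labels) if np.isscalar(pp) else labels


def label_from_percent_malignant(percent: float) -> str:
    """Histopathologic label: PsP below 25% malignant features, else TP+mixed.

    The boundary value 25% is assigned to TP+mixed, mirroring the
    inclusive '>=' of the PP decision rule.
    """
    return TP_MIXED if percent >= MALIGNANT_PERCENT_THRESHOLD else PSP


class ProgressionClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator for the PsP vs TP+mixed logistic model.

    Parameters
    ----------
    coefficients : ModelCoefficients or None
        Fixed published coefficients (default). ``None`` refits the
        logistic model on the training data in `fit`.
    threshold : float
        PP decision boundary; the boundary itself maps to TP+mixed.
    ridge : float
        L2 penalty applied only as a fallback when the unpenalized
        maximum-likelihood fit diverges (complete separation).

    `X` is (n_samples, 3): columns (fa_median, cl_median, rcbv_max).
    """

    def __init__(
        self,
        coefficients: ModelCoefficients | None = ModelCoefficients(),
        threshold: float = 0.5,
        ridge: float = 1e-4,
    ):
        self.coefficients = coefficients
        self.threshold = threshold
        self.ridge = ridge

    def fit(self, X, y):
        X = check_array(X)
        if X.shape[1] != 3:
            raise ValueError("expected 3 features: fa_median, cl_median, rcbv_max")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.coefficients is not None:
            self.coef_ = self.coefficients.as_array()[1:].reshape(1, -1)
            self.intercept_ = np.array([self.coefficients.beta0])
            self.refit_ = False
            return self
        if len(self.classes_) < 2:
            raise ValueError("refitting requires both classes in the training data")
        y01 = (y == self._positive_class()).astype(int)
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        with np.errstate(over="ignore"):
            lr.fit(X, y01)
        if not np.all(np.isfinite(lr.coef_)) or np.max(np.abs(lr.coef_)) > 1e4:
            # separation: small ridge restores a finite maximum
            lr = LogisticRegression(C=1.0 / self.ridge, solver="lbfgs", max_iter=2000)
            lr.fit(X, y01)
        self.coef_ = lr.coef_.copy()
        self.intercept_ = lr.intercept_.copy()
        self.refit_ = True
        return self

    def _positive_class(self):
        # progression is the positive class whenever the labels are the
        # canonical strings; otherwise the larger label (e.g. 1 of {0,1})
        return TP_MIXED if TP_MIXED in getattr(self, "classes_", []) else self.classes_[-1]

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_.ravel() + self.intercept_[0]

    def predict_proba(self, X):
        pp = expit(self.decision_function(X))
        return np.column_stack([1.0 - pp, pp])

    def predict(self, X):
        pp = self.predict_proba(X)[:, 1]
        pos = self._positive_class()
        neg = self.classes_[self.classes_ != pos][0] if len(self.classes_) > 1 else PSP
        return np.where(pp >= self.threshold, pos, neg)


@dataclass
class ConfusionSummary:
    """Per-class correct counts and rates for the two-group cohort."""

    n_psp: int
    n_psp_correct: int
    n_tp: int
    n_tp_correct: int

    @property
    def concordance_pct(self) -> float:
        total = self.n_psp + self.n_tp
        return 100.0 * (self.n_psp_correct + self.n_tp_correct) / total

    @property
    def psp_correct_pct(self) -> float:
        return 100.0 * self.n_psp_correct / self.n_psp if self.n_psp else float("nan")

    @property
    def tp_correct_pct(self) -> float:
        return 100.0 * self.n_tp_correct / self.n_tp if self.n_tp else float("nan")

    def rounded(self) -> dict:
        """Integer percents (half-up) for human-readable reports."""

        def half_up(x: float) -> int | None:
            return None if np.isnan(x) else int(np.floor(x + 0.5))

        return {
            "psp_correct_pct": half_up(self.psp_correct_pct),
            "tp_correct_pct": half_up(self.tp_correct_pct),
            "concordance_pct": half_up(self.concordance_pct),
        }


def summarize_cohort(predicted, truth) -> ConfusionSummary:
    """Per-class concordance of predicted vs reference labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predictions and truths must align case by case")
    psp = truth == PSP
    tp = truth == TP_MIXED
    return ConfusionSummary(
        n_psp=int(psp.sum()),
        n_psp_correct=int((predicted[psp] == PSP).sum()),
        n_tp=int(tp.sum()),
        n_tp_correct=int((predicted[tp] == TP_MIXED).sum()),
    )
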