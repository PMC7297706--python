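"""Infer myopia status from age-of-onset of spectacle wear (AOSW).

A logistic model of myopia (refractive error at or below a dioptre cut)
on AOSW is fitted in individuals with both phenotypes.  Two probability
thresholds are then read off the empirical ROC curve: one calling "myopic"
with at least 90% specificity, one calling "non-myopic" while retaining at
least 90% sensitivity for myopia.  Individuals between the thresholds are
left unclassified and excluded from downstream association fits.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import statsmodels.api as sm
from sklearn.metrics import roc_curve

MYOPIC = "myopic"
NON_MYOPIC = "non_myopic"
UNCLASSIFIED = "unclassified"

#: Default myopia definition (dioptres, mean spherical equivalent).  This is a
#: common epidemiological cut; it is configurable everywhere it is used.
DEFAULT_MYOPIA_CUT = -0.75


class FitError(RuntimeError):
    """Raised when the logistic fit cannot be computed or did not converge."""


@dataclasses.dataclass
class AoswClassifier:
    """Fitted AOSW logistic model plus dual ROC probability thresholds."""

    intercept: float
    slope: float
    threshold_spec90: float
    threshold_sens90: float
    myopia_cut: float
    specificity_target: float = 0.90
    sensitivity_target: float = 0.90
    achieved_specificity: float = float("nan")
    achieved_sensitivity: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 < self.threshold_spec90 < 1 and 0 < self.threshold_sens90 < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.threshold_spec90 < self.threshold_sens90:
            raise ValueError(
                "high-confidence myopic threshold must be at least as "
                "stringent as the non-myopic threshold"
            )

    def predict_proba(self, aosw) -> np.ndarray:
        """P(myopic | AOSW); NaN AOSW gives NaN probability."""
        aosw = np.asarray(aosw, dtype=float)
        eta = self.intercept + self.slope * aosw
        return 1.0 / (1.0 + np.exp(-eta))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "AoswClassifier":
        with open(path) as fh:
            return cls(**json.load(fh))


def _logistic_mle(aosw: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    import warnings

    X = sm.add_constant(aosw)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            raise FitError(f"logistic fit did not converge: {res.mle_retvals}")
        if not np.all(np.isfinite(res.params)):
            raise FitError("logistic fit produced non-finite coefficients")
        return float(res.params[0]), float(res.params[1])
    except Exception as exc:
        # Perfectly separated data: the MLE diverges but the probability
        # *ranking* stays well defined, so a lightly ridge-penalized fit
        # still yields usable ROC thresholds.  Anything else is rejected.
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000)
        lr.fit(aosw.reshape(-1, 1), y)
        prob = lr.predict_proba(aosw.reshape(-1, 1))[:, 1]
        if roc_auc_score(y, prob) == 1.0:
            return float(lr.intercept_[0]), float(lr.coef_[0, 0])
        raise FitError(f"logistic fit failed: {exc}") from exc


def fit_aosw_classifier(
    refractive_error,
    aosw,
    myopia_cut: float = DEFAULT_MYOPIA_CUT,
    specificity: float = 0.90,
    sensitivity: float = 0.90,
) -> AoswClassifier:
    """Fit the AOSW logistic model and derive the dual ROC thresholds.

    Individuals missing either phenotype are dropped.  The "myopic" threshold
    is the least extreme probability cut with specificity >= ``specificity``
    (ties resolved toward maximum sensitivity); the "non-myopic" threshold is
    the least extreme cut below which at most ``1 - sensitivity`` of true
    myopes fall.
    """
    re = np.asarray(refractive_error, dtype=float)
    ao = np.asarray(aosw, dtype=float)
    keep = ~(np.isnan(re) | np.isnan(ao))
    re, ao = re[keep], ao[keep]
    # sort so the fit (and hence the thresholds) is invariant to input order
    order = np.lexsort((re, ao))
    re, ao = re[order], ao[order]
    y = (re <= myopia_cut).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise FitError(
            f"need >= 2 individuals per myopia class, got {n_pos} myopic / "
            f"{n_neg} non-myopic at cut {myopia_cut}"
        )

    intercept, slope = _logistic_mle(ao, y)
    prob = 1.0 / (1.0 + np.exp(-(intercept + slope * ao)))

    fpr, tpr, thr = roc_curve(y, prob, drop_intermediate=False)
    # roc_curve thresholds are decreasing; prediction positive iff prob >= thr.
    ok_spec = fpr <= 1.0 - specificity
    if not ok_spec.any():
        raise FitError("no probability cut achieves the target specificity")
    i = np.flatnonzero(ok_spec)[-1]       # smallest qualifying cut -> max tpr
    t_spec = float(min(max(thr[i], 1e-12), 1 - 1e-12))
    spec_achieved = 1.0 - float(fpr[i])
    sens_at_spec = float(tpr[i])

    ok_sens = tpr >= sensitivity
    if not ok_sens.any():
        raise FitError("no probability cut achieves the target sensitivity")
    j = np.flatnonzero(ok_sens)[0]        # largest qualifying cut -> max spec
    # Individuals strictly below thr[j] are the ones the cut labels negative;
    # use the midpoint down to the next lower achieved probability so the
    # "<= threshold" classification rule reproduces the ROC operating point.
    lower = prob[prob < thr[j]]
    t_sens = float(lower.max() if lower.size else thr[j] / 2.0)
    t_sens = float(min(max(t_sens, 1e-12), 1 - 1e-12))
    sens_achieved = float(tpr[j])
    t_sens = min(t_sens, t_spec)

    return AoswClassifier(
        intercept=intercept,
        slope=slope,
        threshold_spec90=t_spec,
        threshold_sens90=t_sens,
        myopia_cut=float(myopia_cut),
        specificity_target=specificity,
        sensitivity_target=sensitivity,
        achieved_specificity=spec_achieved,
        achieved_sensitivity=sens_achieved,
    )


def classify(classifier: AoswClassifier, aosw) -> np.ndarray:
    """Label individuals myopic / non-myopic / unclassified from AOSW.

    Probability >= threshold_spec90 -> myopic; <= threshold_sens90 ->
    non-myopic; in between (or missing AOSW) -> unclassified.  With collapsed
    thresholds the myopic rule takes precedence and nobody is unclassified.
    """
    prob = classifier.predict_proba(aosw)
    out = np.full(prob.shape, UNCLASSIFIED, dtype=object)
    out[~np.isnan(prob) & (prob >= classifier.threshold_spec90)] = MYOPIC
    out[~np.isnan(prob) & (prob <= classifier.threshold_sens90)
        & (out == UNCLASSIFIED)] = NON_MYOPIC
    return out
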