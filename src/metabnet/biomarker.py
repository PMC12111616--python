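"""Combined-metabolite biomarkers: binomial GLM + ROC.

Two metabolites are combined by a logistic (binomial GLM) score fitted
by iteratively reweighted least squares; the fitted probabilities are
swept into a ROC curve and the apparent (in-sample) AUC is reported,
which equals the Mann-Whitney U statistic of the scores up to ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffsel import COMPARISONS
from .errors import ConfigurationError
from .tables import FeatureTable


@dataclass
class GlmFit:
    """Logistic-regression fit (intercept + one coefficient per
    predictor, log-odds units)."""

    coef: np.ndarray               # [intercept, b1, ...]
    fitted: np.ndarray             # probabilities per sample
    converged: bool
    n_iter: int
    separation: bool               # quasi-complete separation detected
    feature_ids: list[str]

    def predict(self, x: np.ndarray) -> np.ndarray:
        eta = self.coef[0] + np.asarray(x, float) @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RocResult:
    """ROC curve points and area.

    The AUC equals both the trapezoidal area under the (FPR, TPR)
    polyline and the tie-halved Mann-Whitney identity U / (n1 * n0).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def fit_logistic(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GlmFit:
    """Maximum-likelihood logistic regression by IRLS.

    On quasi-separation (diverging coefficients / fitted probabilities
    pinned to 0 or 1) iteration stops at ``max_iter`` with the
    separation flag set; the fitted probabilities still rank samples,
    so the ROC and AUC remain well defined.  A constant predictor
    degrades to an intercept-only fit with a warning.
    """
    feature_ids = list(x.columns) if isinstance(x, pd.DataFrame) else []
    xm = np.atleast_2d(np.asarray(x, float))
    if xm.shape[0] == 1 and len(np.asarray(y)) != 1:
        xm = xm.T
    yv = np.asarray(y, float).ravel()
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ConfigurationError("y must be binary 0/1")
    if yv.min() == yv.max():
        raise ConfigurationError("both classes must be present")
    if xm.size:
        keep = [j for j in range(xm.shape[1]) if np.ptp(xm[:, j]) > 0]
        if len(keep) < xm.shape[1]:
            warnings.warn(
                "constant predictor dropped; intercept-only where none remain",
                stacklevel=2,
            )
            xm = xm[:, keep]
            feature_ids = [feature_ids[j] for j in keep] if feature_ids else []
    design = np.column_stack([np.ones(len(yv)), xm]) if xm.size else np.ones((len(yv), 1))

    beta = np.zeros(design.shape[1])
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = mu * (1.0 - mu)
        if np.abs(eta).max() > 30:
            separation = True
        grad = design.T @ (yv - mu)
        hess = design.T @ (design * np.maximum(w, 1e-10)[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = design @ beta
    fitted = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    # keep probabilities in the open interval even under separation
    fitted = np.clip(fitted, 1e-15, 1 - 1e-15)
    return GlmFit(beta, fitted, converged, it, separation, feature_ids)


def roc_curve(scores: np.ndarray, y: np.ndarray) -> RocResult:
    """ROC by a unique-threshold sweep; tied scores contribute half, so
    the trapezoidal area equals the Mann-Whitney U identity."""
    s = np.asarray(scores, float)
    yv = np.asarray(y, float).ravel()
    if yv.min() == yv.max():
        raise ConfigurationError("both classes must be present")
    n1 = int(yv.sum())
    n0 = len(yv) - n1
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yv[order]
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(1 - y_sorted)[idx]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr, tpr, thresholds, auc)


def combined_biomarker(
    table: FeatureTable,
    features: list[str],
    comparison: str | tuple[str, str] = "ra-hc",
    max_iter: int = 100,
) -> tuple[GlmFit, RocResult]:
    """End-to-end combined-metabolite biomarker: extract the feature
    pair (or single feature) for the disease-vs-HC samples,
    log-transform, fit the binomial GLM, and compute the apparent
    (in-sample) ROC from the fitted probabilities."""
    groups = COMPARISONS[comparison] if isinstance(comparison, str) else comparison
    missing = [f for f in features if f not in table.data.columns]
    if missing:
        raise ConfigurationError(f"feature(s) not in table: {missing}")
    labels = table.groups()
    keep = labels.index[labels.isin(groups)]
    sub = table.biological.loc[keep, features]
    if sub.isna().any().any():
        raise ConfigurationError("impute missing values before biomarker fitting")
    x = np.log(sub.to_numpy())
    y = (labels.loc[keep] == groups[1]).to_numpy(float)
    fit = fit_logistic(pd.DataFrame(x, columns=features), y, max_iter=max_iter)
    roc = roc_curve(fit.fitted, y)
    return fit, roc
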