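"""Pairwise differential analysis: log/Pareto scaling, OPLS-DA with
VIP scores, Wilcoxon-Mann-Whitney testing with Benjamini-Hochberg FDR,
and the combined VIP/significance selection rule.

OPLS-DA is fit with a NIPALS-style algorithm: class-orthogonal
variation is removed sequentially (orthogonal signal correction), then
a single predictive PLS1 component is extracted from the deflated
matrix.  With zero orthogonal components the model reduces exactly to
PLS1.  VIP is computed on the predictive component; by construction the
mean squared VIP over features equals one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .tables import FeatureTable

COMPARISONS = {
    "ra-hc": ("HC", "RA"),
    "sle-hc": ("HC", "SLE"),
    "ra-sle": ("SLE", "RA"),
}


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


def log_pareto(values: pd.DataFrame) -> pd.DataFrame:
    """Log-transform then Pareto-scale each feature:
    ``x -> (log x - mean) / sqrt(SD)``.

    Pareto scaling divides by the square root of the standard deviation,
    so a scaled feature's variance equals the SD of its log values.
    Zero-variance features are scaled to all zeros with a warning.
    """
    if (values <= 0).any().any():
        raise ConfigurationError("log_pareto requires strictly positive values")
    logged = np.log(values)
    sd = logged.std(ddof=1)
    zero = sd < 1e-10  # constants up to float rounding
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s) scaled to zeros",
            stacklevel=2,
        )
    centered = logged - logged.mean()
    scaled = centered.div(np.sqrt(sd))
    scaled.loc[:, zero] = 0.0
    return scaled


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    """Fitted OPLS-DA model for a two-class comparison."""

    weights: np.ndarray         # predictive weight vector w (unit norm)
    scores: np.ndarray          # predictive scores t
    loadings: np.ndarray        # predictive loadings p
    ortho_weights: np.ndarray   # (n_ortho, n_features)
    ortho_scores: np.ndarray    # (n_samples, n_ortho)
    ortho_loadings: np.ndarray  # (n_ortho, n_features)
    y: np.ndarray               # centered class coding actually fitted
    coef: float                 # regression of y on t
    ssy_explained: float        # SS of y explained by the predictive component
    feature_ids: list[str] = field(default_factory=list)

    @property
    def n_ortho(self) -> int:
        return self.ortho_scores.shape[1]

    def predict_scores(self, x_new: np.ndarray) -> np.ndarray:
        """Predictive scores for new (already scaled) observations."""
        x = np.asarray(x_new, float).copy()
        for a in range(self.n_ortho):
            t_o = x @ self.ortho_weights[a]
            x -= np.outer(t_o, self.ortho_loadings[a])
        return x @ self.weights

    def predict_y(self, x_new: np.ndarray) -> np.ndarray:
        return self.predict_scores(x_new) * self.coef


def fit_oplsda(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    n_ortho: int = 1,
    tol: float = 1e-12,
) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    x
        Column-scaled samples x features matrix.
    y
        Binary class coding (0/1 or boolean), at least 3 samples per class.
    n_ortho
        Number of orthogonal (class-unrelated) components removed before
        the single predictive component; 0 reduces the model to PLS1.
    """
    feature_ids = list(x.columns) if isinstance(x, pd.DataFrame) else []
    x = np.asarray(x, float)
    yv = np.asarray(y, float).ravel()
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ConfigurationError("y must be a 0/1 class coding")
    if min((yv == 0).sum(), (yv == 1).sum()) < 3:
        raise ConfigurationError("each class needs at least 3 samples")
    yc = yv - yv.mean()

    xd = x.copy()
    ow, os_, ol = [], [], []
    for _ in range(n_ortho):
        w = xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < tol:
            raise ConfigurationError(
                "no class-correlated variation left for an orthogonal component"
            )
        w /= nw
        t = xd @ w
        p = xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < tol:
            break  # no orthogonal variation remains
        w_o /= n_o
        t_o = xd @ w_o
        p_o = xd.T @ t_o / (t_o @ t_o)
        xd = xd - np.outer(t_o, p_o)
        ow.append(w_o)
        os_.append(t_o)
        ol.append(p_o)

    w = xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < tol:
        raise ConfigurationError("X carries no class-correlated variation")
    w /= nw
    t = xd @ w
    p = xd.T @ t / (t @ t)
    coef = float(t @ yc / (t @ t))
    ssy = float(coef**2 * (t @ t))

    n = len(yv)
    return OplsModel(
        weights=w,
        scores=t,
        loadings=p,
        ortho_weights=np.array(ow).reshape(len(ow), x.shape[1]),
        ortho_scores=(
            np.array(os_).T.reshape(n, len(os_)) if os_ else np.empty((n, 0))
        ),
        ortho_loadings=np.array(ol).reshape(len(ol), x.shape[1]),
        y=yc,
        coef=coef,
        ssy_explained=ssy,
        feature_ids=feature_ids,
    )


def vip_scores(model: OplsModel) -> pd.Series | np.ndarray:
    """Variable importance in projection on the predictive component(s):
    ``VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a)``.
    With one predictive component of unit-norm weights this is
    ``sqrt(p) * |w_j|``, so the mean of VIP^2 is exactly 1."""
    if model.ssy_explained <= 0:
        raise ConfigurationError("model explains no class variance; VIP undefined")
    p = len(model.weights)
    vip = np.sqrt(p * model.ssy_explained * model.weights**2 / model.ssy_explained)
    if model.feature_ids:
        return pd.Series(vip, index=model.feature_ids, name="vip")
    return vip


def cross_val_q2(
    x: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 1,
    n_folds: int = 7,
    seed: int = 0,
) -> float:
    """Cross-validated Q2 of the OPLS-DA class prediction.

    Q2 = 1 - PRESS / SS; at or below zero the model predicts class no
    better than the training-class mean (the permutation-null regime).
    """
    x = np.asarray(x, float)
    yv = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(yv))
    folds = np.array_split(order, n_folds)
    press = ss = 0.0
    for held in folds:
        mask = np.ones(len(yv), bool)
        mask[held] = False
        if min((yv[mask] == 0).sum(), (yv[mask] == 1).sum()) < 3:
            continue
        model = fit_oplsda(x[mask], yv[mask], n_ortho)
        yhat = model.predict_y(x[held]) + yv[mask].mean()
        press += float(((yv[held] - yhat) ** 2).sum())
        ss += float(((yv[held] - yv[mask].mean()) ** 2).sum())
    return 1.0 - press / ss


# ---------------------------------------------------------------------------
# univariate testing and selection
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    """Per-feature differential statistics for one pairwise comparison.

    ``frame`` columns: ``p_value``, ``q_value`` (Benjamini-Hochberg),
    ``fold_change`` (ratio of raw-scale group medians, group2/group1),
    and after selection ``vip`` and ``selected``.
    """

    comparison: tuple[str, str]
    frame: pd.DataFrame

    @property
    def selected(self) -> list[str]:
        if "selected" not in self.frame:
            raise ConfigurationError("selection rule has not been applied")
        return list(self.frame.index[self.frame["selected"]])


def univariate_test(
    table: FeatureTable, groups: tuple[str, str]
) -> DifferentialResult:
    """Two-sided Mann-Whitney test per feature (tie-corrected, exact
    for small untied samples) with BH FDR across the comparison's
    features; fold change is the ratio of raw-scale group medians
    (group2 / group1)."""
    labels = table.groups()
    bio = table.biological
    a = bio.loc[labels.index[labels == groups[0]]]
    b = bio.loc[labels.index[labels == groups[1]]]
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError(
            f"groups {groups} need at least 2 samples each ({len(a)}, {len(b)})"
        )
    pvals = np.ones(bio.shape[1])
    av, bv = a.to_numpy(), b.to_numpy()
    for j in range(bio.shape[1]):
        x, yj = av[:, j], bv[:, j]
        x, yj = x[np.isfinite(x)], yj[np.isfinite(yj)]
        if len(x) < 2 or len(yj) < 2 or (np.ptp(x) == 0 and np.ptp(yj) == 0
                                         and x[0] == yj[0]):
            pvals[j] = 1.0
            continue
        pvals[j] = stats.mannwhitneyu(x, yj, alternative="two-sided").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    fold = (b.median() / a.median()).to_numpy()
    frame = pd.DataFrame(
        {"p_value": pvals, "q_value": qvals, "fold_change": fold},
        index=bio.columns,
    ).rename_axis("feature_id")
    return DifferentialResult(groups, frame)


def select_features(
    diff: DifferentialResult,
    vip: pd.Series,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> list[str]:
    """Apply the selection rule: VIP strictly above ``vip_threshold``
    AND (FDR q-value if ``use_fdr`` else raw p-value) strictly below
    ``alpha``.  Mutates ``diff.frame`` by adding ``vip`` and
    ``selected`` columns and returns the selected feature ids."""
    if not diff.frame.index.equals(vip.index):
        raise ConfigurationError("feature ids of diff result and VIP differ")
    crit = diff.frame["q_value"] if use_fdr else diff.frame["p_value"]
    selected = (vip > vip_threshold) & (crit < alpha)
    diff.frame["vip"] = vip
    diff.frame["selected"] = selected
    return list(diff.frame.index[selected])


def differential_analysis(
    table: FeatureTable,
    comparison: str | tuple[str, str] = "ra-hc",
    n_ortho: int = 1,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> tuple[DifferentialResult, OplsModel]:
    """End-to-end pairwise comparison: subset the two groups, log/Pareto
    scale on those samples, fit OPLS-DA, compute VIP, run the Wilcoxon
    tests and apply the selection rule."""
    groups = COMPARISONS[comparison] if isinstance(comparison, str) else comparison
    labels = table.groups()
    keep = labels.index[labels.isin(groups)]
    sub = table.biological.loc[keep]
    if sub.isna().any().any():
        raise ConfigurationError("run imputation before differential analysis")
    scaled = log_pareto(sub)
    nonconst = scaled.columns[(scaled.std() > 0).to_numpy()]
    y = (labels.loc[keep] == groups[1]).to_numpy(float)
    model = fit_oplsda(scaled[nonconst], y, n_ortho)
    vip = vip_scores(model).reindex(scaled.columns).fillna(0.0)
    diff = univariate_test(table.subset_features(list(sub.columns)), groups)
    select_features(diff, vip, alpha=alpha, use_fdr=use_fdr)
    return diff, model
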