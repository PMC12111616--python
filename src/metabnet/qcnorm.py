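"""QC-based drift normalization and feature filtering.

Implements a SERRF-style correction: for each feature a random forest
is trained on the pooled-QC injections of its run (predictors are the
injection position plus the intensities of the most QC-correlated other
features) to model the systematic, injection-order-dependent component
of the signal; all injections are then rescaled so the modelled
systematic level is flattened to the feature's QC median.  Presence and
QC-reproducibility (%CV) filters follow, then half-minimum imputation
of the remaining left-censored values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError, UndefinedStatisticError
from .tables import GROUPS, PLATFORM_RUN, FeatureTable

#: per-platform QC %CV reproducibility thresholds (LC 20%, GC 30%)
DEFAULT_CV_THRESHOLDS = {"LC": 20.0, "GC": 30.0}

MIN_QC_FOR_FOREST = 5
LOESS_SPAN = 0.75


@dataclass
class FilterRule:
    name: str
    n_before: int
    n_after: int
    stats: pd.DataFrame  # per-feature computed statistic + pass flag


@dataclass
class FilterReport:
    """Per-rule accounting of which features survived and why."""

    rules: list[FilterRule]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for r in self.rules:
            df = r.stats.copy()
            df.insert(0, "rule", r.name)
            frames.append(df)
        return pd.concat(frames)


# ---------------------------------------------------------------------------
# QC %CV
# ---------------------------------------------------------------------------


def qc_cv(table: FeatureTable, feature: str) -> float:
    """Percent coefficient of variation (100 * SD / mean) of a feature
    over the pooled-QC injections of its run.

    Raises
    ------
    UndefinedStatisticError
        If fewer than two non-missing QC values exist.
    """
    run = table.run_of(feature)
    values = table.qc_rows(run)[feature].dropna().to_numpy()
    if len(values) < 2:
        raise UndefinedStatisticError(
            f"%CV undefined for {feature!r}: {len(values)} QC value(s)"
        )
    return float(100.0 * values.std(ddof=1) / values.mean())


def qc_cv_all(table: FeatureTable) -> pd.Series:
    """QC %CV for every feature (NaN where undefined)."""
    out = {}
    for f in table.data.columns:
        try:
            out[f] = qc_cv(table, f)
        except UndefinedStatisticError:
            out[f] = np.nan
    return pd.Series(out, name="cv_qc")


# ---------------------------------------------------------------------------
# SERRF-style normalization
# ---------------------------------------------------------------------------


def _qc_correlated_features(
    qc_log: pd.DataFrame, feature: str, k: int
) -> list[str]:
    """The k features most correlated with ``feature`` across QC
    injections (absolute Pearson correlation of log intensities)."""
    target = qc_log[feature]
    others = qc_log.drop(columns=[feature])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = others.corrwith(target).abs()
    return list(corr.sort_values(ascending=False).index[:k])


def serrf_normalize(
    table: FeatureTable,
    k_correlated: int = 10,
    trees: int = 500,
    seed: int = 0,
) -> FeatureTable:
    """Remove injection-order-dependent systematic error per feature.

    The correction is multiplicative on the raw scale (a subtraction of
    the modelled systematic component on the log scale, re-anchored to
    the feature's QC median), so the missingness pattern and the QC
    median are preserved and scaling a feature by ``c > 0`` scales its
    normalized values by ``c``.

    Features whose run has fewer than five usable QC injections fall
    back to a LOESS fit of QC intensity on injection position; features
    that are constant or all-missing pass through unchanged with a
    warning.
    """
    out = table.copy()
    for run in table.qc_schedules:
        feats = table.features_in_run(run)
        if not feats:
            continue
        qc = table.qc_rows(run)[feats]
        pos_all = table.positions(run)
        qc_pos = pos_all.loc[qc.index].to_numpy(float)
        rows = pos_all.index  # biological rows + this run's QC rows
        row_pos = pos_all.to_numpy(float)
        qc_log = np.log(qc)
        data_log = np.log(table.data.loc[rows, feats])

        for f in feats:
            y = qc_log[f].to_numpy()
            ok = np.isfinite(y)
            observed = data_log[f].to_numpy()
            target = np.isfinite(observed)
            if target.sum() == 0 or ok.sum() < 2:
                warnings.warn(
                    f"feature {f!r}: too few QC values, passed through",
                    stacklevel=2,
                )
                continue
            if np.nanstd(y[ok]) == 0 and np.nanstd(observed[target]) == 0:
                continue  # constant feature: nothing to correct
            if ok.sum() >= MIN_QC_FOR_FOREST:
                pred = _forest_systematic(
                    f, y, ok, qc_pos, qc_log, data_log, row_pos,
                    k_correlated, trees, seed,
                )
            else:
                warnings.warn(
                    f"feature {f!r}: {ok.sum()} QC values, "
                    "LOESS fallback on injection order",
                    stacklevel=2,
                )
                pred = lowess(
                    y[ok], qc_pos[ok], frac=LOESS_SPAN,
                    xvals=row_pos, return_sorted=False,
                )
            med = np.median(y[ok])
            corrected = observed - pred + med
            out.data.loc[rows, f] = np.where(
                target, np.exp(corrected), np.nan
            )
    return out


def _forest_systematic(
    feature: str,
    y: np.ndarray,
    ok: np.ndarray,
    qc_pos: np.ndarray,
    qc_log: pd.DataFrame,
    data_log: pd.DataFrame,
    row_pos: np.ndarray,
    k_correlated: int,
    trees: int,
    seed: int,
) -> np.ndarray:
    companions = _qc_correlated_features(qc_log, feature, k_correlated)
    x_train = np.column_stack(
        [qc_pos[ok]] + [qc_log[c].to_numpy()[ok] for c in companions]
    )
    x_pred = np.column_stack(
        [row_pos] + [data_log[c].to_numpy() for c in companions]
    )
    # companion intensities may themselves be censored on some rows
    col_med = np.nanmedian(x_train, axis=0)
    x_train = np.where(np.isfinite(x_train), x_train, col_med)
    x_pred = np.where(np.isfinite(x_pred), x_pred, col_med)
    forest = RandomForestRegressor(
        n_estimators=trees, random_state=seed, min_samples_leaf=1
    )
    # fit on the centered target: tree construction then depends on the
    # target only through differences, which keeps the correction
    # scale-equivariant (a multiplicative rescaling of the feature
    # shifts log intensities by a constant)
    center = np.median(y[ok])
    forest.fit(x_train, y[ok] - center)
    return forest.predict(x_pred) + center


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def presence_filter(
    table: FeatureTable, min_fraction: float = 0.8
) -> tuple[FeatureTable, FilterReport]:
    """Keep features present (non-missing) in at least ``min_fraction``
    of the samples of at least one biological study group.  QC rows do
    not enter the computation."""
    groups = table.groups()
    for g in GROUPS:
        if (groups == g).sum() == 0:
            raise ConfigurationError(f"empty study group {g!r}")
    bio = table.biological
    fractions = pd.DataFrame(
        {g: bio.loc[groups.index[groups == g]].notna().mean() for g in GROUPS}
    )
    best = fractions.max(axis=1)
    passed = best >= min_fraction
    stats = pd.DataFrame(
        {"statistic": best, "passed": passed}
    ).rename_axis("feature_id")
    kept = list(table.data.columns[passed.to_numpy()])
    report = FilterReport(
        [FilterRule("presence", len(passed), len(kept), stats)]
    )
    return table.subset_features(kept), report


def cv_filter(
    table: FeatureTable,
    thresholds: dict[str, float] | None = None,
) -> tuple[FeatureTable, FilterReport]:
    """Keep features whose QC %CV is <= the threshold of their run
    (boundary values pass; the exclusion rule is 'greater than')."""
    thresholds = dict(DEFAULT_CV_THRESHOLDS if thresholds is None else thresholds)
    for p in set(table.feature_platform):
        run = PLATFORM_RUN.get(p)
        if run is None or (run not in thresholds and p not in thresholds):
            raise ConfigurationError(f"no %CV threshold for platform {p!r}")
    cvs = qc_cv_all(table)
    limits = table.feature_platform.map(
        lambda p: thresholds.get(PLATFORM_RUN[p], thresholds.get(p))
    )
    passed = cvs <= limits[cvs.index]
    stats = pd.DataFrame(
        {"statistic": cvs, "passed": passed}
    ).rename_axis("feature_id")
    kept = list(table.data.columns[passed[table.data.columns].to_numpy()])
    report = FilterReport([FilterRule("qc_cv", len(passed), len(kept), stats)])
    return table.subset_features(kept), report


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Replace remaining missing values by half the per-feature observed
    minimum (left-censoring surrogate).  Observed values are untouched.

    Assumes the presence filter ran first; a fully missing feature is an
    internal error.
    """
    out = table.copy()
    mins = out.data.min()
    if mins.isna().any():
        bad = list(mins.index[mins.isna()])
        raise ConfigurationError(
            f"fully missing feature(s) reached imputation: {bad[:5]}"
        )
    out.data = out.data.fillna(mins / 2.0)
    return out


def preprocess(
    table: FeatureTable,
    min_fraction: float = 0.8,
    cv_thresholds: dict[str, float] | None = None,
    serrf: bool = True,
    k_correlated: int = 10,
    trees: int = 500,
    seed: int = 0,
) -> tuple[FeatureTable, FilterReport]:
    """Full preprocessing: SERRF normalization, presence filter, QC %CV
    filter, half-minimum imputation."""
    if serrf:
        table = serrf_normalize(table, k_correlated, trees, seed)
    table, rep1 = presence_filter(table, min_fraction)
    table, rep2 = cv_filter(table, cv_thresholds)
    table = impute_missing(table)
    return table, FilterReport(rep1.rules + rep2.rules)
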