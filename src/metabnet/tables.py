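"""Core in-memory containers for the pipeline.

The feature table is a samples x features intensity matrix (arbitrary
units, strictly positive where observed, NaN where censored) together
with the injection metadata the QC-based normalization needs.  Two
instrument runs are modelled: ``LC`` (holding both ionization modes of
the liquid-chromatography platform) and ``GC``.  Pooled-QC injections
belong to exactly one run; biological samples are injected on both runs
in the same randomized order, so they carry their biological rank and
their absolute position within each run is derived from the run's QC
schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

GROUPS = ("HC", "RA", "SLE")
QC_GROUP = "QC"

#: instrument platform -> run sharing one QC series
PLATFORM_RUN = {"LC-pos": "LC", "LC-neg": "LC", "GC": "GC"}


@dataclass(frozen=True)
class QcSchedule:
    """Pooled-QC injection pattern for one run: ``initial`` QC
    injections up front, then one QC after every ``interval``
    biological samples."""

    initial: int
    interval: int

    def __post_init__(self) -> None:
        if self.initial < 1 or self.interval < 1:
            raise ConfigurationError(
                f"QC schedule counts must be positive, got {self}"
            )

    def biological_position(self, rank: int | np.ndarray) -> np.ndarray:
        """Absolute injection position of the biological sample with
        1-based rank ``rank`` in this run's sequence."""
        r = np.asarray(rank)
        return self.initial + r + (r - 1) // self.interval

    def qc_positions(self, n_biological: int) -> np.ndarray:
        """Absolute positions of every QC injection in a run of
        ``n_biological`` biological samples."""
        head = np.arange(1, self.initial + 1)
        k = np.arange(1, n_biological // self.interval + 1)
        interleaved = self.biological_position(k * self.interval) + 1
        return np.concatenate([head, interleaved])


DEFAULT_SCHEDULES = {"LC": QcSchedule(10, 8), "GC": QcSchedule(6, 5)}


@dataclass
class FeatureTable:
    """Samples x features intensity matrix plus injection metadata.

    Parameters
    ----------
    data
        DataFrame indexed by sample id, one column per feature id.
        NaN marks a censored (missing) measurement.
    sample_meta
        DataFrame indexed by sample id with columns ``group``
        (HC/RA/SLE/QC), ``injection_order`` (biological rank for
        biological samples; absolute run position for QC rows) and
        ``platform_batch`` (``both`` for biological rows, the run name
        for QC rows).
    feature_platform
        Series mapping feature id -> platform (LC-pos/LC-neg/GC).
    qc_schedules
        Per-run QC injection schedule.
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_platform: pd.Series
    qc_schedules: dict[str, QcSchedule] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULES)
    )

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.sample_meta.index):
            raise ConfigurationError("data and sample_meta indices differ")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ConfigurationError(f"duplicated sample ids: {list(dupes)}")
        if self.data.columns.has_duplicates:
            raise ConfigurationError("duplicated feature ids")
        missing = set(self.data.columns) - set(self.feature_platform.index)
        if missing:
            raise ConfigurationError(
                f"features without platform assignment: {sorted(missing)[:5]}"
            )
        unknown = set(self.sample_meta["group"]) - set(GROUPS) - {QC_GROUP}
        if unknown:
            raise ConfigurationError(f"unknown group labels: {sorted(unknown)}")

    # -- row selections -------------------------------------------------
    @property
    def is_qc(self) -> pd.Series:
        return self.sample_meta["group"] == QC_GROUP

    @property
    def biological(self) -> pd.DataFrame:
        return self.data.loc[~self.is_qc]

    def groups(self) -> pd.Series:
        """Group label per biological sample."""
        return self.sample_meta.loc[~self.is_qc, "group"]

    def qc_rows(self, run: str) -> pd.DataFrame:
        """Pooled-QC rows belonging to one run, in injection order."""
        mask = self.is_qc & (self.sample_meta["platform_batch"] == run)
        rows = self.data.loc[mask]
        order = self.sample_meta.loc[mask, "injection_order"]
        return rows.loc[order.sort_values().index]

    # -- feature selections ---------------------------------------------
    def run_of(self, feature: str) -> str:
        return PLATFORM_RUN[self.feature_platform[feature]]

    def features_in_run(self, run: str) -> list[str]:
        plats = [p for p, r in PLATFORM_RUN.items() if r == run]
        mask = self.feature_platform.isin(plats)
        return [f for f in self.data.columns if mask.get(f, False)]

    # -- injection axis --------------------------------------------------
    def positions(self, run: str) -> pd.Series:
        """Absolute injection position in ``run`` for every row that was
        injected on it (biological rows plus that run's QC rows)."""
        sched = self.qc_schedules[run]
        bio = ~self.is_qc
        qc = self.is_qc & (self.sample_meta["platform_batch"] == run)
        pos = pd.Series(np.nan, index=self.data.index)
        pos[bio] = sched.biological_position(
            self.sample_meta.loc[bio, "injection_order"].to_numpy()
        )
        pos[qc] = self.sample_meta.loc[qc, "injection_order"].to_numpy()
        return pos.dropna().astype(int)

    # -- convenience -----------------------------------------------------
    def subset_features(self, features: list[str]) -> "FeatureTable":
        return replace(
            self,
            data=self.data[features],
            feature_platform=self.feature_platform[features],
        )

    def copy(self) -> "FeatureTable":
        return replace(
            self,
            data=self.data.copy(),
            sample_meta=self.sample_meta.copy(),
            feature_platform=self.feature_platform.copy(),
        )
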