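"""Shared fixtures: small seeded synthetic cohorts and hand-built
feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metabnet.synthdata import CohortDesign, EffectSpec, simulate_cohort
from metabnet.tables import FeatureTable, QcSchedule

SMALL_COMPOSITION = {
    "glycerolipids": 8,
    "cyclic": 8,
    "phospholipids_pc": 8,
    "phospholipids_pe": 8,
    "sphingolipids": 8,
    "fatty_acids": 8,
}


@pytest.fixture(scope="session")
def small_design() -> CohortDesign:
    """Study-sized groups over a 48-feature panel."""
    return CohortDesign(
        n_features=48, class_composition=dict(SMALL_COMPOSITION), seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design, EffectSpec())


@pytest.fixture(scope="session")
def clean_cohort(small_cohort):
    """Preprocessed (SERRF + filters + imputation) small cohort."""
    from metabnet.qcnorm import preprocess

    table, metadata, annotations = small_cohort
    clean, _ = preprocess(table, trees=50, seed=7)
    return clean, metadata, annotations


def toy_table(
    qc_values: dict[str, list[float]] | None = None,
    bio_values: dict[str, np.ndarray] | None = None,
    n_per_group: tuple[int, int, int] = (4, 4, 4),
    platform: str = "LC-pos",
) -> FeatureTable:
    """Hand-built single-platform FeatureTable for unit tests.

    ``qc_values``/``bio_values`` map feature id -> values (QC values in
    injection order, biological values in sample order).
    """
    qc_values = qc_values or {"f1": [100.0, 100.0, 100.0]}
    features = list(qc_values)
    n_bio = sum(n_per_group)
    rng = np.random.default_rng(0)
    bio = {
        f: (bio_values or {}).get(f, rng.uniform(50, 150, n_bio))
        for f in features
    }
    n_qc = len(next(iter(qc_values.values())))
    groups = (
        ["HC"] * n_per_group[0]
        + ["RA"] * n_per_group[1]
        + ["SLE"] * n_per_group[2]
    )
    ids = [f"S{i:02d}" for i in range(n_bio)] + [f"QC{i:02d}" for i in range(n_qc)]
    run = "LC" if platform.startswith("LC") else "GC"
    sched = QcSchedule(2, 2)
    qc_pos = sched.qc_positions(n_bio)[:n_qc]
    meta = pd.DataFrame(
        {
            "group": groups + ["QC"] * n_qc,
            "injection_order": list(range(1, n_bio + 1)) + list(qc_pos),
            "platform_batch": ["both"] * n_bio + [run] * n_qc,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    data = pd.DataFrame(
        {f: list(bio[f]) + list(qc_values[f]) for f in features},
        index=meta.index,
    )
    return FeatureTable(
        data,
        meta,
        pd.Series(platform, index=features),
        {run: sched},
    )
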