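"""Plain-text table formats.

Three CSV tables describe a cohort:

* feature table — first column ``sample_id``, remaining columns one per
  feature id; empty cells or ``NA`` mark missing intensities;
* sample metadata — ``sample_id, group, injection_order,
  platform_batch`` plus clinical columns (hdl, ldl, tc, tg, esr,
  lymphocytes, neutrophils, duration, activity_score) and cytokines;
* annotations — ``feature_id, name, formula, mass, rt, smiles`` (or
  ``fp_bits``), ``platform, cv_qc, msi_level``.

Missing values are written as ``NA``; both empty cells and ``NA`` are
accepted on read.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .tables import FeatureTable, GROUPS, PLATFORM_RUN, QC_GROUP

NA_VALUES = ["", "NA"]


def _check_unique(index: pd.Index, what: str, path: Path) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated {what}: {dupes[:5]}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    _check_unique(df.index, "sample id", path)
    unknown = set(df["group"].dropna()) - set(GROUPS) - {QC_GROUP}
    if unknown:
        rows = df.index[df["group"].isin(unknown)].tolist()
        raise ParseError(
            f"{path}: unknown group labels {sorted(unknown)} at rows {rows[:5]}"
        )
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    if "feature_id" not in df.columns:
        raise ParseError(f"{path}: missing feature_id column")
    df = df.set_index("feature_id")
    _check_unique(df.index, "feature id", path)
    if "smiles" not in df.columns and "fp_bits" not in df.columns:
        raise ParseError(f"{path}: need a smiles or fp_bits column")
    return df


def read_feature_table(
    path: str | Path,
    metadata: pd.DataFrame | str | Path,
    annotations: pd.DataFrame | str | Path,
) -> FeatureTable:
    """Assemble a FeatureTable from the three CSVs, cross-validating
    sample and feature ids."""
    path = Path(path)
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    if not isinstance(annotations, pd.DataFrame):
        annotations = read_annotations(annotations)
    df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "sample_id"
    _check_unique(df.index, "sample id", path)
    _check_unique(df.columns, "feature id", path)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            raise ParseError(
                f"{path}: non-numeric intensity in column {col!r}, "
                f"row(s) {bad.tolist()[:5]}"
            ) from exc
    extra = set(df.index) - set(metadata.index)
    if extra:
        raise ParseError(f"{path}: samples missing from metadata: {sorted(extra)[:5]}")
    extra_f = set(df.columns) - set(annotations.index)
    if extra_f:
        raise ParseError(
            f"{path}: features missing from annotations: {sorted(extra_f)[:5]}"
        )
    meta = metadata.loc[df.index, ["group", "injection_order", "platform_batch"]]
    platform = annotations.loc[df.columns, "platform"]
    bad_plat = set(platform) - set(PLATFORM_RUN)
    if bad_plat:
        raise ParseError(f"unknown platform(s) {sorted(bad_plat)}")
    return FeatureTable(df, meta, platform)


def write_cohort(
    outdir: str | Path,
    table: FeatureTable,
    metadata: pd.DataFrame,
    annotations: pd.DataFrame,
) -> dict[str, Path]:
    """Write the three standard CSVs; missing values become ``NA``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.csv",
        "metadata": outdir / "metadata.csv",
        "annotations": outdir / "annotations.csv",
    }
    table.data.to_csv(paths["features"], na_rep="NA")
    metadata.to_csv(paths["metadata"], na_rep="NA")
    annotations.to_csv(paths["annotations"], na_rep="NA")
    return paths


def load_cohort(outdir: str | Path) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame]:
    outdir = Path(outdir)
    metadata = read_metadata(outdir / "metadata.csv")
    annotations = read_annotations(outdir / "annotations.csv")
    table = read_feature_table(outdir / "features.csv", metadata, annotations)
    return table, metadata, annotations


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, entries: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(entries, indent=2, default=default))
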