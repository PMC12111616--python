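"""Pipeline driver: configuration, stage ordering, artifact manifest.

Every stage is runnable independently from the library API; the driver
chains them in dependency order (simulate -> preprocess -> diff ->
chemmap -> network -> biomarker -> cohort), writes each artifact as a
plain-text table, and records a manifest (parameters, seed, input
hashes, package version) so a rerun with the same seed reproduces the
same hashes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker import combined_biomarker
from .chemmap import (
    detect_clusters,
    module_group_tests,
    split_modules,
    tanimoto_distance_matrix,
    wmcsa,
)
from .cohort_stats import group_comparison_table
from .diffsel import differential_analysis
from .errors import ConfigurationError
from .io import file_sha256, load_cohort, write_cohort, write_manifest
from .netcorr import build_network, disease_panel
from .qcnorm import preprocess
from .synthdata import CohortDesign, EffectSpec, simulate_cohort

log = logging.getLogger("metabnet")


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_hc: int = 27
    n_ra: int = 23
    n_sle: int = 22
    n_features: int = 431


@dataclass
class PreprocessConfig:
    presence: float = 0.8
    cv_lc: float = 20.0
    cv_gc: float = 30.0
    serrf: bool = True
    trees: int = 500
    k_correlated: int = 10


@dataclass
class DiffConfig:
    comparisons: list[str] = field(default_factory=lambda: ["ra-hc", "sle-hc"])
    n_ortho: int = 1
    alpha: float = 0.05
    use_fdr: bool = True


@dataclass
class ChemmapConfig:
    n_bits: int = 1024
    k_min: int = 2
    k_max: int = 10
    min_module_size: int = 3


@dataclass
class NetworkConfig:
    diseases: list[str] = field(default_factory=lambda: ["RA", "SLE"])
    alpha: float = 0.05
    targets: str = "cytokines"


@dataclass
class BiomarkerConfig:
    n_features: int = 2  # top differential metabolites combined per disease


@dataclass
class PipelineConfig:
    outdir: str = "results"
    features: str | None = None
    metadata: str | None = None
    annotations: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)
    chemmap: ChemmapConfig = field(default_factory=ChemmapConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    biomarker: BiomarkerConfig = field(default_factory=BiomarkerConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _build(cls, raw, "config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def _build(cls, raw: dict, where: str):
    """Construct a (possibly nested) config dataclass, rejecting keys
    that are not fields."""
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigurationError(f"{where}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        f = fields[name]
        nested = None
        if f.default_factory is not dataclasses.MISSING:
            probe = f.default_factory()
            if dataclasses.is_dataclass(probe):
                nested = type(probe)
        kwargs[name] = (
            _build(nested, value, f"{where}.{name}") if nested else value
        )
    return cls(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages in order; returns the manifest dict.
    A stage failure raises and aborts downstream stages."""
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "artifacts": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": file_sha256(path)
        }

    # --- stage: cohort data -------------------------------------------------
    if config.simulate.enabled:
        log.info("simulating cohort (seed=%d)", config.seed)
        design = CohortDesign(
            n_hc=config.simulate.n_hc,
            n_ra=config.simulate.n_ra,
            n_sle=config.simulate.n_sle,
            n_features=config.simulate.n_features,
            seed=config.seed,
        )
        table, metadata, annotations = simulate_cohort(design, EffectSpec())
        paths = write_cohort(outdir / "cohort", table, metadata, annotations)
        for k, p in paths.items():
            record(f"cohort/{k}", p)
    else:
        if not (config.features and config.metadata and config.annotations):
            raise ConfigurationError(
                "simulate disabled: features/metadata/annotations paths required"
            )
        from .io import read_annotations, read_feature_table, read_metadata

        metadata = read_metadata(config.metadata)
        annotations = read_annotations(config.annotations)
        table = read_feature_table(config.features, metadata, annotations)

    # --- stage: preprocess --------------------------------------------------
    log.info("preprocessing (SERRF=%s)", config.preprocess.serrf)
    clean, report = preprocess(
        table,
        min_fraction=config.preprocess.presence,
        cv_thresholds={"LC": config.preprocess.cv_lc, "GC": config.preprocess.cv_gc},
        serrf=config.preprocess.serrf,
        k_correlated=config.preprocess.k_correlated,
        trees=config.preprocess.trees,
        seed=config.seed,
    )
    p = outdir / "preprocessed.csv"
    clean.data.to_csv(p, na_rep="NA")
    record("preprocessed", p)
    p = outdir / "filter_report.tsv"
    report.to_frame().to_csv(p, sep="\t", na_rep="NA")
    record("filter_report", p)

    # --- stage: differential analysis ---------------------------------------
    diffs = {}
    for comp in config.diff.comparisons:
        log.info("differential analysis %s", comp)
        diff, _model = differential_analysis(
            clean, comp, config.diff.n_ortho, config.diff.alpha,
            config.diff.use_fdr,
        )
        diffs[comp] = diff
        p = outdir / f"diff_{comp}.tsv"
        diff.frame.to_csv(p, sep="\t", na_rep="NA")
        record(f"diff/{comp}", p)

    # --- stage: chemical mapping --------------------------------------------
    log.info("chemical-similarity mapping")
    kept = [f for f in clean.data.columns if f in annotations.index]
    dist = tanimoto_distance_matrix(
        annotations.loc[kept], n_bits=config.chemmap.n_bits
    )
    clustering = detect_clusters(dist, (config.chemmap.k_min, config.chemmap.k_max))
    modules = split_modules(clustering, config.chemmap.min_module_size)
    assign = pd.DataFrame(
        {"cluster": clustering.clusters, "module": modules}
    ).rename_axis("feature_id")
    p = outdir / "chemical_modules.tsv"
    assign.to_csv(p, sep="\t")
    record("chemmap/modules", p)
    summary = wmcsa(clean, modules)
    p = outdir / "module_scores.csv"
    summary.scores.to_csv(p)
    record("chemmap/scores", p)
    tests = module_group_tests(summary, clean.groups())
    p = outdir / "module_tests.tsv"
    tests.to_csv(p, sep="\t")
    record("chemmap/tests", p)

    # --- stage: correlation networks ----------------------------------------
    bio_meta = metadata[metadata["group"] != "QC"]
    for disease in config.network.diseases:
        comp = f"{disease.lower()}-hc"
        if comp not in diffs:
            continue
        selected = diffs[comp].selected
        if not selected:
            log.warning("no selected metabolites for %s network", disease)
            continue
        samples = bio_meta.index[bio_meta["group"] == disease]
        data = pd.concat(
            [np.log(clean.data.loc[samples, selected]),
             bio_meta.loc[samples].drop(columns=["group", "injection_order",
                                                 "platform_batch"])],
            axis=1,
        )
        kinds = disease_panel(selected, disease, config.network.targets)
        log.info("%s network: %d nodes", disease, len(kinds))
        net = build_network(data, kinds, alpha=config.network.alpha)
        p = outdir / f"network_{disease}_edges.tsv"
        net.edges.to_csv(p, sep="\t", index=False)
        record(f"network/{disease}/edges", p)
        p = outdir / f"network_{disease}_layout.csv"
        net.layout().to_csv(p)
        record(f"network/{disease}/layout", p)

    # --- stage: combined biomarkers -----------------------------------------
    biomarkers = {}
    for disease in config.network.diseases:
        comp = f"{disease.lower()}-hc"
        if comp not in diffs:
            continue
        frame = diffs[comp].frame
        top = (
            frame[frame["selected"]]
            .sort_values("q_value")
            .head(config.biomarker.n_features)
            .index.tolist()
        )
        if len(top) < 1:
            continue
        fit, roc = combined_biomarker(clean, top, comp)
        biomarkers[disease] = {
            "features": top,
            "coefficients": fit.coef.tolist(),
            "auc": roc.auc,
            "separation": fit.separation,
        }
        p = outdir / f"roc_{disease}.csv"
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(p, index=False)
        record(f"biomarker/{disease}/roc", p)
    p = outdir / "biomarkers.json"
    write_manifest(p, biomarkers)
    record("biomarker/summary", p)

    # --- stage: cohort statistics -------------------------------------------
    log.info("cohort statistics")
    numeric = ["hdl", "ldl", "tc", "tg", "esr", "lymphocytes", "neutrophils"]
    numeric = [c for c in numeric if c in metadata.columns]
    table1 = group_comparison_table(bio_meta.reset_index(), numeric)
    p = outdir / "cohort_table.tsv"
    table1.to_csv(p, sep="\t", na_rep="NA")
    record("cohort_table", p)

    write_manifest(outdir / "manifest.json", manifest)
    record_path = outdir / "manifest.json"
    log.info("pipeline complete: %s", record_path)
    return manifest
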