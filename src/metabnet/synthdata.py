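"""Synthetic plasma-metabolomics cohorts with planted structure.

The generator emulates a two-platform (LC and GC QTOF-MS) untargeted
metabolomics study of three groups of women — healthy controls (HC),
rheumatoid arthritis (RA) and systemic lupus erythematosus (SLE) — with
pooled-QC injections interleaved in each run.  It plants the structure
the downstream analysis is designed to detect:

* log-normal metabolite intensities with additive class-by-group
  effects on the log scale (phospholipid and sphingolipid classes
  decreased in disease, glycerolipids increased by default);
* smooth + monotone injection-order signal drift shared by biological
  and QC injections of the same run;
* left-censoring of low intensities (limit-of-detection missingness);
* per-class homologous SMILES series so chemical similarity recovers
  the classes by construction;
* cytokine elevations per disease and reduced HDL, with shared latent
  factors tying chosen metabolites to a hub cytokine and to HDL so the
  correlation networks have a planted truth.

Every quantity is a deterministic function of the design seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, UnsupportedOracleError
from .tables import DEFAULT_SCHEDULES, FeatureTable, QcSchedule

# ---------------------------------------------------------------------------
# chemistry templates
# ---------------------------------------------------------------------------

#: default chemical-class composition (sums to 431 annotated metabolites)
DEFAULT_COMPOSITION = {
    "glycerolipids": 80,
    "cyclic": 50,
    "phospholipids_pc": 90,
    "phospholipids_pe": 80,
    "sphingolipids": 70,
    "fatty_acids": 61,
}

#: which instrument platform measures each class
CLASS_PLATFORM = {
    "glycerolipids": ("LC-pos", "LC-neg"),
    "cyclic": ("LC-pos",),
    "phospholipids_pc": ("LC-pos", "LC-neg"),
    "phospholipids_pe": ("LC-neg", "LC-pos"),
    "sphingolipids": ("LC-pos",),
    "fatty_acids": ("GC",),
}

CYTOKINES = (
    "GM-CSF", "CX3CL1", "IFN-a2", "IL-12p70", "IL-17A",
    "TNF-a", "IL-1b", "IFN-g", "IL-2", "MCP-1", "IL-10",
)

#: cytokines significantly elevated per disease
CYTOKINE_PANELS = {
    "RA": ("GM-CSF", "CX3CL1", "IFN-a2", "IL-12p70", "IL-17A",
           "TNF-a", "IL-1b", "IFN-g", "IL-2"),
    "SLE": ("GM-CSF", "CX3CL1", "IFN-a2", "IL-12p70", "IL-17A",
            "TNF-a", "IL-1b", "IFN-g", "MCP-1", "IL-10"),
}

CLINICAL_COLUMNS = (
    "hdl", "ldl", "tc", "tg", "esr", "lymphocytes",
    "neutrophils", "duration", "activity_score",
)


def _chain(n: int) -> str:
    """Saturated linear acyl chain of ``n`` carbons as a SMILES fragment."""
    return "C" * n


def _smiles_template(chem_class: str, i: int) -> str:
    """Member ``i`` of the homologous series for one chemical class.

    Each class shares one structural motif (diacylglycerol backbone,
    phosphocholine diester, ether/plasmalogen phosphoethanolamine,
    sphingoid amide, free fatty acid, aryl acid) and members differ in
    chain lengths cycled with co-prime strides, so within-class
    Tanimoto similarity is high and graded while the class motifs stay
    well separated — the structure chemical clustering should recover.
    """
    a = _chain(3 + (7 * i) % 11)
    b = _chain(4 + (5 * i) % 9)
    if chem_class == "glycerolipids":
        return f"OCC(COC(=O){a})OC(=O){b}"
    if chem_class == "phospholipids_pc":
        return f"C[N+](C)(C)CCOP([O-])(=O)OCC(COC(=O){a})OC(=O){b}"
    if chem_class == "phospholipids_pe":
        # ether (plasmalogen-like) phosphoethanolamine series
        return f"NCCOP(O)(=O)OCC(CO/C=C/{a})O{b}"
    if chem_class == "sphingolipids":
        return _chain(6 + (3 * i) % 8) + f"C(O)C(CO)NC(=O){b}"
    if chem_class == "fatty_acids":
        return "OC(=O)" + _chain(4 + (7 * i) % 17)
    if chem_class == "cyclic":
        return "OC(=O)" + _chain(2 + (5 * i) % 7) + "c1ccccc1"
    raise ConfigurationError(f"unknown chemical class {chem_class!r}")


# ---------------------------------------------------------------------------
# design / effects
# ---------------------------------------------------------------------------


def scaled_composition(n_features: int) -> dict[str, int]:
    """Scale the default six-class composition proportionally to a
    smaller or larger total feature count."""
    total = sum(DEFAULT_COMPOSITION.values())
    out = {
        cls: max(1, round(n * n_features / total))
        for cls, n in DEFAULT_COMPOSITION.items()
    }
    # fix rounding drift on the largest class
    largest = max(out, key=out.get)
    out[largest] += n_features - sum(out.values())
    return out


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: group sizes, feature panel, QC schedules, seed."""

    n_hc: int = 27
    n_ra: int = 23
    n_sle: int = 22
    n_features: int = 431
    class_composition: dict[str, int] | None = None
    qc_schedules: dict[str, QcSchedule] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hc", "n_ra", "n_sle", "n_features"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.class_composition is None:
            object.__setattr__(
                self,
                "class_composition",
                scaled_composition(self.n_features),
            )
        if any(c <= 0 for c in self.class_composition.values()):
            raise ConfigurationError("class counts must be positive")
        total = sum(self.class_composition.values())
        if total != self.n_features:
            raise ConfigurationError(
                f"class composition sums to {total}, expected {self.n_features}"
            )

    @property
    def n_biological(self) -> int:
        return self.n_hc + self.n_ra + self.n_sle

    def feature_ids(self) -> list[str]:
        return [
            f"{cls}_{k:03d}"
            for cls, n in self.class_composition.items()
            for k in range(1, n + 1)
        ]


@dataclass(frozen=True)
class LatentFactor:
    """A shared Gaussian factor loading on metabolites, cytokines and/or
    HDL; loadings are in units of the respective within-group SD."""

    name: str
    metabolite_loadings: dict[str, float] = field(default_factory=dict)
    cytokine_loadings: dict[str, float] = field(default_factory=dict)
    hdl_loading: float = 0.0


def _default_factors() -> list[LatentFactor]:
    # The hub cytokine bridges two otherwise-independent fatty-acid
    # sub-families (it loads strongly on both of their factors), so in
    # the disease-group correlation network it is the highest-degree
    # node by design.  Spoke loadings are kept moderate on purpose: a
    # chance empirical correlation between the two factors inside one
    # disease group then fades quadratically in the spokes and cannot
    # flood the network with cross-family edges.  A third factor ties
    # an ether-phospholipid trio to HDL.
    return [
        LatentFactor(
            "inflammation-hub-a",
            metabolite_loadings={
                f"fatty_acids_{k:03d}": 1.5 for k in range(1, 7)
            },
            cytokine_loadings={"GM-CSF": 4.0},
        ),
        LatentFactor(
            "inflammation-hub-b",
            metabolite_loadings={
                f"fatty_acids_{k:03d}": 1.5 for k in range(7, 13)
            },
            cytokine_loadings={"GM-CSF": 4.0},
        ),
        LatentFactor(
            "hdl-lipids",
            metabolite_loadings={
                f"phospholipids_pe_{k:03d}": 0.8 for k in range(1, 4)
            },
            hdl_loading=1.0,
        ),
    ]


def _default_class_effects() -> dict[str, dict[str, float]]:
    # qualitative directions of the planted disease effects:
    # phospholipids and sphingolipids down, glycerolipids up
    down = {"RA": -1.0, "SLE": -1.0}
    return {
        "phospholipids_pc": dict(down),
        "phospholipids_pe": dict(down),
        "sphingolipids": dict(down),
        "glycerolipids": {"RA": 1.0, "SLE": 1.0},
        "fatty_acids": {"RA": -0.5, "SLE": -0.5},
        "cyclic": {},
    }


def _default_cytokine_effects() -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {c: {} for c in CYTOKINES}
    for group, panel in CYTOKINE_PANELS.items():
        for c in panel:
            out[c][group] = 1.2
    return out


@dataclass(frozen=True)
class EffectSpec:
    """Planted effects and nuisance processes, all on the log scale.

    Effect sizes are expressed in units of the within-group SD of the
    affected variable, so an effect of -1.0 is a one-SD decrease.
    """

    class_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_class_effects
    )
    cytokine_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_cytokine_effects
    )
    hdl_shift: dict[str, float] = field(
        default_factory=lambda: {"RA": -0.5, "SLE": -0.9}
    )
    drift_amplitude: float = 0.3
    noise_sd: float = 0.4
    qc_noise_sd: float = 0.05
    missingness: float = 0.05
    latent_strength: float = 1.0
    latent_factors: tuple[LatentFactor, ...] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0 <= self.missingness < 1:
            raise ConfigurationError("missingness must be in [0, 1)")
        for mapping in (self.class_effects, self.cytokine_effects):
            for sub in mapping.values():
                if not all(np.isfinite(list(sub.values()) or [0.0])):
                    raise ConfigurationError("effects must be finite")

    @classmethod
    def null(cls) -> "EffectSpec":
        """Zero effects, no drift, no censoring, no latent factors."""
        return cls(
            class_effects={},
            cytokine_effects={},
            hdl_shift={},
            drift_amplitude=0.0,
            missingness=0.0,
            latent_strength=0.0,
            latent_factors=(),
        )

    def resolved_factors(self) -> list[LatentFactor]:
        factors = (
            _default_factors()
            if self.latent_factors is None
            else list(self.latent_factors)
        )
        if self.latent_strength == 0.0:
            return []
        s = self.latent_strength
        return [
            LatentFactor(
                f.name,
                {k: s * v for k, v in f.metabolite_loadings.items()},
                {k: s * v for k, v in f.cytokine_loadings.items()},
                s * f.hdl_loading,
            )
            for f in factors
        ]

    def class_effect(self, chem_class: str, group: str) -> float:
        return self.class_effects.get(chem_class, {}).get(group, 0.0)


def feature_class(feature_id: str) -> str:
    """Chemical class encoded in a generated feature id."""
    return feature_id.rsplit("_", 1)[0]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _whiten_within_groups(z: np.ndarray, groups: list[str]) -> np.ndarray:
    """Make the factor scores exactly standardized and mutually
    orthogonal within every study group.

    The correlation networks are computed inside one disease group
    (n ~ 23), where chance correlation between two raw Gaussian factor
    columns is often sizeable; that would corrupt the planted truth the
    factors define (the hub's edges weaken while spurious cross-factor
    edges appear).  Whitening each group's block pins the empirical
    factor covariance to the identity, so the planted structure is what
    the sampled cohort actually contains."""
    if z.shape[1] == 0:
        return z
    out = z.copy()
    garr = np.asarray(groups)
    for g in np.unique(garr):
        idx = np.where(garr == g)[0]
        if len(idx) <= z.shape[1]:
            continue
        block = z[idx] - z[idx].mean(axis=0)
        cov = block.T @ block / (len(idx) - 1)
        chol = np.linalg.cholesky(cov)
        out[idx] = block @ np.linalg.inv(chol).T
    return out


def _feature_loadings(
    features: list[str], factors: list[LatentFactor]
) -> np.ndarray:
    lam = np.zeros((len(features), len(factors)))
    for j, f in enumerate(features):
        for q, fac in enumerate(factors):
            lam[j, q] = fac.metabolite_loadings.get(f, 0.0)
    return lam


def simulate_cohort(
    design: CohortDesign, effects: EffectSpec | None = None
) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic cohort.

    Returns
    -------
    table : FeatureTable
        Intensities for biological samples and pooled-QC injections.
    metadata : DataFrame
        Per-sample group, injection metadata, clinical panel (HDL, LDL,
        total cholesterol, triglycerides, ESR, blood counts, disease
        duration, activity score) and cytokine levels; clinical cells
        are NaN on QC rows.
    annotations : DataFrame
        Per-feature chemistry: name, formula, monoisotopic mass,
        retention time, SMILES, platform, raw QC %CV, MSI level.
    """
    if effects is None:
        effects = EffectSpec()
    rng = np.random.default_rng(design.seed)

    features = design.feature_ids()
    n_feat = len(features)
    classes = [feature_class(f) for f in features]
    platform = pd.Series(
        [
            CLASS_PLATFORM[c][k % len(CLASS_PLATFORM[c])]
            for k, c in enumerate(classes)
        ],
        index=features,
        name="platform",
    )
    run = platform.map({"LC-pos": "LC", "LC-neg": "LC", "GC": "GC"})

    # --- samples -----------------------------------------------------------
    groups = (
        ["HC"] * design.n_hc + ["RA"] * design.n_ra + ["SLE"] * design.n_sle
    )
    sample_ids = [
        f"{g}{k:02d}"
        for g, n in (("HC", design.n_hc), ("RA", design.n_ra), ("SLE", design.n_sle))
        for k in range(1, n + 1)
    ]
    n_bio = design.n_biological
    rank = rng.permutation(n_bio) + 1  # shared randomized injection order

    qc_ids: list[str] = []
    qc_batch: list[str] = []
    qc_order: list[int] = []
    for r, sched in design.qc_schedules.items():
        pos = sched.qc_positions(n_bio)
        qc_ids += [f"QC_{r}_{p:03d}" for p in pos]
        qc_batch += [r] * len(pos)
        qc_order += list(pos)

    index = pd.Index(sample_ids + qc_ids, name="sample_id")
    sample_meta = pd.DataFrame(
        {
            "group": groups + ["QC"] * len(qc_ids),
            "injection_order": list(rank) + qc_order,
            "platform_batch": ["both"] * n_bio + qc_batch,
        },
        index=index,
    )

    # --- latent factors ----------------------------------------------------
    factors = effects.resolved_factors()
    z = rng.standard_normal((n_bio, len(factors)))
    z = _whiten_within_groups(z, groups)
    lam = _feature_loadings(features, factors)
    sigma = effects.noise_sd
    sd_within = sigma * np.sqrt(1.0 + (lam**2).sum(axis=1))

    # --- feature-level parameters ------------------------------------------
    mu = rng.normal(11.5, 1.0, n_feat)  # baseline log-intensity
    drift_slope = rng.uniform(-1.0, 1.0, n_feat)
    drift_wave = rng.uniform(0.0, 1.0, n_feat)
    drift_phase = rng.uniform(0.0, 2 * np.pi, n_feat)

    shift = np.zeros((n_bio, n_feat))
    for j, c in enumerate(classes):
        for i, g in enumerate(groups):
            shift[i, j] = effects.class_effect(c, g) * sd_within[j]

    log_bio = (
        mu[None, :]
        + shift
        + sigma * (z @ lam.T)
        + rng.normal(0.0, sigma, (n_bio, n_feat))
    )

    # --- injection-order drift (shared by run) ------------------------------
    run_length = {
        r: int(
            design.qc_schedules[r].biological_position(np.array([n_bio]))[0]
        )
        for r in design.qc_schedules
    }

    def drift_at(pos: np.ndarray, j: int, r: str) -> np.ndarray:
        if effects.drift_amplitude == 0:
            return np.zeros(len(pos))
        x = pos / run_length[r]
        trend = drift_slope[j] * 2.0 * (x - 0.5)
        wave = 0.5 * drift_wave[j] * np.sin(2 * np.pi * x + drift_phase[j])
        return effects.drift_amplitude * sigma * (trend + wave)

    n_rows = n_bio + len(qc_ids)
    log_all = np.full((n_rows, n_feat), np.nan)
    log_all[:n_bio] = log_bio

    pooled = mu + shift.mean(axis=0)  # pooled-QC expected log level
    qc_batch_arr = np.array(qc_batch)
    qc_order_arr = np.array(qc_order)
    for r in design.qc_schedules:
        rows = np.where(qc_batch_arr == r)[0] + n_bio
        feats = np.where(run.to_numpy() == r)[0]
        pos = qc_order_arr[qc_batch_arr == r]
        for j in feats:
            log_all[rows, j] = (
                pooled[j]
                + drift_at(pos, j, r)
                + rng.normal(0.0, effects.qc_noise_sd, len(rows))
            )

    for j in range(n_feat):
        r = run.iloc[j]
        bio_pos = design.qc_schedules[r].biological_position(rank)
        log_all[:n_bio, j] += drift_at(bio_pos, j, r)

    data = pd.DataFrame(np.exp(log_all), index=index, columns=features)

    # --- left-censoring below a per-feature LOD quantile --------------------
    if effects.missingness > 0:
        bio_block = data.iloc[:n_bio]
        lod = bio_block.quantile(effects.missingness)
        censored = bio_block.lt(lod)
        data.iloc[:n_bio] = bio_block.mask(censored)

    table = FeatureTable(
        data=data,
        sample_meta=sample_meta,
        feature_platform=platform,
        qc_schedules=dict(design.qc_schedules),
    )

    metadata = _simulate_metadata(
        sample_meta, groups, effects, factors, z, rng
    )
    annotations = _annotate(features, classes, platform, table, rng)
    return table, metadata, annotations


def _simulate_metadata(
    sample_meta: pd.DataFrame,
    groups: list[str],
    effects: EffectSpec,
    factors: list[LatentFactor],
    z: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical panel and cytokines for biological samples (NaN on QC)."""
    n_bio = len(groups)
    g = np.array(groups)
    meta = sample_meta.copy()

    def shifts(per_group: dict[str, float]) -> np.ndarray:
        return np.array([per_group.get(x, 0.0) for x in g])

    hdl_lam = np.array([f.hdl_loading for f in factors])
    hdl = (
        52.5
        + 8.0 * shifts(effects.hdl_shift)
        + 8.0 * (z @ hdl_lam if len(factors) else 0.0)
        + rng.normal(0, 8.0, n_bio)
    )

    clin = {
        "hdl": hdl,
        "ldl": 122 + 25 * shifts({"RA": -0.45, "SLE": -0.95}) + rng.normal(0, 25, n_bio),
        "tc": 205 + 30 * shifts({"RA": -0.6, "SLE": -1.0}) + rng.normal(0, 30, n_bio),
        "tg": np.exp(np.log(110) + 0.35 * shifts({"RA": 0.3, "SLE": 0.3}) + rng.normal(0, 0.35, n_bio)),
        "esr": np.exp(np.log(8) + 0.6 * shifts({"RA": 1.0, "SLE": 0.5}) + rng.normal(0, 0.6, n_bio)),
        "lymphocytes": 1950 + 350 * shifts({"RA": -0.6, "SLE": -1.2}) + rng.normal(0, 350, n_bio),
        "neutrophils": 3300 + 750 * shifts({"RA": 1.3, "SLE": 0.6}) + rng.normal(0, 750, n_bio),
    }
    clin["duration"] = np.where(
        g == "HC", 0.0, np.exp(np.log(5.0) + rng.normal(0, 0.6, n_bio))
    )
    activity = np.full(n_bio, np.nan)
    activity[g == "RA"] = np.clip(rng.normal(3.6, 0.4, (g == "RA").sum()), 3.2, 5.2)
    activity[g == "SLE"] = np.clip(
        np.round(rng.normal(6.0, 2.0, (g == "SLE").sum())), 4, 12
    )
    clin["activity_score"] = activity

    cyto_sd = 0.5
    for c in CYTOKINES:
        lamc = np.array([f.cytokine_loadings.get(c, 0.0) for f in factors])
        shift = shifts(effects.cytokine_effects.get(c, {}))
        logc = (
            np.log(20.0)
            + cyto_sd * shift
            + cyto_sd * (z @ lamc if len(factors) else 0.0)
            + rng.normal(0, cyto_sd, n_bio)
        )
        clin[c] = np.exp(logc)

    for col, values in clin.items():
        meta[col] = np.nan
        meta.iloc[:n_bio, meta.columns.get_loc(col)] = values
    return meta


def _annotate(
    features: list[str],
    classes: list[str],
    platform: pd.Series,
    table: FeatureTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    from rdkit import Chem
    from rdkit.Chem import Descriptors, rdMolDescriptors

    from .qcnorm import qc_cv

    counters: dict[str, itertools.count] = {}
    rows = []
    for f, c in zip(features, classes):
        i = next(counters.setdefault(c, itertools.count()))
        smiles = _smiles_template(c, i)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - templates are valid
            raise ConfigurationError(f"template SMILES failed to parse: {smiles}")
        plat = platform[f]
        rt = rng.uniform(0.5, 15.0) if plat.startswith("LC") else rng.uniform(5.0, 30.0)
        rows.append(
            {
                "feature_id": f,
                "name": f.replace("_", " "),
                "formula": rdMolDescriptors.CalcMolFormula(mol),
                "mass": round(Descriptors.ExactMolWt(mol), 4),
                "rt": round(rt, 2),
                "smiles": smiles,
                "platform": plat,
                "cv_qc": round(qc_cv(table, f), 2),
                "msi_level": int(rng.choice([1, 2, 3, 4], p=[0.1, 0.5, 0.3, 0.1])),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------


def theoretical_auc(
    effects: EffectSpec,
    features: list[str],
    groups: tuple[str, str] = ("HC", "RA"),
) -> float:
    """Closed-form two-class AUC of the Bayes-optimal linear score for
    the generator's Gaussian log-scale model.

    For mean difference ``delta`` and common covariance ``Sigma`` the
    optimal linear combination has AUC ``Phi(sqrt(delta' Sigma^-1 delta / 2))``.
    Only configurations with equal covariance across groups (no drift,
    no censoring) are covered.
    """
    if effects.drift_amplitude != 0 or effects.missingness != 0:
        raise UnsupportedOracleError(
            "closed-form AUC requires drift_amplitude=0 and missingness=0 "
            "(unequal/order-dependent covariance is not supported)"
        )
    factors = effects.resolved_factors()
    lam = _feature_loadings(list(features), factors)
    sigma = effects.noise_sd
    cov = sigma**2 * (np.eye(len(features)) + lam @ lam.T)
    sd_within = sigma * np.sqrt(1.0 + (lam**2).sum(axis=1))
    delta = np.array(
        [
            (
                effects.class_effect(feature_class(f), groups[1])
                - effects.class_effect(feature_class(f), groups[0])
            )
            * sd_within[j]
            for j, f in enumerate(features)
        ]
    )
    m2 = float(delta @ np.linalg.solve(cov, delta))
    return float(norm.cdf(np.sqrt(m2 / 2.0)))
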