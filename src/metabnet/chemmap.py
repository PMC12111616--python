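"""Chemical-similarity mapping of metabolites.

Metabolites are fingerprinted from their SMILES (hashed path-based bit
vectors), compared by Tanimoto distance (1 - Jaccard on bits),
clustered with Ward-linkage hierarchical clustering (K chosen to
maximize mean silhouette width), subdivided into modules by cutting
branches of the tree, and each module's abundances are summarized into
one per-sample score (weighted metabolite chemical similarity analysis,
WMCSA) realized as the sign-oriented first principal component of the
standardized member abundances.  Module scores are compared across
study groups with Kruskal-Wallis plus Dunn's test (Bonferroni over the
three pairwise comparisons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .cohort_stats import dunn_test, kruskal_wallis
from .errors import ConfigurationError
from .netcorr import classical_mds
from .tables import FeatureTable


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------


def fingerprint(smiles: str, n_bits: int = 1024) -> np.ndarray | None:
    """Hashed path-based structural fingerprint of a SMILES string as a
    boolean vector; None (with a warning) if the SMILES fails to parse."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        warnings.warn(f"unparseable SMILES excluded: {smiles!r}", stacklevel=2)
        return None
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a AND b| / |a OR b| of two bit vectors (1.0 for
    two empty fingerprints)."""
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_distance_matrix(
    annotations: pd.DataFrame, n_bits: int = 1024
) -> pd.DataFrame:
    """Pairwise 1 - Tanimoto distances from an annotation table with a
    ``smiles`` column (or precomputed ``fp_bits`` bit strings).
    Metabolites with unparseable SMILES are dropped."""
    fps, ids = [], []
    for fid, row in annotations.iterrows():
        if "smiles" in annotations.columns and isinstance(row.get("smiles"), str):
            fp = fingerprint(row["smiles"], n_bits)
        elif "fp_bits" in annotations.columns:
            bits = str(row["fp_bits"])
            fp = np.frombuffer(bits.encode(), dtype=np.uint8) == ord("1")
        else:
            raise ConfigurationError("annotations need a smiles or fp_bits column")
        if fp is not None:
            fps.append(fp)
            ids.append(fid)
    mat = np.array(fps)
    inter = (mat[:, None, :] & mat[None, :, :]).sum(-1)
    union = (mat[:, None, :] | mat[None, :, :]).sum(-1)
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# clustering and modules
# ---------------------------------------------------------------------------


@dataclass
class ChemicalClustering:
    """Hierarchical chemical clustering with a nested module partition."""

    distance: pd.DataFrame
    linkage: np.ndarray
    clusters: pd.Series           # cluster id per metabolite (1..K)
    silhouette_by_k: dict[int, float]
    modules: pd.Series | None = None  # finer partition nested in clusters
    layout: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.clusters.nunique())


def detect_clusters(
    dist: pd.DataFrame, k_range: tuple[int, int] = (2, 10)
) -> ChemicalClustering:
    """Ward-linkage hierarchical clustering of a Tanimoto distance
    matrix; the number of clusters maximizes the mean silhouette width
    over ``k_range`` (ties broken toward the smallest K)."""
    d = dist.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ConfigurationError("distance matrix must be symmetric")
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="ward")
    if condensed.max() == 0:
        warnings.warn("all metabolites identical; single degenerate cluster",
                      stacklevel=2)
        clusters = pd.Series(1, index=dist.index)
        return ChemicalClustering(dist, z, clusters, {1: float("nan")})

    scores: dict[int, float] = {}
    best_k, best_s = None, -np.inf
    lo, hi = k_range
    for k in range(lo, min(hi, len(dist) - 1) + 1):
        labels = fcluster(z, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = float(silhouette_score(d, labels, metric="precomputed"))
        scores[k] = s
        if s > best_s + 1e-12:  # strict improvement; ties keep smaller K
            best_k, best_s = k, s
    if best_k is None:
        raise ConfigurationError("no valid clustering in the requested range")
    clusters = pd.Series(
        fcluster(z, best_k, criterion="maxclust"), index=dist.index,
        name="cluster",
    )
    layout = pd.DataFrame(
        classical_mds(d, 2)[0], index=dist.index, columns=["x", "y"]
    )
    return ChemicalClustering(dist, z, clusters, scores, layout=layout)


def split_modules(
    clustering: ChemicalClustering, min_size: int = 3
) -> pd.Series:
    """Divide each cluster into modules by recursively cutting branches
    of the cluster's subtree: a branch splits while both children would
    have at least ``min_size`` members; members falling in undersized
    side branches join the nearest module by average Tanimoto distance.
    Stores and returns the module assignment (labels ``c.m``)."""
    if min_size < 2:
        raise ConfigurationError("min_size must be at least 2")
    dist = clustering.distance
    modules = pd.Series(index=dist.index, dtype=object, name="module")
    for c in sorted(clustering.clusters.unique()):
        members = list(clustering.clusters.index[clustering.clusters == c])
        if len(members) < 2 * min_size:
            modules[members] = f"{c}.1"
            continue
        sub = dist.loc[members, members].to_numpy()
        z = linkage(squareform(sub, checks=False), method="ward")
        labels = _cut_branches(z, len(members), min_size)
        leftovers = [i for i, m in enumerate(labels) if m is None]
        assigned = {m for m in labels if m is not None}
        for i in leftovers:
            best = min(
                assigned,
                key=lambda m: np.mean(
                    [sub[i, j] for j, mj in enumerate(labels) if mj == m]
                ),
            )
            labels[i] = best
        for i, m in enumerate(labels):
            modules[members[i]] = f"{c}.{m}"
    clustering.modules = modules
    return modules


def _cut_branches(z: np.ndarray, n: int, min_size: int) -> list:
    """Recursive branch cutting on one scipy linkage tree.  A branch
    splits while both children hold at least ``min_size`` leaves; when
    only one side is large enough the small side's leaves are left as
    None (joined to the nearest module afterwards).  Returns a module
    label per leaf."""
    children = {n + i: (int(z[i, 0]), int(z[i, 1])) for i in range(len(z))}

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    labels: list = [None] * n
    counter = [0]

    def assign(node: int) -> None:
        lv = leaves(node)
        if node < n or len(lv) < 2 * min_size:
            counter[0] += 1
            for leaf in lv:
                labels[leaf] = counter[0]
            return
        a, b = children[node]
        na, nb = len(leaves(a)), len(leaves(b))
        if na >= min_size and nb >= min_size:
            assign(a)
            assign(b)
        else:
            assign(a if na >= nb else b)  # small side stays None

    assign(n + len(z) - 1)
    return labels


# ---------------------------------------------------------------------------
# WMCSA
# ---------------------------------------------------------------------------


@dataclass
class ModuleSummary:
    """One score per module per sample, plus membership and orientation."""

    scores: pd.DataFrame          # samples x modules, zero mean unit variance
    members: dict[str, list[str]]
    orientation: dict[str, float]


def wmcsa(table: FeatureTable, modules: pd.Series) -> ModuleSummary:
    """Summarize each chemical module into one per-sample score: the
    first principal component of the standardized member abundances,
    sign-oriented to correlate positively with the member mean and
    standardized to zero mean / unit variance.  Size-1 modules pass the
    standardized feature through."""
    bio = table.biological
    scores, members, orientation = {}, {}, {}
    for m in sorted(modules.dropna().unique(), key=str):
        ids = [f for f in modules.index[modules == m] if f in bio.columns]
        if not ids:
            continue
        sub = np.log(bio[ids])
        sd = sub.std(ddof=1)
        zero = sd < 1e-10  # constants up to float rounding
        if zero.all():
            raise ConfigurationError(f"module {m!r} has only zero-variance members")
        std = (sub - sub.mean()).div(sd.where(~zero, np.inf))
        if len(ids) == 1:
            score = std.iloc[:, 0].to_numpy()
            sign = 1.0
        else:
            u, s, vt = np.linalg.svd(std.to_numpy(), full_matrices=False)
            score = u[:, 0] * s[0]
            mean_profile = std.mean(axis=1).to_numpy()
            sign = 1.0 if np.dot(score, mean_profile) >= 0 else -1.0
            score = sign * score
        score = (score - score.mean()) / score.std(ddof=1)
        scores[str(m)] = score
        members[str(m)] = ids
        orientation[str(m)] = sign
    return ModuleSummary(
        pd.DataFrame(scores, index=bio.index), members, orientation
    )


def module_group_tests(
    summary: ModuleSummary, groups: pd.Series
) -> pd.DataFrame:
    """Kruskal-Wallis across study groups per module plus Dunn's
    pairwise z tests with Bonferroni correction over the three pairwise
    comparisons."""
    rows = []
    for m in summary.scores.columns:
        values = {
            g: summary.scores.loc[groups.index[groups == g], m].to_numpy()
            for g in groups.unique()
        }
        h, p = kruskal_wallis(list(values.values()))
        dunn = dunn_test(values, adjust="bonferroni")
        row = {"module": m, "kw_h": h, "kw_p": p}
        for (g1, g2), res in dunn.items():
            row[f"dunn_p_{g1}_vs_{g2}"] = res["p_adjusted"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")


def group_median_heatmap(
    table: FeatureTable, modules: pd.Series
) -> pd.DataFrame:
    """Row-standardized per-group medians of each feature, ordered by
    module — the tabular form of the cluster heatmaps."""
    bio = np.log(table.biological)
    groups = table.groups()
    med = pd.DataFrame(
        {g: bio.loc[groups.index[groups == g]].median() for g in groups.unique()}
    )
    z = med.sub(med.mean(axis=1), axis=0).div(med.std(axis=1, ddof=1), axis=0)
    z["module"] = modules.reindex(z.index)
    return z.sort_values("module")
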