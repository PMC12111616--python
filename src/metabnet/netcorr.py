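"""Metabolite-cytokine and metabolite-clinical correlation networks.

Within one disease group, every pair of panel variables is tested with
Spearman's rank correlation; pairs with p below the significance level
become signed edges.  Edge distances ``1 - |rho|`` feed an all-pairs
shortest-path (Floyd-Warshall) completion, and classical (Torgerson)
multidimensional scaling of the geodesic matrix gives the 2-D layout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedStatisticError

#: cytokines significantly elevated per disease, the default network panel
from .synthdata import CYTOKINE_PANELS

CLINICAL_PANEL = (
    "hdl", "ldl", "tc", "esr", "lymphocytes", "neutrophils",
    "duration", "activity_score",
)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value; exact by permutation
    enumeration for n <= 9 (valid under ties), t-approximation above.

    Requires at least 4 complete pairs; ties get average ranks.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ConfigurationError(f"need >=4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        # t-approximation, guarded at |rho| = 1
        r = min(max(rho, -1 + 1e-15), 1 - 1e-15)
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Permutation-exact two-sided p: the fraction of permutations of y
    whose |rho| reaches |rho_obs| (1e-12 slack for float ties)."""
    n = len(rx)
    xc = rx - rx.mean()
    yc = ry - ry.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    perms = np.array(list(itertools.permutations(yc)))
    rhos = perms @ xc / denom
    count = int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
    return count / len(perms)


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------


@dataclass
class CorrelationNetwork:
    """Signed significant-Spearman network over a variable panel."""

    nodes: pd.DataFrame   # index: variable, column: kind
    edges: pd.DataFrame   # node1, node2, rho, p, sign
    alpha: float
    distance_mode: str = "absolute"  # 'absolute': 1-|rho|; 'signed': 1-rho
    geodesic_: pd.DataFrame | None = field(default=None, repr=False)

    def distance_matrix(self) -> pd.DataFrame:
        """Direct distances: connected pairs ``1 - |rho|`` (or
        ``1 - rho`` in signed mode), non-significant pairs +inf, zero
        diagonal.  The edge sign lives on the edge attribute, not in
        the metric."""
        ids = list(self.nodes.index)
        d = np.full((len(ids), len(ids)), np.inf)
        np.fill_diagonal(d, 0.0)
        pos = {v: i for i, v in enumerate(ids)}
        for _, e in self.edges.iterrows():
            rho = e["rho"]
            dist = 1.0 - (abs(rho) if self.distance_mode == "absolute" else rho)
            i, j = pos[e["node1"]], pos[e["node2"]]
            d[i, j] = d[j, i] = dist
        return pd.DataFrame(d, index=ids, columns=ids)

    def geodesic(self) -> pd.DataFrame:
        if self.geodesic_ is None:
            d = self.distance_matrix()
            g = floyd_warshall(d.to_numpy())
            self.geodesic_ = pd.DataFrame(g, index=d.index, columns=d.columns)
        return self.geodesic_

    def layout(self) -> pd.DataFrame:
        """2-D classical-MDS embedding of the geodesic matrix;
        disconnected pairs are set to 1.5x the largest finite geodesic
        before embedding."""
        g = self.geodesic().to_numpy().copy()
        finite = g[np.isfinite(g)]
        if np.isinf(g).any():
            g[np.isinf(g)] = (finite.max() if finite.size else 1.0) * 1.5
        coords, _ = classical_mds(g, 2)
        return pd.DataFrame(coords, index=self.geodesic().index, columns=["x", "y"])

    def degrees(self) -> pd.Series:
        deg = pd.Series(0, index=self.nodes.index, dtype=int)
        for _, e in self.edges.iterrows():
            deg[e["node1"]] += 1
            deg[e["node2"]] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for v, row in self.nodes.iterrows():
            g.add_node(v, kind=row["kind"])
        for _, e in self.edges.iterrows():
            g.add_edge(e["node1"], e["node2"], rho=e["rho"], p=e["p"],
                       sign=e["sign"])
        return g


def build_network(
    data: pd.DataFrame,
    node_kinds: dict[str, str],
    alpha: float = 0.05,
    distance_mode: str = "absolute",
) -> CorrelationNetwork:
    """Correlate every pair of panel variables (columns of ``data``,
    rows = the disease group's samples) and keep significant pairs as
    signed edges.

    ``node_kinds`` maps each variable to ``metabolite`` / ``cytokine``
    / ``clinical``; duplicated or absent variables are configuration
    errors.
    """
    panel = list(node_kinds)
    if len(panel) != len(set(panel)):
        raise ConfigurationError("duplicated variables in the panel")
    missing = [v for v in panel if v not in data.columns]
    if missing:
        raise ConfigurationError(f"panel variables absent from data: {missing}")
    if len(data) < 4:
        raise ConfigurationError("need at least 4 samples")
    edges = []
    for v1, v2 in itertools.combinations(panel, 2):
        try:
            rho, p = spearman(data[v1].to_numpy(), data[v2].to_numpy())
        except (UndefinedStatisticError, ConfigurationError):
            continue
        if p < alpha:
            edges.append(
                {"node1": v1, "node2": v2, "rho": rho, "p": p,
                 "sign": int(np.sign(rho))}
            )
    nodes = pd.DataFrame({"kind": pd.Series(node_kinds)})
    nodes.index.name = "variable"
    edge_df = pd.DataFrame(edges, columns=["node1", "node2", "rho", "p", "sign"])
    return CorrelationNetwork(nodes, edge_df, alpha, distance_mode)


def disease_panel(
    selected_metabolites: list[str],
    disease: str,
    targets: str = "cytokines",
) -> dict[str, str]:
    """Default node panel for one disease network: the differential
    metabolites plus either the disease's elevated-cytokine panel or
    the clinical panel (HDL, LDL, total cholesterol, ESR, blood counts,
    duration, activity score)."""
    kinds = {m: "metabolite" for m in selected_metabolites}
    if targets == "cytokines":
        for c in CYTOKINE_PANELS[disease]:
            kinds[c] = "cytokine"
    elif targets == "hdl":
        kinds["hdl"] = "clinical"
    elif targets == "clinical":
        for c in CLINICAL_PANEL:
            kinds[c] = "clinical"
    else:
        raise ConfigurationError(f"unknown target set {targets!r}")
    return kinds


# ---------------------------------------------------------------------------
# shortest paths and embedding
# ---------------------------------------------------------------------------


def floyd_warshall(dist: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the Floyd-Warshall recurrence on a
    symmetric non-negative weight matrix (+inf = no edge).  Disconnected
    pairs stay +inf."""
    d = np.asarray(dist, float).copy()
    if (d[np.isfinite(d)] < 0).any():
        raise ConfigurationError("negative edge weights not allowed")
    n = d.shape[0]
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def classical_mds(dist: np.ndarray, n_dim: int = 2) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix and embeds on the top
    eigenvectors.  Returns (coordinates, stress) where stress is the
    Kruskal stress-1 of the reproduced distances.  Deterministic up to
    rotation/reflection of the configuration.
    """
    d = np.asarray(dist, float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise ConfigurationError("distance matrix must be symmetric")
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, n_dim)), 0.0
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dim]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    rep = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, 1)
    denom = float((d[iu] ** 2).sum())
    stress = float(np.sqrt(((d[iu] - rep[iu]) ** 2).sum() / denom)) if denom else 0.0
    return coords, stress
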