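"""Fingerprints, Tanimoto clustering, modules, WMCSA summaries."""

import numpy as np
import pandas as pd
import pytest

from metabnet.chemmap import (
    detect_clusters,
    fingerprint,
    group_median_heatmap,
    module_group_tests,
    split_modules,
    tanimoto,
    tanimoto_distance_matrix,
    wmcsa,
)
from metabnet.errors import ConfigurationError
from metabnet.synthdata import _smiles_template, feature_class

from conftest import toy_table


def _series_annotations(series: dict[str, list[str]]) -> pd.DataFrame:
    rows = [
        {"feature_id": f"{cls}_{i}", "smiles": s}
        for cls, smis in series.items()
        for i, s in enumerate(smis)
    ]
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# fingerprints / Tanimoto
# ---------------------------------------------------------------------------


def test_identical_smiles_identical_fingerprints():
    a = fingerprint("CCO")
    b = fingerprint("CCO")
    assert np.array_equal(a, b)
    assert tanimoto(a, b) == 1.0


def test_disjoint_substructures_near_zero_tanimoto():
    # frozen regression pair: linear alkane vs aromatic amine
    t = tanimoto(fingerprint("CCCCCCCC"), fingerprint("Nc1ccccc1O"))
    assert t < 0.05


def test_tanimoto_matches_bit_counting():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.random(64) < 0.3
        b = rng.random(64) < 0.3
        expected = (
            1.0
            if not (a | b).any()
            else sum(x and y for x, y in zip(a, b)) / sum(x or y for x, y in zip(a, b))
        )
        assert tanimoto(a, b) == pytest.approx(expected)


def test_unparseable_smiles_excluded_with_warning():
    ann = _series_annotations({"ok": ["CCO", "CCN"], "bad": ["not-a-smiles"]})
    with pytest.warns(UserWarning, match="unparseable"):
        dist = tanimoto_distance_matrix(ann)
    assert "bad_0" not in dist.index
    assert dist.shape == (2, 2)


def test_distance_matrix_is_metric_like(small_cohort):
    _, _, annotations = small_cohort
    dist = tanimoto_distance_matrix(annotations.head(20))
    d = dist.to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert d.min() >= 0.0 and d.max() <= 1.0


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def test_two_homologous_series_recovered_exactly():
    from sklearn.metrics import adjusted_rand_score

    ann = _series_annotations(
        {
            "fa": ["OC(=O)" + "C" * n for n in range(4, 12)],
            "aryl": ["OC(=O)" + "C" * n + "c1ccccc1" for n in range(2, 10)],
        }
    )
    clustering = detect_clusters(tanimoto_distance_matrix(ann))
    assert clustering.n_clusters == 2
    truth = [fid.split("_")[0] for fid in clustering.clusters.index]
    assert adjusted_rand_score(truth, clustering.clusters.to_numpy()) == 1.0


def test_identical_metabolites_degenerate_single_cluster():
    ann = _series_annotations({"x": ["CCO"] * 5})
    with pytest.warns(UserWarning, match="identical"):
        clustering = detect_clusters(tanimoto_distance_matrix(ann))
    assert clustering.n_clusters == 1


def test_silhouette_matches_direct_formula():
    """Mean silhouette of a 6-point, 2-cluster hand case agrees with
    the direct a/b formula."""
    from sklearn.metrics import silhouette_score

    d = np.array(
        [
            [0.0, 0.1, 0.2, 0.9, 0.8, 0.9],
            [0.1, 0.0, 0.1, 0.8, 0.9, 0.8],
            [0.2, 0.1, 0.0, 0.9, 0.9, 0.9],
            [0.9, 0.8, 0.9, 0.0, 0.2, 0.1],
            [0.8, 0.9, 0.9, 0.2, 0.0, 0.1],
            [0.9, 0.8, 0.9, 0.1, 0.1, 0.0],
        ]
    )
    labels = np.array([0, 0, 0, 1, 1, 1])
    expected = []
    for i in range(6):
        same = [j for j in range(6) if labels[j] == labels[i] and j != i]
        other = [j for j in range(6) if labels[j] != labels[i]]
        a = d[i, same].mean()
        b = d[i, other].mean()
        expected.append((b - a) / max(a, b))
    assert silhouette_score(d, labels, metric="precomputed") == pytest.approx(
        np.mean(expected)
    )


def test_non_symmetric_distance_rejected():
    d = pd.DataFrame([[0.0, 0.5], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ConfigurationError):
        detect_clusters(d)


def test_six_class_panel_recovery():
    """Synthetic six-class SMILES panel: clustering matches the true
    chemical classes (ARI >= 0.8)."""
    from sklearn.metrics import adjusted_rand_score

    comp = {
        "glycerolipids": 20, "cyclic": 15, "phospholipids_pc": 20,
        "phospholipids_pe": 20, "sphingolipids": 18, "fatty_acids": 16,
    }
    rows = [
        {"feature_id": f"{cls}_{i:03d}", "smiles": _smiles_template(cls, i)}
        for cls, n in comp.items()
        for i in range(n)
    ]
    ann = pd.DataFrame(rows).set_index("feature_id")
    clustering = detect_clusters(tanimoto_distance_matrix(ann))
    truth = [feature_class(f) for f in clustering.clusters.index]
    assert adjusted_rand_score(truth, clustering.clusters.to_numpy()) >= 0.8


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


def test_small_cluster_becomes_single_module():
    ann = _series_annotations({"fa": ["OC(=O)CC", "OC(=O)CCC", "OC(=O)CCCC"]})
    dist = tanimoto_distance_matrix(ann)
    clustering = detect_clusters(dist, (2, 2))
    clustering.clusters[:] = 1  # force one cluster of size 3
    modules = split_modules(clustering, min_size=3)
    assert modules.nunique() == 1


def test_two_sub_series_split_into_modules():
    ann = _series_annotations(
        {
            "short": ["OC(=O)" + "C" * n for n in (2, 3, 4)],
            "long": ["OC(=O)" + "C" * n for n in (14, 15, 16)],
        }
    )
    dist = tanimoto_distance_matrix(ann)
    clustering = detect_clusters(dist, (2, 2))
    clustering.clusters[:] = 1  # treat all six acids as one cluster
    modules = split_modules(clustering, min_size=3)
    assert modules.nunique() == 2
    by_module = modules.groupby(modules).groups
    kinds = [
        {fid.split("_")[0] for fid in members} for members in by_module.values()
    ]
    assert all(len(k) == 1 for k in kinds)


def test_modules_partition_without_orphans(small_cohort):
    _, _, annotations = small_cohort
    dist = tanimoto_distance_matrix(annotations)
    clustering = detect_clusters(dist)
    modules = split_modules(clustering, min_size=3)
    assert modules.notna().all()
    assert set(modules.index) == set(dist.index)
    # modules refine clusters
    for m in modules.unique():
        clusters = clustering.clusters[modules.index[modules == m]]
        assert clusters.nunique() == 1


def test_min_size_below_two_rejected(small_cohort):
    _, _, annotations = small_cohort
    clustering = detect_clusters(tanimoto_distance_matrix(annotations.head(10)))
    with pytest.raises(ConfigurationError):
        split_modules(clustering, min_size=1)


# ---------------------------------------------------------------------------
# WMCSA
# ---------------------------------------------------------------------------


def test_wmcsa_identical_members_equal_standardized_feature():
    rng = np.random.default_rng(5)
    base = rng.uniform(50, 150, 12)
    table = toy_table(
        {"f1": [1.0, 1.0, 1.0], "f2": [1.0, 1.0, 1.0]},
        bio_values={"f1": base, "f2": base},
    )
    modules = pd.Series({"f1": "1.1", "f2": "1.1"})
    summary = wmcsa(table, modules)
    logs = np.log(base)
    std = (logs - logs.mean()) / logs.std(ddof=1)
    assert np.allclose(summary.scores["1.1"], std)


def test_wmcsa_summary_standardized_and_oriented(clean_cohort):
    clean, _, annotations = clean_cohort
    modules = pd.Series(
        {f: feature_class(f) for f in clean.data.columns}, name="module"
    )
    summary = wmcsa(clean, modules)
    scores = summary.scores
    assert np.allclose(scores.mean(), 0.0, atol=1e-10)
    assert np.allclose(scores.std(ddof=1), 1.0, atol=1e-10)
    logs = np.log(clean.biological)
    for m, members in summary.members.items():
        std = (logs[members] - logs[members].mean()) / logs[members].std(ddof=1)
        r = np.corrcoef(scores[m], std.mean(axis=1))[0, 1]
        assert r >= 0


def test_wmcsa_first_pc_explains_most_variance(clean_cohort):
    """The module summary captures at least as much member variance as
    any single standardized member profile (first-PC optimality)."""
    clean, _, _ = clean_cohort
    members = [f for f in clean.data.columns if feature_class(f) == "sphingolipids"]
    modules = pd.Series("s", index=members)
    summary = wmcsa(clean, modules)
    logs = np.log(clean.biological[members])
    std = (logs - logs.mean()) / logs.std(ddof=1)
    def explained(profile):
        p = np.asarray(profile, float)
        p = p / np.linalg.norm(p)
        return float(((std.to_numpy().T @ p) ** 2).sum())
    score_explained = explained(summary.scores["s"])
    for f in members:
        assert score_explained >= explained(std[f]) - 1e-9


def test_wmcsa_rejects_all_zero_variance_modules():
    table = toy_table(
        {"f1": [1.0, 1.0, 1.0]},
        bio_values={"f1": np.full(12, 10.0)},
    )
    with pytest.raises(ConfigurationError):
        wmcsa(table, pd.Series({"f1": "m"}))


def test_module_group_tests_reports_dunn_bonferroni(clean_cohort):
    clean, _, _ = clean_cohort
    modules = pd.Series(
        {f: feature_class(f) for f in clean.data.columns}, name="module"
    )
    summary = wmcsa(clean, modules)
    tests = module_group_tests(summary, clean.groups())
    assert "kw_p" in tests.columns
    assert tests["kw_p"].between(0, 1).all()
    dunn_cols = [c for c in tests.columns if c.startswith("dunn_p")]
    assert len(dunn_cols) == 3
    # planted disease effects make lipid modules significant
    assert tests.loc["sphingolipids", "kw_p"] < 0.01


def test_planted_module_effect_detected_repeatedly():
    """A coherent -1 SD module effect in RA is picked up by the
    Kruskal-Wallis test on its WMCSA summary (p < 0.01) in >=90% of 20
    simulated cohorts."""
    from metabnet.synthdata import CohortDesign, EffectSpec, simulate_cohort

    hits = 0
    for seed in range(20):
        design = CohortDesign(
            n_features=10,
            class_composition={"sphingolipids": 5, "cyclic": 5},
            seed=seed,
        )
        effects = EffectSpec(
            class_effects={"sphingolipids": {"RA": -1.0, "SLE": -1.0}},
            drift_amplitude=0.0,
            missingness=0.0,
            latent_strength=0.0,
        )
        table, _, _ = simulate_cohort(design, effects)
        modules = pd.Series(
            {f: feature_class(f) for f in table.data.columns}
        )
        summary = wmcsa(table, modules)
        tests = module_group_tests(summary, table.groups())
        hits += tests.loc["sphingolipids", "kw_p"] < 0.01
    assert hits >= 18


def test_group_median_heatmap_is_row_standardized(clean_cohort):
    clean, _, _ = clean_cohort
    modules = pd.Series(
        {f: feature_class(f) for f in clean.data.columns}, name="module"
    )
    heat = group_median_heatmap(clean, modules)
    z = heat.drop(columns="module")
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-10)
    assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-10)
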