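"""Scaling, OPLS-DA/VIP, Mann-Whitney/BH testing, selection rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metabnet.diffsel import (
    cross_val_q2,
    differential_analysis,
    fit_oplsda,
    log_pareto,
    select_features,
    univariate_test,
    vip_scores,
    DifferentialResult,
)
from metabnet.errors import ConfigurationError

from conftest import toy_table


# ---------------------------------------------------------------------------
# log / Pareto scaling
# ---------------------------------------------------------------------------


def test_log_pareto_hand_computation():
    # log values {1, 2, 3}: mean 2, SD 1 -> Pareto-scaled {-1, 0, 1}
    values = pd.DataFrame({"f": np.exp([1.0, 2.0, 3.0])})
    scaled = log_pareto(values)
    assert np.allclose(scaled["f"], [-1.0, 0.0, 1.0])


def test_pareto_variance_equals_log_sd():
    rng = np.random.default_rng(1)
    values = pd.DataFrame(np.exp(rng.normal(5, 2, (40, 6))))
    scaled = log_pareto(values)
    log_sd = np.log(values).std(ddof=1)
    assert np.allclose(scaled.var(ddof=1), log_sd)


def test_log_pareto_constant_feature_zeroed():
    values = pd.DataFrame({"f": [2.0, 2.0, 2.0], "g": [1.0, 2.0, 4.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        scaled = log_pareto(values)
    assert (scaled["f"] == 0).all()
    assert scaled["g"].std() > 0


def test_log_pareto_requires_positive():
    with pytest.raises(ConfigurationError):
        log_pareto(pd.DataFrame({"f": [1.0, 0.0, 2.0]}))


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _pls1_oracle(x, y):
    """Independent single-component PLS1: w = X'y / ||X'y||, t = Xw."""
    yc = y - y.mean()
    w = x.T @ yc
    w = w / np.linalg.norm(w)
    return x @ w


@pytest.fixture(scope="module")
def opls_data():
    rng = np.random.default_rng(7)
    n, p = 30, 12
    y = np.repeat([0.0, 1.0], n // 2)
    x = rng.standard_normal((n, p))
    x[:, 0] += 1.5 * y
    x[:, 1] -= 1.0 * y
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    return x, y


def test_zero_ortho_reduces_to_pls1(opls_data):
    x, y = opls_data
    model = fit_oplsda(x, y, n_ortho=0)
    assert np.abs(model.scores - _pls1_oracle(x, y)).max() < 1e-6


def test_predictive_orthogonal_scores_uncorrelated(opls_data):
    x, y = opls_data
    model = fit_oplsda(x, y, n_ortho=2)
    for a in range(model.n_ortho):
        r = np.corrcoef(model.scores, model.ortho_scores[:, a])[0, 1]
        assert abs(r) < 1e-8
    assert np.linalg.norm(model.weights) == pytest.approx(1.0)
    for w_o in model.ortho_weights:
        assert np.linalg.norm(w_o) == pytest.approx(1.0)


def test_duplicating_samples_leaves_model_invariant(opls_data):
    x, y = opls_data
    m1 = fit_oplsda(x, y, n_ortho=1)
    m2 = fit_oplsda(np.vstack([x, x]), np.concatenate([y, y]), n_ortho=1)
    assert np.allclose(m2.weights, m1.weights)
    assert np.allclose(m2.scores[: len(y)], m1.scores)
    assert np.allclose(m2.scores[len(y):], m1.scores)


def test_oplsda_requires_three_per_class():
    x = np.random.default_rng(0).standard_normal((5, 3))
    with pytest.raises(ConfigurationError):
        fit_oplsda(x, np.array([0, 0, 1, 1, 1.0]))


def test_shuffled_labels_give_nonpositive_q2(opls_data):
    """Permutation null: cross-validated Q2 <= 0 for >=90% of 50
    label shuffles."""
    x, y = opls_data
    rng = np.random.default_rng(3)
    bad = 0
    for i in range(50):
        q2 = cross_val_q2(x, rng.permutation(y), n_ortho=1, seed=i)
        bad += q2 > 0
    assert bad <= 5


def test_informative_labels_give_positive_q2(opls_data):
    x, y = opls_data
    assert cross_val_q2(x, y, n_ortho=1, seed=0) > 0.2


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------


def test_vip_mean_square_is_one(opls_data):
    x, y = opls_data
    vip = vip_scores(fit_oplsda(x, y, n_ortho=1))
    assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-10)


def test_single_feature_vip_is_one():
    rng = np.random.default_rng(0)
    y = np.repeat([0.0, 1.0], 10)
    x = (y + 0.5 * rng.standard_normal(20)).reshape(-1, 1)
    x = (x - x.mean()) / x.std(ddof=1)
    vip = vip_scores(fit_oplsda(x, y, n_ortho=0))
    assert vip[0] == pytest.approx(1.0)


def test_planted_feature_attains_maximal_vip():
    """One discriminative feature among 50 nulls: it tops the VIP
    ranking with VIP > 1 in >=95% of 100 simulations."""
    rng = np.random.default_rng(42)
    hits = 0
    y = np.repeat([0.0, 1.0], 12)
    for _ in range(100):
        x = rng.standard_normal((24, 51))
        x[:, 0] += 2.0 * y
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        vip = vip_scores(fit_oplsda(x, y, n_ortho=0))
        hits += vip[0] == vip.max() and vip[0] > 1
    assert hits >= 95


# ---------------------------------------------------------------------------
# univariate tests and BH
# ---------------------------------------------------------------------------


def test_identical_groups_give_p_one_fc_one():
    same = np.tile([10.0, 20.0, 30.0, 40.0], 3)
    table = toy_table({"f1": [1.0, 1.0, 1.0]}, bio_values={"f1": same})
    diff = univariate_test(table, ("HC", "RA"))
    assert diff.frame.loc["f1", "p_value"] == pytest.approx(1.0)
    assert diff.frame.loc["f1", "fold_change"] == pytest.approx(1.0)


def test_bh_hand_computation():
    from statsmodels.stats.multitest import multipletests

    q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    assert np.allclose(q, 0.04)


def test_mann_whitney_p_matches_label_permutation_oracle():
    """Small-sample p agrees with brute-force enumeration of all group
    relabelings (the exact null of the rank-sum statistic)."""
    from scipy.stats import mannwhitneyu

    x = np.array([1.2, 3.4, 2.2, 5.0])
    y = np.array([4.1, 6.3, 5.9, 7.0])
    p = mannwhitneyu(x, y, alternative="two-sided").pvalue
    pooled = np.concatenate([x, y])
    u_obs = sum(
        1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y
    )
    count = total = 0
    for idx in itertools.combinations(range(8), 4):
        xs = pooled[list(idx)]
        ys = pooled[[i for i in range(8) if i not in idx]]
        u = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)
        count += abs(u - 8) >= abs(u_obs - 8) - 1e-12  # center n1*n2/2 = 8
        total += 1
    assert p == pytest.approx(count / total, abs=1e-12)


def test_fold_change_is_ratio_of_group_medians():
    hc = np.array([10.0, 20.0, 30.0, 40.0])
    ra = np.array([5.0, 10.0, 15.0, 20.0])
    sle = np.array([1.0, 1.0, 1.0, 1.0])
    table = toy_table(
        {"f1": [1.0, 1.0, 1.0]},
        bio_values={"f1": np.concatenate([hc, ra, sle])},
    )
    diff = univariate_test(table, ("HC", "RA"))
    assert diff.frame.loc["f1", "fold_change"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# selection rule
# ---------------------------------------------------------------------------


def _diff_fixture(vip, q):
    frame = pd.DataFrame(
        {"p_value": q / 2, "q_value": q, "fold_change": 1.0},
        index=[f"f{i}" for i in range(len(q))],
    )
    return (
        DifferentialResult(("HC", "RA"), frame),
        pd.Series(vip, index=frame.index),
    )


@pytest.mark.parametrize(
    "vip,q,expected",
    [
        (1.5, 0.01, True),
        (0.99, 0.001, False),   # VIP below 1 never selected
        (1.5, 0.05, False),     # boundary q: strict inequality
        (1.0, 0.01, False),     # boundary VIP: strict inequality
    ],
)
def test_selection_rule_boundaries(vip, q, expected):
    diff, vips = _diff_fixture(np.array([vip]), np.array([q]))
    selected = select_features(diff, vips)
    assert (len(selected) == 1) == expected


def test_selection_raw_p_mode():
    diff, vips = _diff_fixture(np.array([1.5]), np.array([0.08]))
    # q = 0.08 fails FDR mode, but p = 0.04 passes raw-p mode
    assert select_features(diff, vips) == []
    diff2, vips2 = _diff_fixture(np.array([1.5]), np.array([0.08]))
    assert select_features(diff2, vips2, use_fdr=False) == ["f0"]


def test_selection_mismatched_ids_rejected():
    diff, vips = _diff_fixture(np.array([1.5, 1.2]), np.array([0.01, 0.02]))
    with pytest.raises(ConfigurationError):
        select_features(diff, vips.iloc[::-1])


def test_differential_analysis_end_to_end(clean_cohort):
    clean, _, _ = clean_cohort
    diff, model = differential_analysis(clean, "ra-hc")
    frame = diff.frame
    assert {"p_value", "q_value", "fold_change", "vip", "selected"} <= set(frame)
    assert (frame["fold_change"] > 0).all()
    # BH q monotone non-decreasing in p rank
    ordered = frame.sort_values("p_value")["q_value"].to_numpy()
    assert np.all(np.diff(ordered) >= -1e-12)
    # planted effects are found
    assert len(diff.selected) > 0
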