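"""Ridge fit, backward elimination, minimality, permutation and ΔR² tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurostage.explain import (
    ContributionCall,
    check_minimality,
    choose_lambda,
    class_fractions,
    coefficient_pvalues,
    contribution_delta,
    explainability_call,
    fit_penalized,
    iterative_select,
    minmax_normalize,
    pathway_scores,
    permutation_pvalue,
)


def ridge_stacked_oracle(X, Y, lam):
    """Independent ridge oracle: the penalized problem as an augmented
    ordinary least squares on [Xc; sqrt(lam) I], solved with lstsq."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = X.shape[1]
    X_aug = np.vstack([Xc, np.sqrt(lam) * np.eye(n)])
    Y_aug = np.vstack([Yc, np.zeros((n, Y.shape[1]))])
    B, *_ = np.linalg.lstsq(X_aug, Y_aug, rcond=None)
    return B


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_minmax_linear_map():
    values = pd.DataFrame({"s1": [0.0], "s2": [5.0], "s3": [10.0]},
                          index=["g"])
    out = minmax_normalize(values)
    np.testing.assert_allclose(out.loc["g"], [0.0, 0.5, 1.0])


def test_minmax_removes_constant_and_zero_genes():
    values = pd.DataFrame(
        {"s1": [1.0, 3.0, 0.0], "s2": [2.0, 3.0, 0.0]},
        index=["ok", "flat", "unexpressed"])
    out = minmax_normalize(values)
    assert list(out.index) == ["ok"]
    with pytest.raises(ValueError, match="constant"):
        minmax_normalize(values.loc[["flat"]])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_minmax_postconditions(seed):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(rng.normal(size=(6, 9)))
    out = minmax_normalize(values)
    np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-15)
    np.testing.assert_allclose(out.max(axis=1), 1.0, atol=1e-15)
    assert ((out.to_numpy() >= 0) & (out.to_numpy() <= 1)).all()


def test_pathway_scores_average_members():
    values = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]},
                          index=["g1", "g2"])
    scores = pathway_scores(values, {"P": ["g1", "g2"], "Q": ["g2"]})
    np.testing.assert_allclose(scores.loc["P"], [2.0, 3.0])
    np.testing.assert_allclose(scores.loc["Q"], [3.0, 4.0])


# ---------------------------------------------------------------------------
# penalized fit
# ---------------------------------------------------------------------------

def test_ridge_matches_stacked_oracle_on_random_instances(rng):
    """100 random small instances: coefficients agree with the augmented
    least-squares oracle to 1e-10."""
    for _ in range(100):
        m = int(rng.integers(5, 51))
        n = int(rng.integers(1, 11))
        k = int(rng.integers(1, 6))
        lam = float(rng.uniform(0.01, 10.0))
        X = rng.normal(size=(m, n))
        Y = rng.normal(size=(m, k))
        fit = fit_penalized(X, Y, lam)
        np.testing.assert_allclose(fit.B, ridge_stacked_oracle(X, Y, lam),
                                   atol=1e-10)


def test_spec_instance_6x2(rng):
    X = rng.normal(size=(6, 2))
    Y = rng.normal(size=(6, 1))
    fit = fit_penalized(X, Y, 0.5)
    np.testing.assert_allclose(fit.B, ridge_stacked_oracle(X, Y, 0.5),
                               atol=1e-10)


def test_identity_fit():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 5))
    fit = fit_penalized(X, X, 0.0)
    np.testing.assert_allclose(fit.B, np.eye(5), atol=1e-10)
    assert fit.r2 == pytest.approx(1.0)


def test_lambda_zero_agrees_with_least_squares(rng):
    X = rng.normal(size=(30, 6))
    Y = rng.normal(size=(30, 3))
    fit = fit_penalized(X, Y, 0.0)
    Xc, Yc = X - X.mean(axis=0), Y - Y.mean(axis=0)
    B_ls, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    np.testing.assert_allclose(fit.B, B_ls, atol=1e-8)


def test_collinear_x_at_lambda_zero_advises_ridge(rng):
    X = rng.normal(size=(20, 3))
    X = np.hstack([X, X[:, :1]])  # duplicated column
    with pytest.raises(ValueError, match="lambda > 0"):
        fit_penalized(X, rng.normal(size=(20, 1)), 0.0)
    fit_penalized(X, rng.normal(size=(20, 1)), 0.1)  # penalized: fine


def test_constant_response_flagged_degenerate(rng):
    X = rng.normal(size=(10, 2))
    Y = np.full((10, 1), 3.0)
    fit = fit_penalized(X, Y, 0.1)
    assert fit.degenerate
    assert fit.r2 == 0.0


def test_r2_monotone_nonincreasing_in_lambda(rng):
    X = rng.normal(size=(25, 4))
    Y = X @ rng.normal(size=(4, 2)) + rng.normal(scale=0.3, size=(25, 2))
    r2s = [fit_penalized(X, Y, lam).r2
           for lam in (0.0, 0.1, 1.0, 10.0, 100.0)]
    assert all(a >= b - 1e-12 for a, b in zip(r2s, r2s[1:]))


def test_r2_monotone_in_nested_candidate_sets(rng):
    """Basis of the minimality check: at lambda=0, adding predictors can
    only raise in-sample R^2."""
    X = rng.normal(size=(30, 6))
    Y = X[:, :3] @ rng.normal(size=(3, 2)) + rng.normal(scale=0.5,
                                                        size=(30, 2))
    r2s = [fit_penalized(X[:, :j], Y, 0.0).r2 for j in range(1, 7)]
    assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


def test_choose_lambda_prefers_penalty_for_noisy_overparameterized(rng):
    X = rng.normal(size=(12, 10))
    Y = rng.normal(size=(12, 2))
    lam = choose_lambda(X, Y)
    assert lam > 0


# ---------------------------------------------------------------------------
# coefficient p-values and backward elimination
# ---------------------------------------------------------------------------

def test_orthogonal_null_candidate_gets_large_p(rng):
    X = rng.normal(size=(50, 3))
    Y = X[:, :1] @ np.array([[1.0]]) + rng.normal(scale=0.05, size=(50, 1))
    # make the decoy columns exactly orthogonal to the response and driver
    basis = np.hstack([np.ones((50, 1)), X[:, :1], Y])
    proj = basis @ np.linalg.lstsq(basis, X[:, 1:], rcond=None)[0]
    X[:, 1:] -= proj
    fit = fit_penalized(X, Y, 0.01)
    p = coefficient_pvalues(fit)
    assert p.iloc[0] < 0.01
    assert p.iloc[1] > 0.5 and p.iloc[2] > 0.5
    assert ((p >= 0) & (p <= 1)).all()


def test_planted_driver_significant_across_reps():
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        X = rng.normal(size=(50, 4))
        Y = X[:, :1] * 0.8 + rng.normal(scale=0.05, size=(50, 1))
        p = coefficient_pvalues(fit_penalized(X, Y, 0.01))
        hits += p.iloc[0] < 0.01
    assert hits >= 95


def test_backward_elimination_recovers_true_support():
    """Y built from columns {0, 1} plus 3 decoys: the true pair is selected
    in at least 90 of 100 seeded replicates."""
    exact = 0
    for rep in range(100):
        rng = np.random.default_rng(2000 + rep)
        X = rng.normal(size=(60, 5))
        W = rng.uniform(0.5, 1.0, size=(2, 2))
        Y = X[:, :2] @ W + rng.normal(scale=0.05, size=(60, 2))
        fit = iterative_select(X, Y, lam=1e-3)
        exact += fit.selected == ["x0", "x1"]
        assert fit.n_iterations <= 5
    assert exact >= 90


def test_null_response_fails_the_gate():
    fails = 0
    for rep in range(100):
        rng = np.random.default_rng(3000 + rep)
        X = rng.normal(size=(60, 5))
        Y = rng.normal(size=(60, 2))
        fit = iterative_select(X, Y, lam=1e-3)
        fails += (not fit.selected) or fit.r2 < 2 / 3
    assert fails >= 95


def test_elimination_converges_with_empty_selection(rng, caplog):
    X = rng.normal(size=(30, 4))
    Y = rng.normal(size=(30, 1))
    fit = iterative_select(X, Y, lam=1e-3, alpha_drop=1e-9)
    assert fit.selected == []
    assert fit.r2 == 0.0 and fit.converged


# ---------------------------------------------------------------------------
# minimality
# ---------------------------------------------------------------------------

def test_singleton_selection_is_minimal(rng):
    X = rng.normal(size=(30, 1))
    Y = X * 2 + rng.normal(scale=0.05, size=(30, 1))
    fit = fit_penalized(X, Y, 1e-3)
    minimal, cert = check_minimality(fit, mode="exhaustive")
    assert minimal and cert["passing_subset"] is None


def test_duplicated_column_breaks_minimality(rng):
    x = rng.normal(size=(40, 1))
    X = np.hstack([x, x + rng.normal(scale=1e-6, size=(40, 1))])
    Y = x * 1.5 + rng.normal(scale=0.05, size=(40, 1))
    fit = fit_penalized(X, Y, 1e-3)
    assert fit.r2 > 2 / 3
    minimal, cert = check_minimality(fit, mode="exhaustive")
    assert not minimal
    assert cert["passing_subset"] in (["x0"], ["x1"])


def test_exhaustive_limit_directs_to_greedy(rng):
    X = rng.normal(size=(40, 13))
    Y = X @ rng.normal(size=(13, 1))
    fit = fit_penalized(X, Y, 1e-3)
    with pytest.raises(ValueError, match="greedy"):
        check_minimality(fit, mode="exhaustive")


def test_greedy_agrees_with_exhaustive_oracle():
    """Random 8-candidate instances: the greedy verdict matches exhaustive
    subset enumeration in at least 95 of 100 replicates."""
    agree = 0
    for rep in range(100):
        rng = np.random.default_rng(4000 + rep)
        X = rng.normal(size=(40, 8))
        support = rng.integers(2, 9)
        W = np.zeros((8, 1))
        W[:support, 0] = rng.uniform(0.3, 1.0, size=support)
        Y = X @ W + rng.normal(scale=rng.uniform(0.05, 0.8), size=(40, 1))
        fit = fit_penalized(X, Y, 1e-3)
        if fit.r2 < 2 / 3:
            continue
        g, _ = check_minimality(fit, mode="greedy")
        e, _ = check_minimality(fit, mode="exhaustive")
        agree += g == e
    assert agree >= 95


# ---------------------------------------------------------------------------
# permutation p-value
# ---------------------------------------------------------------------------

def test_perfect_fit_gets_smallest_possible_p(rng):
    X = rng.normal(size=(20, 3))
    p = permutation_pvalue(X, X.copy(), lam=0.0, n_perm=200, seed=1)
    assert p == pytest.approx(1 / 201)


def test_permutation_p_deterministic_in_seed(rng):
    X = rng.normal(size=(15, 2))
    Y = X @ rng.normal(size=(2, 1)) + rng.normal(scale=2.0, size=(15, 1))
    p1 = permutation_pvalue(X, Y, lam=0.1, n_perm=150, seed=42)
    p2 = permutation_pvalue(X, Y, lam=0.1, n_perm=150, seed=42)
    assert p1 == p2


def test_permutation_guards():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_pvalue(rng.normal(size=(10, 2)),
                           rng.normal(size=(10, 1)), 0.1, n_perm=10)
    with pytest.raises(ValueError, match="samples"):
        permutation_pvalue(rng.normal(size=(3, 2)),
                           rng.normal(size=(3, 1)), 0.1, n_perm=100)


# ---------------------------------------------------------------------------
# explainability call
# ---------------------------------------------------------------------------

def test_explainable_when_signal_strong_and_minimal():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 4))
    Y = X[:, :1] * 1.2 + rng.normal(scale=0.05, size=(60, 2))
    call = explainability_call(X, Y, n_perm=200, seed=3)
    assert call.explainable
    assert call.fit.selected == ["x0"]
    assert call.r2 >= 2 / 3 and call.perm_p < 0.05 and call.minimal


def test_not_explainable_under_null():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(40, 4))
    Y = rng.normal(size=(40, 2))
    call = explainability_call(X, Y, n_perm=200, seed=3)
    assert not call.explainable


# ---------------------------------------------------------------------------
# ΔR² attribution
# ---------------------------------------------------------------------------

def test_null_block_not_contributing():
    calls = []
    for rep in range(40):
        rng = np.random.default_rng(5000 + rep)
        X = rng.normal(size=(60, 6))
        Y = X[:, :3] @ rng.normal(size=(3, 1)) + rng.normal(scale=0.1,
                                                            size=(60, 1))
        blocks = {"signal": ["x0", "x1", "x2"], "null": ["x3", "x4", "x5"]}
        call = contribution_delta(Y, pd.DataFrame(X, columns=blocks["signal"]
                                                  + blocks["null"]),
                                  blocks, "null", lam=1e-3, n_perm=99,
                                  seed=rep)
        calls.append(call)
    assert sum(c.contributing for c in calls) <= 2
    assert all(abs(c.delta_r2) < 0.1 for c in calls)


def test_planted_block_contributes():
    hits = 0
    for rep in range(40):
        rng = np.random.default_rng(6000 + rep)
        X = rng.normal(size=(60, 6))
        w = np.zeros((6, 1))
        w[:3] = rng.uniform(0.4, 0.8, size=(3, 1))
        w[3:] = rng.uniform(0.4, 0.8, size=(3, 1))
        Y = X @ w + rng.normal(scale=0.1, size=(60, 1))
        blocks = {"focal": ["x0", "x1", "x2"], "rest": ["x3", "x4", "x5"]}
        call = contribution_delta(Y, pd.DataFrame(X, columns=blocks["focal"]
                                                  + blocks["rest"]),
                                  blocks, "focal", lam=1e-3, n_perm=199,
                                  seed=rep)
        hits += call.contributing
    assert hits >= 36


def test_orthogonal_blocks_deltas_are_additive():
    """With orthogonal centered predictors at lambda=0, block ΔR² values sum
    exactly to the full-model R^2."""
    rng = np.random.default_rng(12)
    raw = rng.normal(size=(30, 6))
    Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    X = pd.DataFrame(Q, columns=[f"x{i}" for i in range(6)])
    Y = Q @ rng.normal(size=(6, 2)) + rng.normal(scale=0.2, size=(30, 2))
    blocks = {"a": ["x0", "x1"], "b": ["x2", "x3"], "c": ["x4", "x5"]}
    deltas = [contribution_delta(Y, X, blocks, name, lam=0.0, n_perm=99,
                                 seed=0).delta_r2 for name in blocks]
    r2_full = fit_penalized(X, Y, 0.0).r2
    assert sum(deltas) == pytest.approx(r2_full - 0.0, abs=1e-10)


def test_block_partition_enforced(rng):
    X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["x0", "x1", "x2"])
    Y = rng.normal(size=(20, 1))
    with pytest.raises(ValueError, match="partition"):
        contribution_delta(Y, X, {"a": ["x0"]}, "a", lam=0.1)
    with pytest.raises(ValueError, match="unknown block"):
        contribution_delta(Y, X, {"a": ["x0", "x1", "x2"]}, "b", lam=0.1)


# ---------------------------------------------------------------------------
# class fractions
# ---------------------------------------------------------------------------

def test_class_fraction_arithmetic():
    fractions = class_fractions({
        "T1N0": ["cell adhesion", "hemopoiesis", "cytokine and chemokine "
                 "production", "organelle assembly"],
        "T2N0": ["endocytosis", "cell adhesion"],
    }, stage_order=("T1N0", "T2N0"))
    np.testing.assert_allclose(
        fractions.loc["T1N0"], [0.75, 0.25])
    # 'endocytosis' is in neither class: denominators keep it
    np.testing.assert_allclose(fractions.loc["T2N0"], [0.5, 0.0])
    total = fractions.sum(axis=1)
    assert (total <= 1 + 1e-12).all()


def test_class_fractions_missing_stage_warns(caplog):
    with caplog.at_level("WARNING"):
        fractions = class_fractions({}, stage_order=("T1N0",))
    assert fractions.isna().all().all()
    assert "fractions undefined" in caplog.text


def test_class_fractions_alternating_pattern():
    """A planted alternation between the two super-classes across six stages
    shows up directly in the fractions."""
    env = ["cell adhesion", "hemopoiesis"]
    dmg = ["organelle assembly", "cell skeleton synthesis"]
    stage_cats = {s: (env if i % 2 == 0 else dmg)
                  for i, s in enumerate(("T1N0", "T2N0", "T3N0", "N1", "N2",
                                         "N3"))}
    fr = class_fractions(stage_cats)
    np.testing.assert_allclose(fr["fraction_cell_environment"],
                               [1, 0, 1, 0, 1, 0])
    np.testing.assert_allclose(fr["fraction_intracellular_damage"],
                               [0, 1, 0, 1, 0, 1])
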