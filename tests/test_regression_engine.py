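"""OLS fitting, nested LRT, J-test and star verdicts."""

import numpy as np
import pytest
from scipy import stats

from cisreg.regression_engine import (
    CollinearityError,
    fit_ols,
    jtest,
    lrt_f_change,
    lrt_nested,
    stars,
)

from tests.conftest import genotypes_from_dosages, random_genotypes


def normal_equation_oracle(y, X):
    """Brute-force OLS via explicit normal equations (test oracle only)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss
    n, p = X.shape
    adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    return beta, rss, adj


# ---------------------------------------------------------------------------
# fit_ols
# ---------------------------------------------------------------------------

def test_perfect_fit():
    g = genotypes_from_dosages([[0], [1], [2], [1], [0], [2]])
    y = g.dosage("v1")
    fit = fit_ols(y, g, ["v1"])
    assert fit.r2 == pytest.approx(1.0)
    assert fit.adj_r2 == pytest.approx(1.0)
    assert fit.coefficients[0] == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)


def test_orthogonal_predictor_null_fit():
    g = genotypes_from_dosages([[0], [1], [2], [1], [0], [2], [1], [1]])
    d = g.dosage("v1")
    rng = np.random.default_rng(3)
    y = rng.normal(size=8)
    # project out intercept and dosage so the sample correlation is exactly 0
    X = np.column_stack([np.ones(8), d])
    y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    y = y + 5.0  # restore a nonzero mean; orthogonality to d is preserved
    fit = fit_ols(y, g, ["v1"])
    assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-10)
    assert fit.term_pvalues[0] == pytest.approx(1.0, abs=1e-8)


def test_six_point_normal_equations():
    d = np.array(
        [[0, 1], [1, 0], [2, 2], [1, 1], [0, 2], [2, 0]], dtype=float
    )
    g = genotypes_from_dosages(d)
    y = np.array([0.3, 1.1, 3.9, 1.8, 1.9, 2.2])
    fit = fit_ols(y, g, ["v1", "v2"])
    beta, rss, adj = normal_equation_oracle(y, d)
    assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
    np.testing.assert_allclose(fit.coefficients, beta[1:], atol=1e-10)
    assert fit.rss == pytest.approx(rss, abs=1e-10)
    assert fit.adj_r2 == pytest.approx(adj, abs=1e-10)


def test_fit_matches_oracle_on_random_instances():
    """100 random small designs agree with the normal-equation oracle."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = int(rng.integers(10, 51))
        p = int(rng.integers(1, 6))
        g = random_genotypes(rng, n, p)
        y = rng.normal(size=n) + g.dosages @ rng.normal(0, 0.5, p)
        fit = fit_ols(y, g, g.variant_ids)
        beta, rss, adj = normal_equation_oracle(y, g.dosages)
        np.testing.assert_allclose(
            np.concatenate(([fit.intercept], fit.coefficients)), beta, atol=1e-8
        )
        assert fit.rss == pytest.approx(rss, abs=1e-8)
        assert fit.adj_r2 == pytest.approx(adj, abs=1e-8)
        # adjusted r2 is strictly below r2 for p >= 1, r2 < 1
        if fit.r2 < 1:
            assert fit.adj_r2 < fit.r2
        # residuals orthogonal to the design
        X = np.column_stack([np.ones(n), g.dosages])
        assert np.abs(X.T @ fit.residuals).max() < 1e-8


def test_collinearity_and_size_guards(rng):
    d = rng.binomial(2, 0.4, size=(20, 1)).astype(float)
    g = genotypes_from_dosages(np.column_stack([d, d]))
    with pytest.raises(CollinearityError, match="v2"):
        fit_ols(rng.normal(size=20), g, ["v1", "v2"])
    g1 = genotypes_from_dosages([[0.0], [1.0]])
    with pytest.raises(ValueError, match="insufficient"):
        fit_ols(np.array([1.0, 2.0]), g1, ["v1"])


def test_loglik_consistent_with_rss(rng):
    g = random_genotypes(rng, 40, 2)
    y = rng.normal(size=40)
    fit = fit_ols(y, g, g.variant_ids)
    n = fit.n
    expected = -0.5 * n * (np.log(2 * np.pi * fit.rss / n) + 1)
    assert fit.loglik == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# nested LRT
# ---------------------------------------------------------------------------

def test_lrt_self_is_null(rng):
    g = random_genotypes(rng, 30, 2)
    y = rng.normal(size=30)
    fit = fit_ols(y, g, g.variant_ids)
    res = lrt_nested(fit, fit)
    assert res.statistic == 0.0 and res.p_value == 1.0 and res.verdict == "n.s."


def test_lrt_monotone_in_true_effects(rng):
    """Stronger added true effects push the LRT statistic up (RSS down)."""
    n = 300
    g = random_genotypes(rng, n, 2)
    noise = rng.normal(size=n)
    small_stats = []
    for beta in (0.0, 0.3, 0.6, 1.0):
        y = 0.8 * g.dosage("v1") + beta * g.dosage("v2") + noise
        small = fit_ols(y, g, ["v1"])
        large = fit_ols(y, g, ["v1", "v2"])
        small_stats.append(lrt_nested(small, large).statistic)
    assert all(b >= a for a, b in zip(small_stats, small_stats[1:]))


def test_lrt_guards(rng):
    g = random_genotypes(rng, 30, 3)
    y = rng.normal(size=30)
    fit_a = fit_ols(y, g, ["v1", "v2"])
    fit_b = fit_ols(y, g, ["v3"])
    with pytest.raises(ValueError, match="not nested"):
        lrt_nested(fit_a, fit_b)


def test_lrt_equals_squared_t_and_f_change(rng):
    """For one added column: LRT ~ t^2 and chi2/F calibrations agree, n=300."""
    n = 300
    g = random_genotypes(rng, n, 2)
    y = 0.5 * g.dosage("v1") + 0.2 * g.dosage("v2") + rng.normal(size=n)
    small = fit_ols(y, g, ["v1"])
    large = fit_ols(y, g, ["v1", "v2"])
    res = lrt_nested(small, large)
    t2 = float(large.t_values[-1] ** 2)
    assert res.statistic == pytest.approx(t2, rel=0.05)
    res_f = lrt_f_change(small, large)
    assert res_f.p_value == pytest.approx(res.p_value, abs=0.01)


# ---------------------------------------------------------------------------
# J-test
# ---------------------------------------------------------------------------

def test_jtest_guards(rng):
    g = random_genotypes(rng, 50, 3)
    y = rng.normal(size=50)
    with pytest.raises(ValueError, match="nested"):
        jtest(y, g, ["v1"], ["v1", "v2"])


def test_jtest_degenerate_shared_span(rng):
    """Models spanning the same design trigger the degeneracy guard."""
    d = rng.binomial(2, 0.4, size=(60, 1)).astype(float)
    g = genotypes_from_dosages(np.column_stack([d, 2 - d, rng.binomial(2, 0.3, 60)]))
    y = rng.normal(size=60)
    # v2 = 2 - v1: the two "different" models have identical fitted values
    with pytest.raises(CollinearityError, match="degenerate"):
        jtest(y, g, ["v1", "v3"], ["v2", "v3"])


def test_jtest_returns_both_directions(rng):
    n = 200
    g = random_genotypes(rng, n, 2)
    y = 0.9 * g.dosage("v1") + rng.normal(size=n)
    res_a, res_b = jtest(y, g, ["v1"], ["v2"], name_a="A", name_b="B")
    assert res_a.direction == "A" and res_b.direction == "B"
    # truth is model A: B's adequacy is rejected, A's is not
    assert res_b.p_value < 0.01
    assert res_a.p_value > 0.01


# ---------------------------------------------------------------------------
# stars
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p,label",
    [
        (0.2, "n.s."), (0.05, "n.s."), (0.049, "*"), (0.01, "*"),
        (0.004, "**"), (0.001, "**"), (0.0009, "***"), (0.0001, "***"),
        (5e-5, "****"), (0.0, "****"), (1.0, "n.s."),
    ],
)
def test_star_thresholds(p, label):
    assert stars(p) == label


def test_star_domain():
    with pytest.raises(ValueError):
        stars(1.5)
    with pytest.raises(ValueError):
        stars(-0.1)
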