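"""Pinball-loss quantile fitting: oracles, equivariance, inference, fit measures."""

from itertools import combinations

import numpy as np
import pytest

from divclim import (
    bootstrap_inference,
    fit_polynomial_quantile,
    fit_quantile,
    fit_wed_quantile,
    generate_known_quantile_dataset,
    pinball_loss,
    pseudo_r2,
)


def combinatorial_oracle(X, y, tau):
    """Best pinball loss over all interpolating basic solutions."""
    n, p = X.shape
    best = np.inf
    for idx in combinations(range(n), p):
        sub = X[list(idx)]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        beta = np.linalg.solve(sub, y[list(idx)])
        best = min(best, pinball_loss(y - X @ beta, tau))
    return best


@pytest.mark.parametrize(
    "residuals, tau, expected",
    [((0, 0, 0), 0.3, 0.0), ((1, -1), 0.5, 1.0), ((2, -1), 0.9, 1.9)],
)
def test_pinball_examples(residuals, tau, expected):
    assert pinball_loss(residuals, tau) == pytest.approx(expected)


def test_pinball_zero_iff_zero():
    assert pinball_loss([0.0, 1e-12], 0.5) > 0
    with pytest.raises(ValueError):
        pinball_loss([1.0], 1.5)


def test_zero_noise_interpolation():
    x = np.linspace(0, 10, 40)
    for tau in (0.1, 0.5, 0.9):
        fit = fit_polynomial_quantile(x, 2 * x + 1, 1, tau)
        np.testing.assert_allclose(fit.coefficients, [2.0, 1.0], atol=1e-8)
    fit = fit_polynomial_quantile(x, x**2, 2, 0.5)
    np.testing.assert_allclose(fit.coefficients, [1.0, 0.0, 0.0], atol=1e-7)


def test_intercept_only_is_sample_quantile():
    y = np.array([1.0, 2, 3, 4, 100])
    assert fit_quantile(np.ones((5, 1)), y, 0.5)[0] == pytest.approx(3.0)
    y = np.arange(1.0, 11)
    beta = fit_quantile(np.ones((10, 1)), y, 0.1)[0]
    grid = np.linspace(0, 11, 2201)
    losses = [pinball_loss(y - g, 0.1) for g in grid]
    assert pinball_loss(y - beta, 0.1) <= min(losses) + 1e-9
    assert beta in y  # an order statistic


def test_line_fit_matches_combinatorial_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(4, 9))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        X = np.column_stack([x, np.ones(n)])
        beta = fit_quantile(X, y, 0.5)
        assert pinball_loss(y - X @ beta, 0.5) <= combinatorial_oracle(X, y, 0.5) + 1e-9


def test_rank_deficient_design_errors():
    X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_quantile(X, np.arange(6.0), 0.5)


def test_coverage_condition_on_random_instances(rng):
    """At the optimum: fraction(residual<0) <= tau <= fraction(residual<=0)."""
    for _ in range(20):
        n = int(rng.integers(30, 80))
        x = rng.uniform(0, 5, n)
        y = np.sin(x) + rng.normal(0, 0.5, n)
        tau = float(rng.uniform(0.05, 0.95))
        deg = int(rng.integers(1, 4))
        fit = fit_polynomial_quantile(x, y, deg, tau)
        r = fit.residuals
        assert (r < -1e-9).mean() <= tau + 1e-9
        assert tau <= (r <= 1e-9).mean() + 1e-9


def test_equivariance(rng):
    x = rng.uniform(0, 3, 60)
    y = 1 + x + 0.5 * x**2 + rng.normal(0, 0.3, 60)
    base = fit_polynomial_quantile(x, y, 2, 0.5).coefficients
    scaled = fit_polynomial_quantile(x, 7.0 * y, 2, 0.5).coefficients
    np.testing.assert_allclose(scaled, 7.0 * base, atol=1e-8)
    shifted = fit_polynomial_quantile(x + 2.0, y, 2, 0.5).coefficients
    # re-expand base polynomial around the shift: p(x) = q(x + 2) with q fitted
    from numpy.polynomial import Polynomial

    q = Polynomial(shifted[::-1])
    p = q(Polynomial([2.0, 1.0]))
    np.testing.assert_allclose(p.coef[::-1], base, atol=1e-7)


def test_agrees_with_statsmodels(rng):
    import statsmodels.api as sm

    x = rng.uniform(0, 10, 300)
    y = 1 + 0.5 * x + rng.normal(0, 1, 300) * (1 + 0.1 * x)
    X = np.column_stack([x, np.ones_like(x)])
    for tau in (0.1, 0.5, 0.9):
        ours = fit_polynomial_quantile(x, y, 1, tau).coefficients
        p = sm.QuantReg(y, sm.add_constant(x)).fit(q=tau).params
        theirs = np.array([p[1], p[0]])
        # the LP solution is exact; IRLS may stop short of the optimum
        assert pinball_loss(y - X @ ours, tau) <= pinball_loss(y - X @ theirs, tau) + 1e-9
        np.testing.assert_allclose(ours, theirs, atol=0.05)


def test_bootstrap_determinism_and_zero_noise():
    x = np.linspace(0, 10, 60)
    y = 2 * x + 1
    fit = fit_polynomial_quantile(x, y, 1, 0.5)
    se1, p1 = bootstrap_inference(fit, B=100, seed=5)
    se2, p2 = bootstrap_inference(fit, B=100, seed=5)
    np.testing.assert_array_equal(se1, se2)
    np.testing.assert_array_equal(p1, p2)
    assert np.all(se1 < 1e-8)
    assert p1[0] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        bootstrap_inference(fit, B=50)


def test_bootstrap_interval_coverage():
    """~95% normal-approximation intervals cover the true slope.

    60 repeats at n=120 with B=100; the binomial tolerance for 60
    repeats of a nominal 0.95 event is wide (about +-0.09 at 3 sd).
    """
    rng = np.random.default_rng(99)
    hits = 0
    reps = 60
    for _ in range(reps):
        x = rng.uniform(0, 10, 120)
        y = 1.0 + 2.0 * x + rng.normal(0, 1, 120)
        fit = fit_polynomial_quantile(x, y, 1, 0.5)
        se, _ = bootstrap_inference(fit, B=100, seed=int(rng.integers(2**31)))
        lo, hi = fit.coefficients[0] - 1.96 * se[0], fit.coefficients[0] + 1.96 * se[0]
        hits += lo <= 2.0 <= hi
    assert 0.85 <= hits / reps <= 1.0


def test_pseudo_r2_examples():
    x = np.linspace(0, 10, 30)
    perfect = fit_polynomial_quantile(x, 3 * x + 2, 1, 0.5)
    assert pseudo_r2(perfect, "km") == pytest.approx(1.0)
    assert pseudo_r2(perfect, "rho") == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    y = rng.normal(size=40)
    from divclim.quantreg import QuantileFit

    null_fit = QuantileFit(
        response="y", covariates=(), tau=0.5, degree="linear",
        coefficients=np.array([0.0, float(np.quantile(y, 0.5, method="inverted_cdf"))]),
        n=40, covariate_range={}, _x=np.zeros((40, 1)), _y=y,
    )
    assert pseudo_r2(null_fit, "km") == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="constant"):
        pseudo_r2(null_fit, "rho")


def test_pseudo_r2_rho_matches_hand_computation():
    # frozen n=10 fixture; oracle computed with plain-python arithmetic
    x = np.array([0.5, 1.1, 1.9, 2.4, 3.3, 4.1, 4.8, 5.5, 6.2, 7.0])
    y = np.array([1.2, 2.9, 2.1, 4.8, 4.1, 6.3, 5.2, 7.9, 7.1, 9.4])
    tau = 0.5
    fit = fit_polynomial_quantile(x, y, 1, tau)
    yhat = [float(v) for v in fit.predict(x)]
    rho = [(yi - yh) * (tau - (1 if yi - yh < 0 else 0)) for yi, yh in zip(y, yhat)]
    u = yhat
    v = [yh + r for yh, r in zip(yhat, rho)]
    mu_u, mu_v = sum(u) / 10, sum(v) / 10
    cov = sum((a - mu_u) * (b - mu_v) for a, b in zip(u, v))
    var_u = sum((a - mu_u) ** 2 for a in u)
    var_v = sum((b - mu_v) ** 2 for b in v)
    oracle = (cov / (var_u * var_v) ** 0.5) ** 2
    assert pseudo_r2(fit, "rho") == pytest.approx(oracle, rel=1e-12)


def test_known_truth_recovery_moderate_n():
    ds = generate_known_quantile_dataset(
        [2.0, -1.0, 0.5, 3.0], [1.0], taus=(0.5,), n=2000, seed=4, x_range=(-2, 2)
    )
    fit = fit_polynomial_quantile(ds.x, ds.y, 3, 0.5)
    se, _ = bootstrap_inference(fit, B=100, seed=8)
    assert np.all(np.abs(fit.coefficients - ds.truth(0.5)) <= 3 * se)


def test_wed_fit_layout(small_climate, rng):
    n = len(small_climate)
    y = (
        0.003 * small_climate["MAP"].to_numpy()
        - 0.3 * small_climate["MMAX"].to_numpy()
        + 12
        + rng.normal(0, 0.5, n)
    )
    fit = fit_wed_quantile(small_climate["MAP"], small_climate["MMAX"], y, 0.5, response="v0")
    assert fit.covariates == ("MAP", "MMAX")
    assert fit.coefficients[0] == pytest.approx(0.003, abs=5e-4)
    assert fit.coefficients[1] == pytest.approx(-0.3, abs=0.1)
    assert 0 <= fit.pseudo_r2_km <= 1 and 0 <= fit.pseudo_r2_rho <= 1


def test_monotone_quantile_curves_do_not_cross():
    ds = generate_known_quantile_dataset(
        [1.0, 0.0, 2.0], [0.2, 0.1], taus=(0.1, 0.5, 0.9), n=2500, seed=12, x_range=(0, 2)
    )
    fits = {tau: fit_polynomial_quantile(ds.x, ds.y, 2, tau) for tau in (0.1, 0.5, 0.9)}
    grid = np.linspace(0.05, 1.95, 100)
    lo, mid, hi = (fits[t].predict(grid) for t in (0.1, 0.5, 0.9))
    assert np.all(lo <= mid + 1e-6) and np.all(mid <= hi + 1e-6)
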