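"""Spearman screening, sphericity, PCA + varimax, predictor selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divclim import bartlett_sphericity, kmo, pca_varimax, select_predictors, spearman
from divclim.screening import correlation_table


def _midrank(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def test_spearman_perfect_monotone():
    assert spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)


def test_spearman_equals_pearson_of_midranks():
    x, y = [1, 2, 2, 4], [3, 1, 1, 2]
    oracle = np.corrcoef(_midrank(x), _midrank(y))[0, 1]
    assert spearman(x, y)[0] == pytest.approx(oracle, rel=1e-12)


def test_spearman_p_is_t_approximation(rng):
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    r, p = spearman(x, y)
    t = r * np.sqrt(28 / (1 - r**2))
    assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-6)


def test_spearman_monotone_transform_invariance(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    r, _ = spearman(x, y)
    assert spearman(np.exp(x), y)[0] == pytest.approx(r, rel=1e-12)
    assert spearman(x, y**3)[0] == pytest.approx(r, rel=1e-12)


def test_spearman_constant_vector_errors():
    with pytest.raises(ValueError, match="constant"):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


def test_bartlett_identity_and_closed_form(rng):
    X = rng.normal(size=(2000, 4))
    chi2, p = bartlett_sphericity(X)
    assert p > 0.05  # independent normals: no correlation structure
    Y = rng.normal(size=(100, 3))
    chi2, _ = bartlett_sphericity(Y)
    R = np.corrcoef(Y, rowvar=False)
    oracle = -(100 - 1 - (2 * 3 + 5) / 6) * np.log(np.linalg.det(R))
    assert chi2 == pytest.approx(oracle, rel=1e-10)


def test_bartlett_collinear_errors(rng):
    x = rng.normal(size=50)
    X = np.column_stack([x, 2 * x, rng.normal(size=50)])
    with pytest.raises(ValueError, match="singular|collinear"):
        bartlett_sphericity(X)


def test_kmo_range(rng):
    base = rng.normal(size=(500, 2))
    X = np.hstack([base + 0.1 * rng.normal(size=(500, 2)) for _ in range(3)])
    assert 0.4 < kmo(X) <= 1.0
    assert kmo(rng.normal(size=(500, 6))) < 0.7


def _two_block_data(rng, n=500, noise=0.1):
    t = rng.normal(size=n)
    w = rng.normal(size=n)
    cols = {f"t{i}": t * s + noise * rng.normal(size=n) for i, s in enumerate([1, -1, 0.9, 1.2])}
    cols |= {f"w{i}": w * s + noise * rng.normal(size=n) for i, s in enumerate([1, 1.1, -0.8])}
    return pd.DataFrame(cols)


def test_pca_varimax_recovers_blocks(rng):
    data = _two_block_data(rng)
    fm = pca_varimax(data, 2)
    t_factors = {fm.assignment[c] for c in data.columns if c.startswith("t")}
    w_factors = {fm.assignment[c] for c in data.columns if c.startswith("w")}
    assert len(t_factors) == 1 and len(w_factors) == 1 and t_factors != w_factors
    assert fm.variance_explained[0] >= fm.variance_explained[1]
    assert np.all(fm.variance_explained > 0) and fm.variance_explained.sum() <= 1 + 1e-9


def test_varimax_preserves_communalities_and_is_idempotent(rng):
    from statsmodels.multivariate.factor_rotation import rotate_factors

    data = _two_block_data(rng)
    fm = pca_varimax(data, 2)
    X = np.asarray(data, float)
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    idx = np.argsort(eigval)[::-1][:2]
    unrotated = eigvec[:, idx] * np.sqrt(eigval[idx])
    # communalities preserved by the orthogonal rotation
    np.testing.assert_allclose(
        (fm.loadings.to_numpy() ** 2).sum(axis=1),
        (unrotated**2).sum(axis=1),
        atol=1e-8,
    )
    # re-rotating an already optimal solution changes nothing (up to sign/perm)
    again, _ = rotate_factors(fm.loadings.to_numpy(), "varimax")
    best = min(
        np.abs(np.abs(again[:, list(perm)]) - np.abs(fm.loadings.to_numpy())).max()
        for perm in itertools.permutations(range(2))
    )
    assert best < 1e-6


def _mock_diversity_correlations():
    rows = []
    strong = {"MAT": -0.317, "MTWM": -0.338, "MMAX": -0.358, "DD5": -0.318,
              "GSDD5": -0.302, "AAI": -0.412, "NIP": 0.472}
    weak = {"ELEV": 0.272, "MAP": 0.248, "SDAY": 0.295, "LAT": 0.021}
    for var, r in {**strong, **weak}.items():
        rows.append({"var_a": "v0", "var_b": var, "r_s": r,
                     "p": 1e-6 if abs(r) > 0.3 else 0.5, "significant": abs(r) > 0.3})
    return pd.DataFrame(rows)


class _FakeFactors:
    def __init__(self, factor1):
        self._f1 = list(factor1)

    def factor_members(self, k):
        return self._f1 if k == 0 else []


def test_select_predictors_realized_set():
    corr = _mock_diversity_correlations()
    factors = _FakeFactors(
        ["MAT", "MTCM", "FDAY", "DD5", "FFP", "GSDD5", "SDAY", "MMIN",
         "D100", "MTWM", "MMINDD0", "ELEV", "MMAX", "DD0"]
    )
    chosen = select_predictors(corr, factors)
    assert set(chosen) == {"MAT", "MTWM", "MMAX", "DD5", "GSDD5", "AAI", "NIP"}


def test_select_predictors_degenerate_cases():
    corr = _mock_diversity_correlations()
    corr["r_s"] = 0.1
    factors = _FakeFactors(["MAT", "MMAX"])
    assert select_predictors(corr, factors) == ["AAI", "NIP"]
    corr = _mock_diversity_correlations()
    corr["p"] = 0.0
    chosen = select_predictors(corr, factors, r_threshold=0.0)
    assert set(chosen) >= {"MAT", "MMAX"}


def test_correlation_table_symmetric_flags(small_climate):
    sub = small_climate[["MAT", "MMAX", "MAP"]].iloc[:200]
    table = correlation_table(sub)
    get = lambda a, b: table[(table.var_a == a) & (table.var_b == b)].iloc[0]  # noqa: E731
    assert get("MAT", "MMAX").r_s == pytest.approx(get("MMAX", "MAT").r_s)
    assert get("MAT", "MAT").r_s == 1.0
    assert bool(get("MAT", "MMAX").significant)  # same temperature group
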