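"""Variable screening: rank correlations, sphericity, PCA with varimax.

The screening stage decides which climate variables enter the quantile
models: variables loading on the dominant ("temperature") factor of a
varimax-rotated PCA of the climate table, whose Spearman correlation with
any diversity index exceeds |r_s| > 0.3 at p < 0.01, plus a small set of
unconditional extras (AAI and stand density NIP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorModel",
    "spearman",
    "correlation_table",
    "bartlett_sphericity",
    "kmo",
    "pca_varimax",
    "select_predictors",
]

R_THRESHOLD = 0.3
ALPHA = 0.01


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Midranks are used for ties. Constant input has undefined rank
    correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_table(
    data: pd.DataFrame,
    rows: list[str] | None = None,
    cols: list[str] | None = None,
    r_threshold: float = R_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Tidy Spearman correlation table with significance flags.

    One row per (row variable, column variable) pair with ``r_s``, ``p``
    and ``significant`` (|r_s| > r_threshold and p < alpha). The classic
    display convention marks non-significant entries "ns"; that rendering
    is left to the report writer.
    """
    rows = list(rows or data.columns)
    cols = list(cols or data.columns)
    out = []
    for a in rows:
        for b in cols:
            if a == b:
                r, p = 1.0, 0.0
            else:
                r, p = spearman(data[a], data[b])
            out.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "r_s": r,
                    "p": p,
                    "significant": bool(abs(r) > r_threshold and p < alpha),
                }
            )
    return pd.DataFrame(out)


def bartlett_sphericity(data: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R) on p(p-1)/2 degrees of
    freedom, upper tail. A singular correlation matrix (perfectly
    collinear variables) is rejected with advice to drop a variable.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than variables")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet) or logdet < -50 * p:
        raise ValueError("correlation matrix is singular; remove collinear variables")
    statistic = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    pvalue = float(stats.chi2.sf(statistic, df))
    return float(statistic), pvalue


def kmo(data: pd.DataFrame | np.ndarray) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy (overall).

    Ratio of summed squared correlations to summed squared correlations
    plus squared partial correlations, off-diagonal. Values near 1 mean
    the data are factorable.
    """
    X = np.asarray(data, dtype=float)
    R = np.corrcoef(X, rowvar=False)
    Rinv = np.linalg.pinv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))


@dataclass
class FactorModel:
    """Rotated factor solution of a PCA on the correlation matrix."""

    loadings: pd.DataFrame  # variables x factors
    variance_explained: np.ndarray  # per rotated factor, fraction of total
    variance_explained_unrotated: np.ndarray
    assignment: dict[str, int]  # variable -> factor index (0-based)

    def factor_members(self, k: int) -> list[str]:
        return [v for v, f in self.assignment.items() if f == k]


def pca_varimax(data: pd.DataFrame, n_factors: int = 2) -> FactorModel:
    """PCA of the correlation matrix with varimax-rotated loadings.

    Variables are standardized implicitly by working on the correlation
    matrix (the inputs have wildly different units). The leading
    ``n_factors`` components are rotated by the orthogonal varimax
    criterion; each factor's sign is fixed so its largest-|loading|
    variable loads positively, and factors are ordered by rotated
    variance explained. Each variable is assigned to the factor where its
    absolute loading is largest.
    """
    if n_factors > data.shape[1]:
        raise ValueError("n_factors exceeds number of variables")
    X = np.asarray(data, dtype=float)
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    p = R.shape[0]
    var_unrot = eigval[:n_factors] / p
    load = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    rotated, _ = rotate_factors(load, "varimax")
    ssq = (rotated**2).sum(axis=0)
    order = np.argsort(ssq)[::-1]
    rotated = rotated[:, order]
    ssq = ssq[order]
    for k in range(n_factors):  # sign convention
        imax = np.argmax(np.abs(rotated[:, k]))
        if rotated[imax, k] < 0:
            rotated[:, k] = -rotated[:, k]
    loadings = pd.DataFrame(
        rotated,
        index=list(data.columns),
        columns=[f"factor{k + 1}" for k in range(n_factors)],
    )
    assignment = {
        v: int(np.argmax(np.abs(rotated[i, :]))) for i, v in enumerate(data.columns)
    }
    return FactorModel(
        loadings=loadings,
        variance_explained=ssq / p,
        variance_explained_unrotated=var_unrot,
        assignment=assignment,
    )


def select_predictors(
    corr_with_diversity: pd.DataFrame,
    factors: FactorModel,
    extras: tuple[str, ...] = ("AAI", "NIP"),
    r_threshold: float = R_THRESHOLD,
    alpha: float = ALPHA,
) -> list[str]:
    """Predictor selection rule for the quantile models.

    Takes the tidy correlation table of climate variables (``var_b``)
    against the diversity indices (``var_a``) and keeps every main-factor
    (factor 1) variable with |r_s| > r_threshold and p < alpha against
    *any* diversity index, then appends the ``extras`` unconditionally.
    """
    factor1 = set(factors.factor_members(0))
    keep: list[str] = []
    for var in corr_with_diversity["var_b"].unique():
        if var not in factor1 or var in extras:
            continue
        sub = corr_with_diversity[corr_with_diversity["var_b"] == var]
        hit = ((sub["r_s"].abs() > r_threshold) & (sub["p"] < alpha)).any()
        if hit:
            keep.append(var)
    for e in extras:
        if e not in keep:
            keep.append(e)
    return keep
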