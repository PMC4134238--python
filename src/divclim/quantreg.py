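"""Linear-in-parameters quantile regression by exact linear programming.

A conditional quantile Q_tau(y|x) is estimated by minimizing the pinball
(check) loss

    rho_tau(r) = r * (tau - 1[r < 0]),     0 < tau < 1,

over coefficients of a design matrix. Polynomial "nonlinear" models
(degree 1-4 in one covariate) are linear in their parameters, so they are
fitted as basis-expanded linear quantile regressions and solved exactly
as a linear program — at a nondegenerate optimum the fitted hyperplane
interpolates at least as many observations as it has parameters.
Inference is by xy-pair bootstrap; two pseudo-R^2 variants are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy import sparse, stats
from scipy.optimize import linprog

__all__ = [
    "QuantileFit",
    "pinball_loss",
    "fit_quantile",
    "fit_polynomial_quantile",
    "fit_wed_quantile",
    "bootstrap_inference",
    "pseudo_r2",
]

#: Default bootstrap seed: reproducible inference unless the caller reseeds.
DEFAULT_BOOTSTRAP_SEED = 20140815


def pinball_loss(residuals, tau: float) -> float:
    """Total check loss sum_i r_i * (tau - 1[r_i < 0]); zero iff all zero."""
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


def _check_rank(X: np.ndarray) -> None:
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dependent = sorted(piv[rank:].tolist())
        raise ValueError(f"design is rank-deficient; dependent column(s): {dependent}")


def _fit_quantile_primal(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Split-residual primal LP: min tau*1'u + (1-tau)*1'v, y = X beta + u - v."""
    n, p = X.shape
    cost = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1 - tau)])
    eye = sparse.eye(n, format="csc")
    A_eq = sparse.hstack([sparse.csc_matrix(X), eye, -eye], format="csc")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(cost, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS solves feasible LPs
        raise RuntimeError(f"LP solver failed: {res.message}")
    return res.x[:p]


def fit_quantile(X, y, tau: float) -> np.ndarray:
    """Exact LP solution of the tau-quantile regression on design ``X``.

    Minimizes ``sum_i rho_tau(y_i - x_i' beta)``. The small dual LP
    (``max y'a`` subject to ``X'a = (1-tau) X'1``, ``0 <= a <= 1``) is
    solved first and the primal coefficients recovered from the
    interpolated observations; the solution is accepted only if it
    passes the complementary-slackness optimality check, otherwise the
    full primal LP is solved. Deterministic given the row order; ties
    among optimal vertices are resolved by the solver's vertex choice.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and y length n")
    _check_rank(X)
    n, p = X.shape
    res = linprog(
        -y, A_eq=X.T, b_eq=(1 - tau) * X.sum(axis=0), bounds=[(0, 1)] * n, method="highs"
    )
    if res.success:
        a = res.x
        eps = 1e-7
        interior = np.flatnonzero((a > eps) & (a < 1 - eps))
        if interior.size >= 1:
            beta = np.linalg.lstsq(X[interior], y[interior], rcond=None)[0]
            r = y - X @ beta
            tol = 1e-7 * max(1.0, float(np.max(np.abs(y))))
            ok = (
                np.all(r[a >= 1 - eps] >= -tol)
                and np.all(r[a <= eps] <= tol)
                and np.all(np.abs(r[interior]) <= tol)
            )
            if ok:
                return beta
    return _fit_quantile_primal(X, y, tau)


@dataclass
class QuantileFit:
    """One fitted quantile model on the raw covariate scale.

    ``coefficients`` are ordered highest-degree first for polynomial
    models (a..e with ``a`` the x^4 term) and (a: MAP slope, b: MMAX
    slope, c: intercept) for the bivariate water-energy model.
    """

    response: str
    covariates: tuple[str, ...]
    tau: float
    degree: int | str
    coefficients: np.ndarray
    n: int
    covariate_range: dict[str, tuple[float, float]]
    pseudo_r2_km: float = np.nan
    pseudo_r2_rho: float = np.nan
    std_errors: np.ndarray | None = None
    p_values: np.ndarray | None = None
    _x: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)

    def predict(self, x) -> np.ndarray:
        """Evaluate the fitted quantile curve/plane at raw covariates."""
        x = np.asarray(x, dtype=float)
        if self.degree == "linear":
            if x.ndim == 1:
                x = x.reshape(1, -1)
            return x @ self.coefficients[:-1] + self.coefficients[-1]
        return np.polyval(self.coefficients, x)

    @property
    def fitted(self) -> np.ndarray:
        return self.predict(self._x)

    @property
    def residuals(self) -> np.ndarray:
        return self._y - self.fitted


def _poly_raw_coefficients(beta_z: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Back-transform coefficients fitted on z=(x-mu)/sd to the raw x scale."""
    pz = Polynomial(beta_z[::-1])
    px = pz(Polynomial([-mu / sd, 1.0 / sd]))
    coef = np.zeros(len(beta_z))
    coef[: len(px.coef)] = px.coef
    return coef[::-1]


def _fit_poly_raw(x: np.ndarray, y: np.ndarray, degree: int, tau: float) -> np.ndarray:
    # standardize before expansion: raw quartics of small covariates (AAI^4
    # ~ 1e-5) would otherwise destroy LP conditioning
    mu, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0:
        raise ValueError("covariate is constant")
    z = (x - mu) / sd
    X = np.vander(z, degree + 1)
    beta_z = fit_quantile(X, y, tau)
    return _poly_raw_coefficients(beta_z, mu, sd)


def fit_polynomial_quantile(
    x,
    y,
    degree: int,
    tau: float,
    response: str = "y",
    covariate: str = "x",
) -> QuantileFit:
    """Fit ``Q_tau(y|x)`` as a polynomial of the given degree (1-4).

    The covariate is internally centred and scaled for conditioning;
    reported coefficients are back-transformed to the raw scale,
    highest-degree first.
    """
    if not 1 <= int(degree) <= 4:
        raise ValueError("degree must be 1..4")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < degree + 1:
        raise ValueError("need at least degree+1 distinct covariate values")
    if y.size <= degree + 1:
        raise ValueError("need n > degree + 1")
    coef = _fit_poly_raw(x, y, int(degree), tau)
    fit = QuantileFit(
        response=response,
        covariates=(covariate,),
        tau=tau,
        degree=int(degree),
        coefficients=coef,
        n=int(y.size),
        covariate_range={covariate: (float(x.min()), float(x.max()))},
        _x=x,
        _y=y,
    )
    fit.pseudo_r2_km = pseudo_r2(fit, method="km")
    fit.pseudo_r2_rho = pseudo_r2(fit, method="rho")
    return fit


def fit_wed_quantile(
    map_mm,
    mmax,
    y,
    tau: float,
    response: str = "y",
) -> QuantileFit:
    """Fit the water-energy model ``Q_tau(v|.) = a*MAP + b*MMAX + c``."""
    map_mm = np.asarray(map_mm, dtype=float)
    mmax = np.asarray(mmax, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([map_mm, mmax, np.ones_like(y)])
    coef = fit_quantile(X, y, tau)
    fit = QuantileFit(
        response=response,
        covariates=("MAP", "MMAX"),
        tau=tau,
        degree="linear",
        coefficients=coef,
        n=int(y.size),
        covariate_range={
            "MAP": (float(map_mm.min()), float(map_mm.max())),
            "MMAX": (float(mmax.min()), float(mmax.max())),
        },
        _x=np.column_stack([map_mm, mmax]),
        _y=y,
    )
    fit.pseudo_r2_km = pseudo_r2(fit, method="km")
    fit.pseudo_r2_rho = pseudo_r2(fit, method="rho")
    return fit


def _refit_coefficients(fit: QuantileFit, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if fit.degree == "linear":
        X = np.column_stack([x, np.ones(len(y))])
        return fit_quantile(X, y, fit.tau)
    return _fit_poly_raw(x, y, int(fit.degree), fit.tau)


def bootstrap_inference(
    fit: QuantileFit, B: int = 1000, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """xy-pair bootstrap standard errors and normal-approximation p-values.

    Rows are resampled with replacement and the model refitted ``B``
    times; the SE of each coefficient is its standard deviation across
    replicates, and p-values come from a two-sided normal approximation
    of coef/SE. Replicates with rank-deficient designs are redrawn (at
    most ``10 * B`` attempts). Results are stored on the fit and
    returned; reproducible given the seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(DEFAULT_BOOTSTRAP_SEED if seed is None else seed)
    n = fit.n
    reps = []
    attempts = 0
    while len(reps) < B:
        attempts += 1
        if attempts > 10 * B:
            raise RuntimeError("too many degenerate bootstrap replicates")
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(_refit_coefficients(fit, fit._x[idx], fit._y[idx]))
        except ValueError:
            continue
    reps = np.asarray(reps)
    se = reps.std(axis=0, ddof=1)
    coef = fit.coefficients
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(coef) / se, np.inf)
    p = np.where(se > 0, 2 * stats.norm.sf(z), np.where(coef != 0, 0.0, 1.0))
    fit.std_errors = se
    fit.p_values = p
    return se, p


def pseudo_r2(fit: QuantileFit, method: str = "km") -> float:
    """Goodness of fit of a quantile model.

    ``"km"`` (default): the Koenker–Machado measure
    ``R1(tau) = 1 - V(fit) / V(null)`` where ``V`` is total pinball loss
    and the null model is the unconditional tau-quantile; always in
    [0, 1] for models with an intercept.

    ``"rho"``: the squared correlation between the fitted values and
    (fitted values + per-observation pinball contributions) — an
    unconventional replication variant retained for comparability with
    published tables. Undefined (raises) when the fitted values are
    constant.
    """
    y = fit._y
    yhat = fit.fitted
    r = y - yhat
    if method == "km":
        v_fit = pinball_loss(r, fit.tau)
        q0 = np.quantile(y, fit.tau, method="inverted_cdf")
        v_null = pinball_loss(y - q0, fit.tau)
        if v_null == 0:
            return 1.0
        return float(1.0 - v_fit / v_null)
    if method == "rho":
        rho = r * (fit.tau - (r < 0))
        if np.ptp(yhat) == 0:
            raise ValueError("constant fitted values: correlation undefined")
        if np.ptp(rho + yhat) == 0:  # perfect fit: rho == 0 everywhere
            return 1.0
        c = np.corrcoef(yhat, rho + yhat)[0, 1]
        return float(c**2)
    raise ValueError(f"unknown method {method!r}")
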