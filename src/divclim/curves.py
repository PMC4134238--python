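"""Analysis of fitted quantile curves: extrema and climate-change projection.

Polynomial quantile fits of diversity against a climate covariate are
summarized by their interior critical points (the hollow/hump shape of a
diversity-climate relation is read off the local minima and maxima), and
the bivariate water-energy fits are projected under a climate-change
scenario (a temperature increment and a multiplicative precipitation
change) to estimate the relative diversity loss at a mean plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

__all__ = [
    "ExtremumPoint",
    "ScenarioSpec",
    "ProjectionResult",
    "polynomial_extrema",
    "best_min_max",
    "tabulate_min_max",
    "project_scenario",
    "project_wed_table",
    "round_half_up",
]

ABSENT = "–"  # en dash used for "no such extremum" in report tables


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (display convention for report tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ExtremumPoint:
    """A critical point of a fitted curve, classified by curvature."""

    x: float
    y: float
    kind: str  # "local-min" | "local-max"
    in_range: bool


@dataclass(frozen=True)
class ScenarioSpec:
    """A climate scenario: additive warming and multiplicative precipitation change.

    Defaults encode the end-of-century (2090) forecast used for the
    replication runs: +3.75 degC (midpoint of the forecast 3.7-3.8 range)
    and an 18.2% precipitation decrease (factor 0.818).
    """

    delta_t: float = 3.75
    precip_factor: float = 0.818

    def __post_init__(self):
        if not self.precip_factor > 0:
            raise ValueError("precip_factor must be > 0")


@dataclass(frozen=True)
class ProjectionResult:
    """Baseline and scenario predictions with the relative change."""

    response: str
    baseline_pred: float
    scenario_pred: float
    percent_change: float  # 100 * (baseline - scenario) / baseline
    scenario_negative: bool


def _clean_coefficients(coefficients) -> np.ndarray:
    coef = [np.nan if c is None else float(c) for c in coefficients]
    coef = np.asarray(coef, dtype=float)
    keep = np.flatnonzero(~np.isnan(coef))
    if keep.size == 0:
        raise ValueError("no coefficients")
    coef = coef[keep.min():]
    if np.isnan(coef).any():
        raise ValueError("interior missing coefficient")
    nz = np.flatnonzero(coef != 0)
    coef = coef[nz.min():] if nz.size else coef
    return coef


def polynomial_extrema(coefficients, interval: tuple[float, float]) -> list[ExtremumPoint]:
    """Locate and classify the real critical points of a polynomial.

    ``coefficients`` are highest-degree first (a..e layout; leading
    entries may be None/NaN for lower-degree models). Roots of the
    derivative are found from the companion matrix and polished by Newton
    steps to |f'| below 1e-9 of the derivative's coefficient scale;
    each root is classified by the sign of f''. Roots outside
    ``interval`` are returned with ``in_range=False``.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if not np.isfinite([lo, hi]).all() or not lo < hi:
        raise ValueError("interval must be finite with lo < hi")
    coef = _clean_coefficients(coefficients)
    if coef.size < 2 or np.all(coef[:-1] == 0):
        raise ValueError("constant curve: no non-intercept coefficient")
    p = Polynomial(coef[::-1])
    d1 = p.deriv()
    d2 = d1.deriv()
    scale = np.max(np.abs(d1.coef)) or 1.0
    points: list[ExtremumPoint] = []
    roots = d1.roots()
    for root in roots:
        if abs(root.imag) > 1e-8 * max(1.0, abs(root)):
            continue
        x = float(root.real)
        for _ in range(3):  # Newton polish
            f1, f2 = d1(x), d2(x)
            if abs(f1) < 1e-12 * scale or f2 == 0:
                break
            x -= f1 / f2
        if abs(d1(x)) > 1e-9 * scale:
            continue
        curvature = d2(x)
        if abs(curvature) <= 1e-9 * scale:
            continue  # inflection / degenerate critical point
        points.append(
            ExtremumPoint(
                x=x,
                y=float(p(x)),
                kind="local-min" if curvature > 0 else "local-max",
                in_range=bool(lo <= x <= hi),
            )
        )
    points.sort(key=lambda pt: pt.x)
    return points


def best_min_max(
    points: list[ExtremumPoint],
) -> tuple[ExtremumPoint | None, ExtremumPoint | None]:
    """The reported (Min, Max): in-range local minimum with smallest y,
    in-range local maximum with largest y; None where absent."""
    mins = [pt for pt in points if pt.in_range and pt.kind == "local-min"]
    maxs = [pt for pt in points if pt.in_range and pt.kind == "local-max"]
    best_min = min(mins, key=lambda pt: pt.y) if mins else None
    best_max = max(maxs, key=lambda pt: pt.y) if maxs else None
    return best_min, best_max


def _format_point(pt: ExtremumPoint | None) -> str:
    if pt is None:
        return ABSENT
    return f"({round_half_up(pt.x, 2):.2f}; {round_half_up(pt.y, 2):.2f})"


def tabulate_min_max(
    fits: pd.DataFrame,
    ranges: dict[str, tuple[float, float]],
    taus: tuple[float, ...] = (0.5, 0.9),
) -> pd.DataFrame:
    """Summary table of in-range extrema of polynomial quantile fits.

    ``fits`` is a coefficient table with columns response, covariate,
    tau and a..e (as produced by the engine or the packaged reference
    fits). One row per (response, covariate), with "(x; y)" entries
    rounded to two decimals and an en dash where no such extremum exists.
    """
    coef_cols = [c for c in "abcde" if c in fits.columns]
    rows = []
    for (response, covariate), grp in fits.groupby(["response", "covariate"], sort=False):
        row: dict[str, object] = {"response": response, "covariate": covariate}
        for tau in taus:
            sub = grp[np.isclose(grp["tau"].astype(float), tau)]
            if sub.empty:
                row[f"min_tau{tau}"] = row[f"max_tau{tau}"] = ABSENT
                continue
            coef = sub.iloc[0][coef_cols].to_numpy(dtype=float)
            pts = polynomial_extrema(coef, ranges[covariate])
            lo_pt, hi_pt = best_min_max(pts)
            row[f"min_tau{tau}"] = _format_point(lo_pt)
            row[f"max_tau{tau}"] = _format_point(hi_pt)
        rows.append(row)
    return pd.DataFrame(rows)


def project_scenario(
    coefficients,
    baseline_map: float,
    baseline_mmax: float,
    scenario: ScenarioSpec,
    response: str = "v",
) -> ProjectionResult:
    """Project a water-energy fit ``v = a*MAP + b*MMAX + c`` under a scenario.

    The temperature increment is applied to the model's temperature
    covariate (MMAX) and precipitation is scaled multiplicatively.
    ``percent_change`` is the relative reduction in percent; a negative
    scenario prediction is allowed but flagged.
    """
    a, b, c = (float(v) for v in coefficients)
    baseline = a * baseline_map + b * baseline_mmax + c
    if baseline <= 0:
        raise ValueError(f"baseline prediction {baseline:.4g} <= 0: percent change undefined")
    scen = a * (baseline_map * scenario.precip_factor) + b * (baseline_mmax + scenario.delta_t) + c
    return ProjectionResult(
        response=response,
        baseline_pred=baseline,
        scenario_pred=scen,
        percent_change=100.0 * (baseline - scen) / baseline,
        scenario_negative=bool(scen < 0),
    )


def project_wed_table(
    wed_fits: pd.DataFrame,
    baseline_map: float,
    baseline_mmax: float,
    scenario: ScenarioSpec | None = None,
    tau: float = 0.5,
) -> pd.DataFrame:
    """Scenario projections for every response in a water-energy fit table."""
    scenario = scenario or ScenarioSpec()
    rows = []
    sub = wed_fits[np.isclose(wed_fits["tau"].astype(float), tau)]
    for _, fit in sub.iterrows():
        res = project_scenario(
            (fit["a"], fit["b"], fit["c"]),
            baseline_map,
            baseline_mmax,
            scenario,
            response=str(fit["response"]),
        )
        rows.append(
            {
                "response": res.response,
                "tau": tau,
                "baseline_pred": res.baseline_pred,
                "scenario_pred": res.scenario_pred,
                "percent_change": res.percent_change,
                "scenario_negative": res.scenario_negative,
            }
        )
    return pd.DataFrame(rows)
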