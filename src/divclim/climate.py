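"""Climate variable catalogue, annual aridity index, and input validation.

The pipeline works with 19 geographic/climatic variables per plot
(point estimates from an external climate-surface model; this package
does not interpolate climate). The derived annual aridity index

    AAI = sqrt(DD5) / MAP        [days^0.5 / mm]

combines energy (degree-days above 5 degC) and water (mean annual
precipitation); larger values mean more arid sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import climate_summary

__all__ = [
    "CLIMATE_VARIABLES",
    "VARIABLE_UNITS",
    "Violation",
    "aridity_index",
    "ensure_aai",
    "validate_climate",
]

#: Canonical column order of a climate table.
CLIMATE_VARIABLES: tuple[str, ...] = (
    "LONG", "LAT", "ELEV", "MAT", "MAP", "GSP", "MTCM", "MMIN", "MTWM",
    "MMAX", "SDAY", "FDAY", "FFP", "DD5", "GSDD5", "D100", "DD0",
    "MMINDD0", "AAI",
)

VARIABLE_UNITS: dict[str, str] = {
    "LONG": "deg", "LAT": "deg", "ELEV": "m", "MAT": "degC", "MAP": "mm",
    "GSP": "mm", "MTCM": "degC", "MMIN": "degC", "MTWM": "degC",
    "MMAX": "degC", "SDAY": "julian day", "FDAY": "julian day",
    "FFP": "days", "DD5": "degree-days", "GSDD5": "degree-days",
    "D100": "julian day", "DD0": "degree-days", "MMINDD0": "degree-days",
    "AAI": "days^0.5/mm",
}

#: Hard ordering invariant among the temperature variables.
_TEMP_ORDER = ("MMIN", "MTCM", "MAT", "MTWM", "MMAX")


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    variable: str
    message: str


def aridity_index(dd5, map_mm):
    """Annual aridity index sqrt(DD5)/MAP.

    Accepts scalars or arrays; strictly increasing in ``dd5`` and
    strictly decreasing in ``map_mm``.
    """
    dd5 = np.asarray(dd5, dtype=float)
    map_mm = np.asarray(map_mm, dtype=float)
    if np.any(dd5 < 0):
        raise ValueError("DD5 must be >= 0")
    if np.any(map_mm <= 0):
        raise ValueError("MAP must be > 0")
    out = np.sqrt(dd5) / map_mm
    return float(out) if out.ndim == 0 else out


def ensure_aai(table: pd.DataFrame, rel_tol: float = 1e-6) -> tuple[pd.DataFrame, list[Violation]]:
    """Fill AAI from DD5 and MAP when absent; cross-check when present.

    Input tables often carry a rounded AAI column, so a relative mismatch
    above ``rel_tol`` is reported as a warning, never an error. Returns
    the (possibly augmented) table and the list of warnings.
    """
    out = table.copy()
    violations: list[Violation] = []
    computed = aridity_index(out["DD5"], out["MAP"])
    if "AAI" not in out.columns or out["AAI"].isna().all():
        out["AAI"] = computed
        return out, violations
    rel = np.abs(out["AAI"].to_numpy(dtype=float) - computed) / np.abs(computed)
    bad = np.flatnonzero(rel > rel_tol)
    for i in bad:
        violations.append(
            Violation(
                "warning",
                "AAI",
                f"row {i}: AAI={out['AAI'].iloc[i]:.6g} differs from "
                f"sqrt(DD5)/MAP={computed[i]:.6g} (rel {rel[i]:.2e})",
            )
        )
    return out, violations


def validate_climate(record, soft_bounds: bool = True) -> list[Violation]:
    """Check one climate record against hard and soft constraints.

    Hard constraints (level ``"error"``): MAP > 0, 0 <= GSP <= MAP,
    DD5 >= 0, FFP >= 0, and the temperature ordering
    MMIN <= MTCM <= MAT <= MTWM <= MMAX, plus AAI consistency with
    sqrt(DD5)/MAP (warning, see :func:`ensure_aai`). Soft constraints
    (level ``"warning"``): values outside the packaged observed
    min/max summary for the Durango study region — the pipeline must
    still run on climates from elsewhere.
    """
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)
    v: list[Violation] = []

    def has(name):
        val = get(name)
        return val is not None and not (isinstance(val, float) and np.isnan(val))

    if has("MAP") and get("MAP") <= 0:
        v.append(Violation("error", "MAP", f"MAP={get('MAP')} must be > 0"))
    if has("GSP"):
        if get("GSP") < 0:
            v.append(Violation("error", "GSP", "GSP must be >= 0"))
        if has("MAP") and get("GSP") > get("MAP"):
            v.append(Violation("error", "GSP", "GSP exceeds MAP"))
    for name in ("DD5", "FFP"):
        if has(name) and get(name) < 0:
            v.append(Violation("error", name, f"{name} must be >= 0"))
    present = [t for t in _TEMP_ORDER if has(t)]
    for lo, hi in zip(present[:-1], present[1:]):
        if get(lo) > get(hi):
            v.append(
                Violation("error", hi, f"temperature ordering violated: {lo}={get(lo)} > {hi}={get(hi)}")
            )
    if has("AAI") and has("DD5") and has("MAP") and get("MAP") > 0:
        expected = aridity_index(get("DD5"), get("MAP"))
        if expected > 0 and abs(get("AAI") - expected) / expected > 1e-6:
            v.append(
                Violation("warning", "AAI", f"AAI={get('AAI'):.6g} != sqrt(DD5)/MAP={expected:.6g}")
            )
    if soft_bounds:
        summary = climate_summary()
        for name in CLIMATE_VARIABLES:
            if not has(name) or name not in summary.index:
                continue
            lo, hi = summary.loc[name, "min"], summary.loc[name, "max"]
            if get(name) < lo or get(name) > hi:
                v.append(
                    Violation(
                        "warning",
                        name,
                        f"{name}={get(name)} outside observed range [{lo}, {hi}]",
                    )
                )
    return v
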