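"""Packaged reference tables.

Small CSVs shipped with the package: the published quantile-regression
coefficients for tree diversity in the Sierra Madre Occidental (Durango)
and the descriptive summary of that region's geographic/climatic
variables. They let the curve-analysis and projection stages run as
verification exercises without access to the (undeposited) raw inventory
data.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = [
    "quartic_quantile_fits",
    "wed_quantile_fits",
    "climate_summary",
    "REPLICATION_RANGES",
]

#: Covariate intervals over which the published fitted curves are analyzed.
#: Temperature covariates use the observed min/max; AAI uses the plotted
#: curve range (the published extrema at AAI = 0.04 fall below the observed
#: minimum 0.060, so the observed range cannot bracket them); NIP uses the
#: stated validity range of its models.
REPLICATION_RANGES: dict[str, tuple[float, float]] = {
    "MAT": (8.3, 26.2),
    "MTWM": (12.6, 30.5),
    "MMAX": (20.6, 40.2),
    "AAI": (0.03, 0.16),
    "NIP": (1.0, 120.0),
}


def _load(name: str) -> pd.DataFrame:
    with files("divclim.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def quartic_quantile_fits() -> pd.DataFrame:
    """Published univariate polynomial quantile-fit coefficients.

    Columns: response (v0|v2|vinf), covariate, tau, r2, a..e with ``a``
    the x^4 term. One model (v0–MMAX at tau=0.5) is a cubic; its ``a``
    cell is empty (NaN).
    """
    return _load("quartic_quantile_fits.csv")


def wed_quantile_fits() -> pd.DataFrame:
    """Published water-energy (v_a = a*MAP + b*MMAX + c) quantile fits."""
    return _load("wed_quantile_fits.csv")


def climate_summary() -> pd.DataFrame:
    """Descriptive statistics (mean, sd, min, max) of the study variables."""
    return _load("durango_climate_summary.csv").set_index("variable")
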