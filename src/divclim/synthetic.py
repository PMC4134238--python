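"""Synthetic forest-inventory data with known statistical structure.

The raw national-inventory plot data behind the published Durango
analysis is not deposited, so every pipeline stage is exercised on
synthetic data that emulates its documented structure: plots on a jittered
5 x 5 km grid; an elevation-driven, strongly collinear temperature
variable group; a separate precipitation gradient; an aridity index
computed exactly as sqrt(DD5)/MAP; stand density (NIP) falling with
aridity; and species-abundance vectors whose richness responds to
temperature and aridity with the hollow/hump shapes seen in the region,
with geometric-series evenness over a 327-label regional species pool.

All randomness flows from a single integer seed through named substreams
(climate, communities, stems, quantile-data), so stages can be
regenerated independently and identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import CLIMATE_VARIABLES, aridity_index
from .plot_io import PlotSample

__all__ = [
    "SyntheticConfig",
    "TEMPERATURE_GROUP",
    "PRECIPITATION_GROUP",
    "generate_climate",
    "generate_communities",
    "generate_stems",
    "generate_known_quantile_dataset",
    "KnownQuantileDataset",
    "error_quantile",
]

#: Planted factor structure of the generated climate table.
TEMPERATURE_GROUP: tuple[str, ...] = (
    "ELEV", "MAT", "MTCM", "MMIN", "MTWM", "MMAX", "SDAY", "FDAY", "FFP",
    "DD5", "GSDD5", "D100", "DD0", "MMINDD0",
)
PRECIPITATION_GROUP: tuple[str, ...] = ("MAP", "GSP", "LAT", "AAI")

_STREAMS = {"climate": 0, "communities": 1, "stems": 2, "quantile": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[_STREAMS[stream]])


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the Durango study region scale.

    1,632 plots, elevations 390-3,156 m, a 6.5 degC/km lapse rate pinned so
    mean annual temperature spans roughly 8-26 degC, precipitation averaging
    ~917 mm on a latitudinal gradient, mean stand density ~70 trees/plot
    decaying with aridity, mean richness ~6.5 species from a regional pool
    of 327, and geometric-series evenness.
    """

    n_plots: int = 1632
    seed: int = 0
    # geography / temperature group
    lon_range: tuple[float, float] = (-107.2, -104.1)
    lat_range: tuple[float, float] = (22.4, 26.8)
    elevation_range: tuple[float, float] = (390.0, 3156.0)
    mat_at_sea_level: float = 28.0  # degC
    lapse_rate: float = 6.5  # degC per km of elevation
    temp_noise_sd: float = 0.3  # degC, noise on MAT around the lapse line
    collinearity_noise: float = 0.4  # sd of the derived temperature variables
    # precipitation group
    map_mean: float = 916.8  # mm
    map_lat_slope: float = -140.0  # mm per degree latitude
    map_noise_sd: float = 140.0  # mm
    gsp_fraction: float = 0.75  # growing-season share of MAP
    gsp_noise_sd: float = 30.0  # mm
    # communities
    nip_max_mean: float = 170.0  # NIP mean at AAI = 0
    aridity_decay: float = 14.0  # per unit AAI
    nip_dispersion: float = 3.0  # negative-binomial k
    # log-mean richness: b0 + b1*zMAT + b2*zMAT^2 + b3*zAAI + b4*zAAI^2
    richness_params: tuple[float, ...] = (1.4, -0.2, 0.08, -0.45, 0.10)
    nip_coupling: float = 0.35  # accumulation effect: d log(richness) / d log(NIP)
    evenness_theta: float = 0.55  # geometric-series abundance ratio
    species_pool: int = 327
    # stem-level emission
    subthreshold_fraction: float = 0.05  # extra non-qualifying stems per plot

    def __post_init__(self):
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if not 0 < self.evenness_theta <= 1:
            raise ValueError("evenness_theta must be in (0, 1]")


def generate_climate(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a plot climate table with the planted two-factor structure.

    The temperature-group variables are affine in MAT plus small noise
    (pairwise |r| > 0.9 within the group by construction, with the
    MMIN <= MTCM <= MAT <= MTWM <= MMAX ordering enforced through
    one-sided noise); MAP rides a latitudinal gradient independent of
    elevation, GSP is a noisy fraction of MAP, and AAI is computed
    exactly as sqrt(DD5)/MAP. Deterministic given the config seed.
    """
    cfg = config
    rng = _rng(cfg.seed, "climate")
    n = cfg.n_plots
    # jittered grid over the study window
    side = int(np.ceil(np.sqrt(n)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    cells = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    lon_step = (cfg.lon_range[1] - cfg.lon_range[0]) / side
    lat_step = (cfg.lat_range[1] - cfg.lat_range[0]) / side
    lon = cfg.lon_range[0] + (cells[:, 0] + rng.uniform(0.1, 0.9, n)) * lon_step
    lat = cfg.lat_range[0] + (cells[:, 1] + rng.uniform(0.1, 0.9, n)) * lat_step

    elev = rng.uniform(*cfg.elevation_range, n)
    mat = cfg.mat_at_sea_level - cfg.lapse_rate * elev / 1000.0 + rng.normal(0, cfg.temp_noise_sd, n)
    cn = cfg.collinearity_noise
    half = np.abs(rng.normal(0, cn, (4, n)))  # one-sided: ordering always holds
    mtcm = mat - 5.2 - half[0]
    mmin = mtcm - 9.2 - half[1]
    mtwm = mat + 4.6 + half[2]
    mmax = mtwm + 8.4 + half[3]
    # slopes chosen so no variable hits its physical floor/ceiling over the
    # MAT range: clipping would break the planted within-group collinearity
    mat_c = mat - 13.5
    sday = np.clip(112 - 8.0 * mat_c + rng.normal(0, 5, n), 1, 182)
    fday = np.clip(303 + 5.0 * mat_c + rng.normal(0, 4, n), 183, 365)
    ffp = np.maximum(fday - sday + rng.normal(0, 3, n), 0.0)
    dd5 = np.maximum(275.0 * mat - 512.0 + rng.normal(0, 100, n), 1.0)
    gsdd5 = np.clip(0.74 * dd5 + rng.normal(0, 60, n), 0.0, dd5)
    d100 = np.clip(36 - 2.5 * mat_c + rng.normal(0, 3, n), 1, 200)
    dd0 = np.maximum(45 - 3.4 * mat_c + rng.normal(0, 3, n), 0.0)
    mmindd0 = np.maximum(725 - 50.0 * mat_c + rng.normal(0, 30, n), 0.0)

    map_mm = cfg.map_mean + cfg.map_lat_slope * (lat - np.mean(cfg.lat_range)) + rng.normal(
        0, cfg.map_noise_sd, n
    )
    if np.any(map_mm <= 0):
        raise ValueError("configuration produced non-positive MAP")
    gsp = np.clip(cfg.gsp_fraction * map_mm + rng.normal(0, cfg.gsp_noise_sd, n), 0.0, map_mm)

    table = pd.DataFrame(
        {
            "plot_id": [f"P{i:05d}" for i in range(1, n + 1)],
            "LONG": lon, "LAT": lat, "ELEV": elev, "MAT": mat, "MAP": map_mm,
            "GSP": gsp, "MTCM": mtcm, "MMIN": mmin, "MTWM": mtwm, "MMAX": mmax,
            "SDAY": sday, "FDAY": fday, "FFP": ffp, "DD5": dd5, "GSDD5": gsdd5,
            "D100": d100, "DD0": dd0, "MMINDD0": mmindd0,
            "AAI": aridity_index(dd5, map_mm),
        }
    )
    return table[["plot_id", *CLIMATE_VARIABLES]]


def generate_communities(
    climate: pd.DataFrame, config: SyntheticConfig
) -> list[PlotSample]:
    """Generate species-abundance vectors responding to climate.

    NIP is negative-binomial with mean ``nip_max_mean *
    exp(-aridity_decay * AAI)``; latent richness is ``1 + Poisson(lambda)``
    with ``log lambda`` quadratic in standardized MAT and AAI
    (``richness_params``), capped at NIP and the pool size. Each species
    receives one individual before the remainder is split multinomially
    with geometric-series weights ``theta**k``, so realized richness
    equals the planted richness. Plots drawing NIP = 0 are omitted (they
    would be excluded by the filtering stage anyway).
    """
    cfg = config
    rng = _rng(cfg.seed, "communities")
    aai = climate["AAI"].to_numpy(dtype=float)
    mat = climate["MAT"].to_numpy(dtype=float)
    z = lambda v: (v - v.mean()) / v.std()  # noqa: E731
    z_mat, z_aai = z(mat), z(aai)
    b0, b1, b2, b3, b4 = cfg.richness_params
    mean_nip = cfg.nip_max_mean * np.exp(-cfg.aridity_decay * aai)
    k = cfg.nip_dispersion
    nip = rng.negative_binomial(k, k / (k + mean_nip))
    # accumulation effect: denser plots sample more species, saturating
    density_term = cfg.nip_coupling * np.log((nip + 1) / 70.0)
    lam = np.exp(b0 + b1 * z_mat + b2 * z_mat**2 + b3 * z_aai + b4 * z_aai**2 + density_term)
    richness = np.minimum.reduce(
        [1 + rng.poisson(lam), np.maximum(nip, 1), np.full_like(nip, cfg.species_pool)]
    )
    pool = np.array([f"sp{i:03d}" for i in range(1, cfg.species_pool + 1)])
    pool_w = 1.0 / (np.arange(cfg.species_pool) + 5.0)  # a few dominant labels
    pool_w /= pool_w.sum()

    plots: list[PlotSample] = []
    ids = climate["plot_id"].astype(str).to_numpy()
    lon = climate["LONG"].to_numpy(float)
    lat = climate["LAT"].to_numpy(float)
    elev = climate["ELEV"].to_numpy(float)
    for i in range(len(climate)):
        if nip[i] < 1:
            continue
        s = int(richness[i])
        labels = rng.choice(pool, size=s, replace=False, p=pool_w)
        w = cfg.evenness_theta ** np.arange(s)
        w /= w.sum()
        counts = np.ones(s, dtype=int)
        remainder = int(nip[i]) - s
        if remainder > 0:
            counts += rng.multinomial(remainder, w)
        plots.append(
            PlotSample(
                plot_id=ids[i],
                species_counts=dict(zip(labels.tolist(), counts.tolist())),
                longitude=lon[i],
                latitude=lat[i],
                elevation=elev[i],
            )
        )
    return plots


def generate_stems(plots: list[PlotSample], config: SyntheticConfig) -> pd.DataFrame:
    """Expand plot samples to a stem-level table.

    Qualifying stems get height >= 3 m and dbh >= 7.5 cm; a configurable
    fraction of extra non-qualifying stems (too short or too thin) is
    added per plot so that the filtering stage has work to do. Filtering
    and aggregating the emitted table reproduces the input plots exactly.
    """
    cfg = config
    rng = _rng(cfg.seed, "stems")
    rows = []
    for plot in plots:
        for sp, count in plot.species_counts.items():
            h = 3.0 + rng.gamma(2.0, 4.0, count)
            d = 7.5 + rng.gamma(2.0, 6.0, count)
            for j in range(count):
                rows.append((plot.plot_id, sp, float(h[j]), float(d[j])))
        n_extra = rng.binomial(plot.nip, cfg.subthreshold_fraction)
        for _ in range(n_extra):
            sp = rng.choice(list(plot.species_counts))
            if rng.random() < 0.5:  # sapling: tall enough fails, thin fails too
                rows.append((plot.plot_id, str(sp), float(rng.uniform(0.5, 2.9)), float(rng.uniform(1.0, 7.4))))
            else:  # thin but tall
                rows.append((plot.plot_id, str(sp), float(3.0 + rng.gamma(2.0, 2.0)), float(rng.uniform(1.0, 7.4))))
    return pd.DataFrame(rows, columns=["plot_id", "species", "height", "dbh"])


def error_quantile(tau: float) -> float:
    """tau-quantile of the generator's error distribution.

    Errors are shifted exponential, ``eps = Exp(1) - ln 2`` (median
    zero, right-skewed), so the three fitted quantile curves differ
    materially: z_tau = -ln(1 - tau) - ln 2.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    return float(-np.log1p(-tau) - np.log(2.0))


@dataclass
class KnownQuantileDataset:
    """Synthetic (x, y) data whose conditional quantiles are known polynomials."""

    x: np.ndarray
    y: np.ndarray
    taus: tuple[float, ...]
    true_coefficients: dict[float, np.ndarray] = field(repr=False)

    def truth(self, tau: float) -> np.ndarray:
        return self.true_coefficients[tau]


def generate_known_quantile_dataset(
    location_coefficients,
    scale_coefficients,
    taus: tuple[float, ...] = (0.1, 0.5, 0.9),
    n: int = 2000,
    seed: int = 0,
    x_range: tuple[float, float] = (0.03, 0.16),
) -> KnownQuantileDataset:
    """Location-scale data ``y = m(x) + s(x) * eps`` with polynomial quantiles.

    ``m`` and ``s`` are polynomial coefficient vectors (highest-degree
    first). With eps shifted exponential (see :func:`error_quantile`),
    the true conditional quantile ``Q_tau(y|x) = m(x) + z_tau * s(x)``
    is itself a polynomial; its coefficient vector is returned per tau.
    ``s`` must be strictly positive on the x-range.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    m = np.asarray(location_coefficients, dtype=float)
    s = np.asarray(scale_coefficients, dtype=float)
    grid = np.linspace(*x_range, 512)
    if np.any(np.polyval(s, grid) <= 0):
        raise ValueError("scale polynomial must be > 0 on the x-range")
    rng = _rng(seed, "quantile")
    x = rng.uniform(*x_range, n)
    eps = rng.exponential(1.0, n) - np.log(2.0)
    y = np.polyval(m, x) + np.polyval(s, x) * eps
    width = max(m.size, s.size)
    pad = lambda c: np.concatenate([np.zeros(width - c.size), c])  # noqa: E731
    truths = {
        tau: pad(m) + error_quantile(tau) * pad(s) for tau in taus
    }
    return KnownQuantileDataset(x=x, y=y, taus=tuple(taus), true_coefficients=truths)
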