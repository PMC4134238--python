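"""Reading, filtering and joining of inventory plot tables.

Two input shapes are supported, selected explicitly by the caller (no
auto-detection): stem-level records (one row per measured tree) or
pre-aggregated species-count tables. Stem records are filtered by the
inventory qualification rule — height >= 3 m and diameter at breast
height >= 7.5 cm, both inclusive — and aggregated to per-plot species
counts; plots left without qualifying stems are dropped.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StemRecord",
    "PlotSample",
    "RowError",
    "read_stems",
    "read_counts",
    "filter_and_aggregate",
    "join_climate",
    "write_counts",
]

DEFAULT_STEM_COLUMNS = {
    "plot_id": "plot_id",
    "species": "species",
    "height": "height",
    "dbh": "dbh",
}
DEFAULT_COUNT_COLUMNS = {
    "plot_id": "plot_id",
    "species": "species",
    "count": "count",
    "longitude": "longitude",
    "latitude": "latitude",
    "elevation": "elevation",
}


@dataclass(frozen=True)
class StemRecord:
    """One measured tree: plot, species label, height (m), dbh (cm)."""

    plot_id: str
    species: str
    height: float
    dbh: float

    def __post_init__(self):
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if not self.dbh > 0:
            raise ValueError(f"dbh must be > 0, got {self.dbh}")


@dataclass
class PlotSample:
    """One inventory plot with its qualifying-stem species counts.

    ``nip`` (number of individuals per plot) is always the sum of the
    counts; it is recomputed on construction.
    """

    plot_id: str
    species_counts: dict[str, int]
    longitude: float = np.nan
    latitude: float = np.nan
    elevation: float = np.nan
    nip: int = field(init=False)

    def __post_init__(self):
        if any(c < 1 for c in self.species_counts.values()):
            raise ValueError("every listed species needs count >= 1")
        self.nip = int(sum(self.species_counts.values()))
        if self.nip < 1:
            raise ValueError(f"plot {self.plot_id} has no individuals")
        if not np.isnan(self.longitude) and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")
        if not np.isnan(self.latitude) and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")


@dataclass(frozen=True)
class RowError:
    """A malformed input row: 1-based line number and what was wrong."""

    line: int
    message: str


def _require_columns(frame: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_stems(
    path, columns: Mapping[str, str] | None = None
) -> tuple[list[StemRecord], list[RowError]]:
    """Read a stem-level CSV.

    Returns ``(records, errors)``: one :class:`StemRecord` per parseable
    row, and one :class:`RowError` per malformed row (unparseable or
    non-positive height/dbh), each carrying the 1-based data line number.
    Nothing is dropped silently; errors are also logged. A missing
    required column is fatal.
    """
    cols = {**DEFAULT_STEM_COLUMNS, **(columns or {})}
    frame = pd.read_csv(path, dtype=str)
    _require_columns(frame, cols.values(), path)
    records: list[StemRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # line 1 = header
        raw = dict(zip(frame.columns, row))
        try:
            records.append(
                StemRecord(
                    plot_id=str(raw[cols["plot_id"]]),
                    species=str(raw[cols["species"]]),
                    height=float(raw[cols["height"]]),
                    dbh=float(raw[cols["dbh"]]),
                )
            )
        except (TypeError, ValueError) as exc:
            err = RowError(line=i, message=str(exc))
            errors.append(err)
            logger.warning("%s line %d skipped: %s", path, i, exc)
    return records, errors


def read_counts(path, columns: Mapping[str, str] | None = None) -> list[PlotSample]:
    """Read a pre-aggregated species-count CSV (one row per plot x species)."""
    cols = {**DEFAULT_COUNT_COLUMNS, **(columns or {})}
    frame = pd.read_csv(path)
    _require_columns(frame, [cols["plot_id"], cols["species"], cols["count"]], path)
    plots: list[PlotSample] = []
    for plot_id, grp in frame.groupby(cols["plot_id"], sort=False):
        meta = {}
        for key in ("longitude", "latitude", "elevation"):
            if cols[key] in grp.columns:
                meta[key] = float(grp[cols[key]].iloc[0])
        counts = {
            str(sp): int(c)
            for sp, c in zip(grp[cols["species"]], grp[cols["count"]])
            if int(c) > 0
        }
        if counts:
            plots.append(PlotSample(plot_id=str(plot_id), species_counts=counts, **meta))
    return plots


def write_counts(plots: Iterable[PlotSample], path) -> pd.DataFrame:
    """Write plots as a long species-count CSV (inverse of :func:`read_counts`)."""
    rows = []
    for p in plots:
        for sp, c in p.species_counts.items():
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "species": sp,
                    "count": c,
                    "longitude": p.longitude,
                    "latitude": p.latitude,
                    "elevation": p.elevation,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def filter_and_aggregate(
    stems: Sequence[StemRecord],
    min_height: float = 3.0,
    min_dbh: float = 7.5,
    plot_meta: Mapping[str, Mapping[str, float]] | None = None,
) -> list[PlotSample]:
    """Apply the stem qualification rule and aggregate to plot samples.

    Stems with ``height >= min_height`` and ``dbh >= min_dbh`` (inclusive
    thresholds) qualify; plots with no qualifying stem are excluded.
    ``plot_meta`` optionally supplies ``longitude``/``latitude``/
    ``elevation`` per plot id. Empty input yields an empty list.
    """
    if not min_height > 0 or not min_dbh > 0:
        raise ValueError("thresholds must be positive")
    per_plot: dict[str, dict[str, int]] = {}
    for stem in stems:
        if stem.height >= min_height and stem.dbh >= min_dbh:
            counts = per_plot.setdefault(stem.plot_id, {})
            counts[stem.species] = counts.get(stem.species, 0) + 1
    dropped = {s.plot_id for s in stems} - set(per_plot)
    if dropped:
        logger.info("excluded %d plot(s) without qualifying trees", len(dropped))
    plots = []
    for plot_id, counts in per_plot.items():
        meta = dict((plot_meta or {}).get(plot_id, {}))
        plots.append(PlotSample(plot_id=plot_id, species_counts=counts, **meta))
    return plots


def join_climate(plots: Sequence[PlotSample], climate: pd.DataFrame) -> pd.DataFrame:
    """Inner-join plot diversity inputs with a climate table on plot_id.

    Duplicate plot ids in the climate table are fatal; ids present on
    only one side are reported via logging and dropped by the join.
    """
    if climate["plot_id"].duplicated().any():
        dups = climate.loc[climate["plot_id"].duplicated(), "plot_id"].unique()
        raise ValueError(f"duplicate plot_id in climate table: {list(dups)[:5]}")
    left = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "nip": [p.nip for p in plots],
        }
    )
    if left["plot_id"].duplicated().any():
        raise ValueError("duplicate plot_id among plots")
    climate = climate.copy()
    climate["plot_id"] = climate["plot_id"].astype(str)
    only_left = set(left["plot_id"]) - set(climate["plot_id"])
    only_right = set(climate["plot_id"]) - set(left["plot_id"])
    for side, ids in (("plots", only_left), ("climate", only_right)):
        if ids:
            logger.warning("%d %s id(s) unmatched in join: %s", len(ids), side, sorted(ids)[:5])
    return left.merge(climate, on="plot_id", how="inner")
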