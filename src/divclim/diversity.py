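"""Hill-number diversity profiles for species-abundance data.

The diversity of order ``a`` of a relative-frequency vector ``p`` is

    v_a = (sum_i p_i ** a) ** (1 / (1 - a)),   a >= 0, a != 1,

with the continuous extension ``v_1 = exp(-sum_i p_i log p_i)`` (the
exponential of Shannon entropy) and the limit ``v_inf = 1 / max_i p_i``.
Three orders are surfaced throughout the pipeline: ``v_0`` (species
richness), ``v_2`` (the effective species number, the reciprocal of
Simpson's concentration) and ``v_inf`` (the number of prevalent species).
``v_a`` is non-increasing in ``a``; the three values coincide exactly when
all species are equally abundant, in which case each equals the number of
species.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EmptyPlotError",
    "DiversityProfile",
    "hill_diversity",
    "diversity_profile",
    "profiles_table",
]


class EmptyPlotError(ValueError):
    """Raised for an abundance vector with no individuals.

    Plots without qualifying trees carry no diversity information and are
    excluded upstream; asking for their diversity is a caller error.
    """


@dataclass(frozen=True)
class DiversityProfile:
    """The (v0, v2, v_inf) diversity profile of one plot."""

    v0: float
    v2: float
    v_inf: float

    def __iter__(self):
        return iter((self.v0, self.v2, self.v_inf))


def _frequencies(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        values = np.asarray(list(counts.values()), dtype=float)
    else:
        values = np.asarray(list(counts), dtype=float)
    if values.size and (values < 0).any():
        raise ValueError("negative species count")
    total = values.sum()
    if values.size == 0 or total == 0:
        raise EmptyPlotError("plot has no individuals (excluded upstream)")
    values = values[values > 0]
    return values / total


def hill_diversity(counts, a: float) -> float:
    """Diversity of order ``a`` of an abundance vector.

    Parameters
    ----------
    counts
        Mapping species -> count, or a plain sequence of counts. Zero
        counts are ignored; all counts must be non-negative with a
        positive total.
    a
        Diversity order, ``0 <= a <= inf``. ``a=0`` counts species,
        ``a=2`` is the effective number, ``numpy.inf`` weighs only the
        most frequent species. ``a=1`` returns the Shannon limit.

    Returns
    -------
    float
        ``v_a``, a value in ``[1, number of species]``.
    """
    if a < 0:
        raise ValueError(f"diversity order must be >= 0, got {a}")
    p = _frequencies(counts)
    if math.isinf(a):
        return float(1.0 / p.max())
    if a == 0:
        return float(p.size)
    if a == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**a) ** (1.0 / (1.0 - a)))


def diversity_profile(counts) -> DiversityProfile:
    """The (v0, v2, v_inf) profile of one abundance vector."""
    return DiversityProfile(
        v0=hill_diversity(counts, 0),
        v2=hill_diversity(counts, 2),
        v_inf=hill_diversity(counts, np.inf),
    )


def profiles_table(plots: Iterable) -> pd.DataFrame:
    """Per-plot diversity table for a collection of ``PlotSample``s.

    Returns a frame with columns plot_id, nip, v0, v2, v_inf — the
    response table every later pipeline stage consumes.
    """
    rows = []
    for plot in plots:
        prof = diversity_profile(plot.species_counts)
        rows.append(
            {
                "plot_id": plot.plot_id,
                "nip": plot.nip,
                "v0": prof.v0,
                "v2": prof.v2,
                "v_inf": prof.v_inf,
            }
        )
    return pd.DataFrame(rows, columns=["plot_id", "nip", "v0", "v2", "v_inf"])
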