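"""Onset analyses over harmonized phenology rows.

Implements the standard downstream workflow for integrated status/event
data: select rows bearing one presence class but not another (e.g. 'true
leaves present' without 'senescing true leaves present'), snap coordinates
to a 0.1-degree grid, keep the earliest qualifying observation per grid
cell and year, drop thinly sampled decades, and summarize each remaining
decade by its median day of year and a Gaussian kernel density estimate
whose bandwidth follows the interquartile-range rule of thumb

    h = 0.9 * min(sd, IQR / 1.34) * n ** (-1/5).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .catalog import TraitCatalog
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    RangeError,
    UnknownTermError,
)

ONSET_COLUMNS = ("cell_lat", "cell_lon", "year", "day_of_year", "observation_id")


@dataclass(frozen=True)
class TraitQuery:
    """Keep rows bearing ``require_class`` but not ``exclude_class``."""

    require_class: str
    exclude_class: str | None = None
    genus: str | None = None
    year_range: tuple[int, int] | None = None

    def __post_init__(self):
        if self.exclude_class == self.require_class:
            raise ValueError("exclude_class must differ from require_class")


@dataclass(frozen=True)
class DecadeSummary:
    """Median onset and KDE for one sufficiently sampled decade."""

    decade: int
    n: int
    median_doy: float
    density: tuple[tuple[float, float], ...]  # (doy, density) pairs


def select_observations(
    rows: pd.DataFrame, q: TraitQuery, catalog: TraitCatalog | None = None
) -> pd.DataFrame:
    """Filter harmonized rows by inferred class membership, genus and years.

    Genus matching is case-insensitive exact.  With a catalog supplied, the
    query's class ids are checked against it first.
    """
    if catalog is not None:
        for cid in (q.require_class, q.exclude_class):
            if cid is not None and cid not in catalog.presence_classes:
                raise UnknownTermError(cid)
    if rows.empty:
        return rows.copy()
    mask = rows["inferred_classes"].map(lambda s: q.require_class in s)
    if q.exclude_class is not None:
        mask &= rows["inferred_classes"].map(lambda s: q.exclude_class not in s)
    if q.genus is not None:
        mask &= rows["genus"].str.lower() == q.genus.lower()
    if q.year_range is not None:
        years = rows["date"].dt.year
        mask &= (years >= q.year_range[0]) & (years <= q.year_range[1])
    return rows[mask].copy()


def grid_cell(latitude: float, longitude: float) -> tuple[float, float]:
    """Round a coordinate pair to the 0.1-degree grid, half away from zero."""
    if not -90.0 <= latitude <= 90.0:
        raise RangeError(f"latitude {latitude} outside [-90, 90]")
    if not -180.0 <= longitude <= 180.0:
        raise RangeError(f"longitude {longitude} outside [-180, 180]")
    return _round_tenth(latitude), _round_tenth(longitude)


def _round_tenth(value: float) -> float:
    # Decimal(str(...)) uses the shortest float repr, so 0.05 rounds as
    # written, not as its binary expansion; ROUND_HALF_UP is away-from-zero.
    return float(Decimal(str(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def earliest_per_cell_year(rows: pd.DataFrame) -> pd.DataFrame:
    """Earliest qualifying observation per (0.1-degree cell, year).

    Returns one row per occupied (cell_lat, cell_lon, year) with the
    minimum day of year; ties broken by observation_id.  Rows missing
    coordinates are skipped; their count is available via the difference in
    row totals (inputs are expected to carry coordinates after validation).
    """
    if rows.empty:
        return pd.DataFrame(columns=ONSET_COLUMNS)
    df = rows.dropna(subset=["latitude", "longitude"]).copy()
    df["cell_lat"] = df["latitude"].map(_round_tenth)
    df["cell_lon"] = df["longitude"].map(_round_tenth)
    df["year"] = df["date"].dt.year.astype(int)
    df["day_of_year"] = df["date"].dt.dayofyear.astype(int)
    df = df.sort_values(
        ["cell_lat", "cell_lon", "year", "day_of_year", "observation_id"],
        kind="mergesort",
    )
    first = df.groupby(["cell_lat", "cell_lon", "year"], as_index=False).first()
    return first[list(ONSET_COLUMNS)].reset_index(drop=True)


def decade_of(year: int) -> int:
    return (year // 10) * 10


def filter_decades(estimates: pd.DataFrame, min_records: int) -> pd.DataFrame:
    """Drop all estimates in decades holding fewer than ``min_records``."""
    if min_records < 0:
        raise ValueError("min_records must be >= 0")
    if estimates.empty or min_records == 0:
        return estimates.copy()
    decades = (estimates["year"] // 10) * 10
    counts = decades.value_counts()
    keep = decades.map(lambda d: counts[d] >= min_records)
    return estimates[keep].copy()


def rule_of_thumb_bandwidth(values) -> float:
    """IQR rule-of-thumb bandwidth: ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``.

    ``sd`` is the sample standard deviation (n-1 denominator); the IQR uses
    linear-interpolation quantiles.  When the IQR is zero but the data still
    have spread, the standard deviation alone is used.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 values, got {n}")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise DegenerateDataError("all values identical")
    q75, q25 = np.percentile(arr, [75, 25])
    iqr = float(q75 - q25)
    spread = sd if iqr == 0 else min(sd, iqr / 1.34)
    return 0.9 * spread * n ** (-0.2)


def kde_density(
    values, grid=None, *, bandwidth: float | None = None, grid_size: int = 512
) -> np.ndarray:
    """Gaussian KDE evaluated on a grid; returns an (m, 2) array of
    (position, density) pairs.

    The default grid spans the data range extended by four bandwidths on
    each side, which captures essentially all kernel mass, so the
    trapezoidal integral of the returned curve is 1 to within 1e-3.
    """
    arr = np.asarray(values, dtype=float)
    h = rule_of_thumb_bandwidth(arr) if bandwidth is None else float(bandwidth)
    if grid is None:
        grid = np.linspace(arr.min() - 4 * h, arr.max() + 4 * h, grid_size)
    else:
        grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - arr[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (arr.size * h * np.sqrt(2 * np.pi))
    return np.column_stack([grid, dens])


def decade_summary(
    estimates: pd.DataFrame, min_records: int, *, grid_size: int = 512
) -> list[DecadeSummary]:
    """Per-decade sample size, median day of year and density curve.

    Decades below ``min_records`` are dropped first.  The median uses the
    midpoint convention for even n (the mean of the two central order
    statistics).  Decades whose onsets are all identical get an empty
    density (no bandwidth is estimable).
    """
    kept = filter_decades(estimates, min_records)
    summaries: list[DecadeSummary] = []
    if kept.empty:
        return summaries
    decades = (kept["year"] // 10) * 10
    for decade in sorted(decades.unique()):
        values = kept.loc[decades == decade, "day_of_year"].to_numpy(dtype=float)
        try:
            curve = kde_density(values, grid_size=grid_size)
            density = tuple((float(x), float(y)) for x, y in curve)
        except (InsufficientDataError, DegenerateDataError):
            density = ()
        summaries.append(
            DecadeSummary(
                decade=int(decade),
                n=int(values.size),
                median_doy=float(np.median(values)),
                density=density,
            )
        )
    return summaries


def summaries_to_frames(
    summaries: list[DecadeSummary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular form of decade summaries: (per-decade stats, density curves)."""
    stats = pd.DataFrame(
        [(s.decade, s.n, s.median_doy) for s in summaries],
        columns=["decade", "n", "median_doy"],
    )
    curves = pd.DataFrame(
        [(s.decade, x, y) for s in summaries for x, y in s.density],
        columns=["decade", "doy", "density"],
    )
    return stats, curves
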