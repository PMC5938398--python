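"""Seeded generator of status- and event-dialect phenology datasets.

The generator emulates the statistical structure the analyses assume: each
plant sits at a fixed location, and its onset day of year in each year is
drawn from ``Normal(a + b * latitude, sigma^2)`` — a latitudinal cline in
spring onset (later at higher latitude, roughly the classical few-days-per-
degree gradient) with plant-to-plant and year-to-year noise — truncated to
the feasible window ``[1, 366 - season_length]``.  The structure is then
visible (status "yes" / the BBCH-style event) from onset until onset +
``season_length`` days.

Two network dialects are emitted from the same ground truth:

* **status**: a visit every ``status_cadence`` days over the whole year,
  each producing a yes/no record; "yes" visits carry a count-range
  intensity that widens through the season (the 10-to-20-leaves pattern).
  The first "yes" therefore lags true onset by up to one cadence.
* **event**: one record per plant-year holding the exact onset day; a
  seeded fraction instead carries an agricultural code (crop-harvest-style
  records that the mapping stage must skip).

Every emitted record is accounted for in the :class:`TruthLedger`, so tests
can check conservation and onset recovery exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import _round_tenth
from .errors import ParameterError
from .harmonize import EVENT_COLUMNS, STATUS_COLUMNS

#: source codes the default mapping table understands
DEFAULT_STATUS_CODE = "true_leaves"
DEFAULT_EVENT_CODE = "BBCH11"
AGRICULTURAL_EVENT_CODE = "BBCH99"

LEDGER_COLUMNS = (
    "subject_id",
    "genus",
    "species",
    "year",
    "latitude",
    "longitude",
    "cell_lat",
    "cell_lon",
    "onset_doy",
    "senescence_doy",
)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated campaign.

    Defaults describe a weekly-visited deciduous-leafing campaign on a
    European-style latitudinal gradient: onset near day 120 at 40°N rising
    by 2.5 days per degree, 5-day onset noise, a 120-day green season.
    """

    seed: int = 0
    n_plants: int = 200
    genera: tuple[str, ...] = ("Acer",)
    species: str = ""
    lat_range: tuple[float, float] = (40.0, 60.0)
    lon_range: tuple[float, float] = (-5.0, 25.0)
    years: tuple[int, ...] = tuple(range(2000, 2010))
    onset_intercept: float = 20.0   # DOY at latitude 0 (extrapolated)
    onset_slope: float = 2.5        # days per degree latitude
    onset_sd: float = 5.0           # days
    season_length: int = 120        # days the structure stays visible
    status_cadence: int = 7         # days between status visits
    networks: tuple[str, ...] = ("status", "event")
    fraction_agricultural: float = 0.05
    status_code: str = DEFAULT_STATUS_CODE
    event_code: str = DEFAULT_EVENT_CODE

    def __post_init__(self):
        if self.n_plants < 1:
            raise ParameterError("n_plants must be >= 1")
        if self.onset_sd < 0:
            raise ParameterError("onset_sd must be >= 0")
        if self.status_cadence < 1:
            raise ParameterError("status_cadence must be >= 1")
        if not 0.0 <= self.fraction_agricultural <= 1.0:
            raise ParameterError("fraction_agricultural must be in [0, 1]")
        if 366 - self.season_length < 1:
            raise ParameterError(
                f"season_length {self.season_length} leaves no feasible onset window"
            )
        for network in self.networks:
            if network not in ("status", "event"):
                raise ParameterError(f"unknown network {network!r}")


@dataclass
class TruthLedger:
    """Ground truth per plant-year, updated as records are emitted."""

    table: pd.DataFrame
    params: SimulationParams
    expected_status_rows: pd.Series | None = field(default=None, repr=False)
    event_agricultural: pd.Series | None = field(default=None, repr=False)

    def true_median_onset(self, years: tuple[int, int] | None = None) -> float:
        t = self.table
        if years is not None:
            t = t[(t["year"] >= years[0]) & (t["year"] <= years[1])]
        return float(np.median(t["onset_doy"]))


def simulate_plants(params: SimulationParams) -> TruthLedger:
    """Draw plant locations and per-plant-year onsets.

    Latitudes and longitudes are uniform on their ranges; onsets are normal
    around the latitudinal cline, truncated (by clipping — the window is
    many sigma wide under any sane parameterization) to
    ``[1, 366 - season_length]`` and rounded to whole days.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_plants
    lats = rng.uniform(*params.lat_range, size=n)
    lons = rng.uniform(*params.lon_range, size=n)
    genera = [params.genera[i % len(params.genera)] for i in range(n)]
    width = len(str(n))

    rows = []
    hi = 366 - params.season_length
    for year in params.years:
        means = params.onset_intercept + params.onset_slope * lats
        if params.onset_sd > 0:
            onsets = rng.normal(means, params.onset_sd)
        else:
            onsets = means.copy()
        onsets = np.clip(np.rint(onsets), 1, hi).astype(int)
        for i in range(n):
            rows.append(
                (
                    f"plant_{i + 1:0{width}d}",
                    genera[i],
                    params.species,
                    int(year),
                    float(lats[i]),
                    float(lons[i]),
                    _round_tenth(float(lats[i])),
                    _round_tenth(float(lons[i])),
                    int(onsets[i]),
                    int(onsets[i]) + params.season_length,
                )
            )
    table = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    return TruthLedger(table=table, params=params)


def _year_length(year: int) -> int:
    return 366 if (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)) else 365


def emit_status_records(
    ledger: TruthLedger, params: SimulationParams, path: str | Path | None = None
) -> pd.DataFrame:
    """Emit one status record per visit (visits on days 1, 1+cadence, ...).

    "yes" whenever the visit day falls in ``[onset, senescence)``, with a
    (k, k+10) count window where k grows with days since onset; "no"
    otherwise.  Updates the ledger's expected per-plant-year row counts.
    """
    if "status" not in params.networks:
        raise ParameterError("status network not enabled in params")
    records = []
    expected = []
    idx = 0
    for row in ledger.table.itertuples(index=False):
        visits = range(1, _year_length(row.year) + 1, params.status_cadence)
        n_rows = 0
        for doy in visits:
            idx += 1
            in_season = row.onset_doy <= doy < row.senescence_doy
            if in_season and params.season_length > 0:
                k = (doy - row.onset_doy) + 1
                status, lower, upper = "yes", k, k + 10
            else:
                status, lower, upper = "no", "", ""
            date = pd.Timestamp(year=row.year, month=1, day=1) + pd.Timedelta(
                days=doy - 1
            )
            records.append(
                (
                    f"S{idx:07d}",
                    row.subject_id,
                    row.genus,
                    row.species,
                    row.latitude,
                    row.longitude,
                    date.date().isoformat(),
                    params.status_code,
                    status,
                    lower,
                    upper,
                )
            )
            n_rows += 1
        expected.append(n_rows)
    df = pd.DataFrame(records, columns=STATUS_COLUMNS)
    ledger.expected_status_rows = pd.Series(expected, index=ledger.table.index)
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    return df


def emit_event_records(
    ledger: TruthLedger, params: SimulationParams, path: str | Path | None = None
) -> pd.DataFrame:
    """Emit one event record per plant-year at the true onset day.

    A seeded ``fraction_agricultural`` of records carry the agricultural
    code instead of the phenological one; the ledger marks exactly which.
    """
    if "event" not in params.networks:
        raise ParameterError("event network not enabled in params")
    rng = np.random.default_rng(params.seed + 1)
    n = len(ledger.table)
    agricultural = rng.random(n) < params.fraction_agricultural
    records = []
    for idx, (row, is_agri) in enumerate(
        zip(ledger.table.itertuples(index=False), agricultural), start=1
    ):
        code = AGRICULTURAL_EVENT_CODE if is_agri else params.event_code
        records.append(
            (
                f"E{idx:07d}",
                row.subject_id,
                row.genus,
                row.species,
                row.latitude,
                row.longitude,
                row.year,
                code,
                row.onset_doy,
            )
        )
    df = pd.DataFrame(records, columns=EVENT_COLUMNS)
    ledger.event_agricultural = pd.Series(agricultural, index=ledger.table.index)
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    return df


def simulate_to_dir(params: SimulationParams, out_dir: str | Path) -> dict:
    """Run the generator end to end, writing CSVs and the ledger.

    Returns a small manifest of written paths and counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ledger = simulate_plants(params)
    manifest: dict = {"n_plant_years": len(ledger.table)}
    if "status" in params.networks:
        status_path = out_dir / "status_records.csv"
        df = emit_status_records(ledger, params, status_path)
        manifest["status_path"] = str(status_path)
        manifest["n_status_records"] = len(df)
    if "event" in params.networks:
        event_path = out_dir / "event_records.csv"
        df = emit_event_records(ledger, params, event_path)
        manifest["event_path"] = str(event_path)
        manifest["n_event_records"] = len(df)
        manifest["n_agricultural"] = int(ledger.event_agricultural.sum())
    ledger_path = out_dir / "truth_ledger.csv"
    ledger_out = ledger.table.copy()
    if ledger.expected_status_rows is not None:
        ledger_out["expected_status_rows"] = ledger.expected_status_rows
    if ledger.event_agricultural is not None:
        ledger_out["event_agricultural"] = ledger.event_agricultural
    ledger_out.to_csv(ledger_path, index=False, lineterminator="\n")
    manifest["ledger_path"] = str(ledger_path)
    return manifest


def params_from_dict(config: dict) -> SimulationParams:
    """Build params from a plain dict (e.g. parsed YAML/JSON config)."""
    kwargs = dict(config)
    for key in ("genera", "years", "networks"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    for key in ("lat_range", "lon_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(float(v) for v in kwargs[key])
    return SimulationParams(**kwargs)
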