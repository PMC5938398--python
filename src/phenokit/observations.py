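"""Plant subjects, observing events, and range-valued measurement data.

A phenology observation is modeled as one observing event on one plant
subject (an individual plant or a local population), dated to the day and
producing one measurement datum per trait: a count or percentage *range*
``[lower, upper]`` so that observer uncertainty ("between 10 and 20 unfolded
leaves") is first-class.  Counts may be unbounded above (``upper=None``),
which encodes "at least ``lower``" — the natural reading of a status-network
"yes" with no intensity reported.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path

from .catalog import TraitCatalog
from .errors import RangeError

COUNT = "count"
PERCENT = "percent"
VALUE_KINDS = (COUNT, PERCENT)
SOURCES = ("status_network", "event_network", "other")

#: subject-id prefix marking station-scoped (population) subjects
STATION_PREFIX = "station:"


@dataclass(frozen=True)
class PlantSubject:
    """An observed plant or local plant population with a fixed location."""

    subject_id: str
    taxon_genus: str
    taxon_species: str = ""
    latitude: float | None = None
    longitude: float | None = None
    subject_kind: str = "individual"  # individual | population

    def __post_init__(self):
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise RangeError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise RangeError(f"longitude {self.longitude} outside [-180, 180]")

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass(frozen=True)
class MeasurementDatum:
    """A count or percentage range measuring one presence trait.

    ``upper=None`` means "unbounded above" and is only valid for counts.
    """

    trait: str
    value_kind: str
    lower: float
    upper: float | None

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise RangeError(f"value_kind must be count|percent, got {self.value_kind!r}")
        if self.lower < 0:
            raise RangeError(f"negative lower bound {self.lower}")
        if self.upper is not None:
            if self.upper < 0:
                raise RangeError(f"negative upper bound {self.upper}")
            if self.lower > self.upper:
                raise RangeError(f"lower {self.lower} > upper {self.upper}")
        if self.value_kind == COUNT:
            for name, value in (("lower", self.lower), ("upper", self.upper)):
                if value is not None and not float(value).is_integer():
                    raise RangeError(f"count {name} bound {value} is not an integer")
        else:
            if self.upper is None:
                raise RangeError("percent measurements cannot be unbounded")
            if self.upper > 100 or self.lower > 100:
                raise RangeError(
                    f"percent range [{self.lower}, {self.upper}] outside [0, 100]"
                )


@dataclass(frozen=True)
class Observation:
    """One observing event: a subject, a date, and its trait measurements."""

    observation_id: str
    subject: str
    date: dt.date
    measurements: tuple[MeasurementDatum, ...]
    source: str = "other"
    source_record_id: str = ""

    def __post_init__(self):
        if not isinstance(self.measurements, tuple):
            object.__setattr__(self, "measurements", tuple(self.measurements))


def make_measurement(
    trait: str,
    value_kind: str,
    lower: float,
    upper: float | None,
    catalog: TraitCatalog | None = None,
) -> MeasurementDatum:
    """Build a validated measurement datum.

    If a catalog is given, the trait id must resolve in it.  Count bounds
    are kept exactly as integers (no silent coercion through floats).
    """
    if catalog is not None and trait not in catalog.traits:
        from .errors import UnknownTermError

        raise UnknownTermError(trait)
    if value_kind == COUNT:
        lower = int(lower) if float(lower).is_integer() else lower
        if upper is not None and float(upper).is_integer():
            upper = int(upper)
    return MeasurementDatum(trait, value_kind, lower, upper)


@dataclass(frozen=True)
class ObservationProblem:
    """One validation finding; ``severity`` is ``error`` or ``warning``."""

    observation_id: str
    severity: str
    message: str


def validate_observation(
    obs: Observation,
    catalog: TraitCatalog,
    subject: PlantSubject | None = None,
) -> list[ObservationProblem]:
    """Collect invariant violations for one observation (never raises).

    Missing subject coordinates are a warning, not an error: such records
    are valid but will be excluded from spatial analyses.
    """
    problems: list[ObservationProblem] = []
    if not obs.measurements:
        problems.append(
            ObservationProblem(obs.observation_id, "error", "no measurements")
        )
    seen_traits: set[str] = set()
    for datum in obs.measurements:
        if datum.trait in seen_traits:
            problems.append(
                ObservationProblem(
                    obs.observation_id, "error", f"trait {datum.trait!r} measured twice"
                )
            )
        seen_traits.add(datum.trait)
        if datum.trait not in catalog.traits:
            problems.append(
                ObservationProblem(
                    obs.observation_id, "error", f"unknown trait {datum.trait!r}"
                )
            )
    if obs.source not in SOURCES:
        problems.append(
            ObservationProblem(obs.observation_id, "error", f"unknown source {obs.source!r}")
        )
    if subject is not None and not subject.has_coordinates:
        problems.append(
            ObservationProblem(
                obs.observation_id, "warning", "subject has no coordinates"
            )
        )
    return problems


# ---------------------------------------------------------------------------
# Observation CSV dialect (one measurement per row, grouped by observation)

OBSERVATION_COLUMNS = (
    "observation_id",
    "subject_id",
    "genus",
    "species",
    "latitude",
    "longitude",
    "date",
    "trait_id",
    "value_kind",
    "lower",
    "upper",
    "source",
    "source_record_id",
)


def _fmt_bound(value: float | None) -> str:
    if value is None:
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def _fmt_coord(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_observations_csv(
    observations: list[Observation],
    subjects: dict[str, PlantSubject],
    path: str | Path,
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(OBSERVATION_COLUMNS)
        for obs in observations:
            subject = subjects[obs.subject]
            for datum in obs.measurements:
                writer.writerow(
                    (
                        obs.observation_id,
                        subject.subject_id,
                        subject.taxon_genus,
                        subject.taxon_species,
                        _fmt_coord(subject.latitude),
                        _fmt_coord(subject.longitude),
                        obs.date.isoformat(),
                        datum.trait,
                        datum.value_kind,
                        _fmt_bound(datum.lower),
                        _fmt_bound(datum.upper),
                        obs.source,
                        obs.source_record_id,
                    )
                )


def _parse_bound(text: str, value_kind: str) -> float | None:
    text = text.strip()
    if text == "":
        return None
    value = float(text)
    if value_kind == COUNT and value.is_integer():
        return int(value)
    return value


def read_observations_csv(
    path: str | Path,
) -> tuple[list[Observation], dict[str, PlantSubject]]:
    """Read the observation CSV dialect back into model objects.

    Rows sharing an ``observation_id`` are grouped into one observation (in
    file order); subjects are deduplicated by id.  Station-prefixed subject
    ids are read back as populations.
    """
    observations: list[Observation] = []
    subjects: dict[str, PlantSubject] = {}
    grouped: dict[str, dict] = {}
    order: list[str] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(OBSERVATION_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            from .errors import SchemaError

            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            oid = row["observation_id"]
            sid = row["subject_id"]
            if sid not in subjects:
                lat = row["latitude"].strip()
                lon = row["longitude"].strip()
                subjects[sid] = PlantSubject(
                    subject_id=sid,
                    taxon_genus=row["genus"],
                    taxon_species=row["species"],
                    latitude=float(lat) if lat else None,
                    longitude=float(lon) if lon else None,
                    subject_kind="population" if sid.startswith(STATION_PREFIX) else "individual",
                )
            kind = row["value_kind"]
            lower = _parse_bound(row["lower"], kind)
            if lower is None:
                lower = 0
            datum = MeasurementDatum(
                row["trait_id"], kind, lower, _parse_bound(row["upper"], kind)
            )
            if oid not in grouped:
                grouped[oid] = {
                    "subject": sid,
                    "date": dt.date.fromisoformat(row["date"]),
                    "source": row["source"],
                    "source_record_id": row["source_record_id"],
                    "measurements": [],
                }
                order.append(oid)
            grouped[oid]["measurements"].append(datum)
    for oid in order:
        info = grouped[oid]
        observations.append(
            Observation(
                observation_id=oid,
                subject=info["subject"],
                date=info["date"],
                measurements=tuple(info["measurements"]),
                source=info["source"],
                source_record_id=info["source_record_id"],
            )
        )
    return observations, subjects
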