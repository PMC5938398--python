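"""Four-stage integration pipeline for heterogeneous phenology sources.

Status-based networks (per-visit yes/no records with optional intensity
ranges, as in North American monitoring) and event-based networks (a single
day-of-year per phenological event, as in European BBCH-coded monitoring)
are harmonized into one flat table:

1. **normalize** — parse each source dialect's CSV, collecting unparseable
   rows as rejects (with line numbers), never aborting;
2. **map** — translate source phenophase/event codes to catalog traits via a
   user-supplied mapping table, turning each record into a model
   observation (agricultural and unmapped codes become skip notices);
3. **reason** — materialize the present/absent class closure for every
   observation;
4. **export** — write one harmonized row per observation, with its inferred
   classes, plus a machine-readable pipeline report.

Conservation holds on every run: input rows = harmonized + rejects + skips
(+ conflicts, which are structurally zero for single-measurement records).
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalog import TraitCatalog
from .errors import SchemaError, UnresolvedReferenceError
from .observations import (
    COUNT,
    STATION_PREFIX,
    Observation,
    PlantSubject,
    make_measurement,
)
from .reasoner import check_consistency, materialize

STATUS_DIALECT = "status"
EVENT_DIALECT = "event"

STATUS_COLUMNS = (
    "record_id",
    "plant_id",
    "genus",
    "species",
    "latitude",
    "longitude",
    "date",
    "phenophase_code",
    "status",
    "intensity_lower",
    "intensity_upper",
)

EVENT_COLUMNS = (
    "record_id",
    "plant_or_station_id",
    "genus",
    "species",
    "latitude",
    "longitude",
    "year",
    "event_code",
    "day_of_year",
)

HARMONIZED_COLUMNS = (
    "observation_id",
    "subject_id",
    "genus",
    "species",
    "latitude",
    "longitude",
    "date",
    "inferred_classes",
    "source",
)

VALUE_RULES = ("status_to_range", "event_onset", "excluded_agricultural")


@dataclass(frozen=True)
class StatusRecord:
    record_id: str
    plant_id: str
    genus: str
    species: str
    latitude: float
    longitude: float
    date: dt.date
    phenophase_code: str
    status: str  # yes | no | unknown
    intensity_lower: float | None = None
    intensity_upper: float | None = None


@dataclass(frozen=True)
class EventRecord:
    record_id: str
    plant_or_station_id: str
    genus: str
    species: str
    latitude: float
    longitude: float
    year: int
    event_code: str
    day_of_year: int


@dataclass(frozen=True)
class Reject:
    line_no: int
    reason: str
    raw: str = ""


@dataclass
class ParseResult:
    records: list
    rejects: list[Reject] = field(default_factory=list)


@dataclass(frozen=True)
class MappingRule:
    source_dialect: str
    source_code: str
    trait_id: str
    value_rule: str
    value_kind: str = COUNT


class MappingTable:
    """Translates (source dialect, source code) pairs to catalog traits."""

    def __init__(self, rules: list[MappingRule]):
        self._rules: dict[tuple[str, str], MappingRule] = {}
        for rule in rules:
            key = (rule.source_dialect, rule.source_code)
            if key in self._rules:
                raise UnresolvedReferenceError(f"duplicate mapping for {key}")
            if rule.value_rule not in VALUE_RULES:
                raise UnresolvedReferenceError(
                    f"unknown value_rule {rule.value_rule!r} for {key}"
                )
            self._rules[key] = rule

    def lookup(self, dialect: str, code: str) -> MappingRule | None:
        return self._rules.get((dialect, code))

    def validate(self, catalog: TraitCatalog) -> list[str]:
        """Trait ids must resolve unless the rule excludes the record."""
        issues = []
        for (dialect, code), rule in sorted(self._rules.items()):
            if rule.value_rule != "excluded_agricultural" and rule.trait_id not in catalog.traits:
                issues.append(f"{dialect}:{code}: unknown trait {rule.trait_id!r}")
        return issues

    @classmethod
    def from_csv(cls, path: str | Path) -> "MappingTable":
        rules = []
        with Path(path).open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"source_dialect", "source_code", "trait_id", "value_rule"}
            missing = required - set(reader.fieldnames or ())
            if missing:
                raise SchemaError(f"{path}: missing columns {sorted(missing)}")
            for row in reader:
                rules.append(
                    MappingRule(
                        source_dialect=row["source_dialect"].strip(),
                        source_code=row["source_code"].strip(),
                        trait_id=(row["trait_id"] or "").strip(),
                        value_rule=row["value_rule"].strip(),
                        value_kind=(row.get("value_kind") or "").strip() or COUNT,
                    )
                )
        return cls(rules)


def default_mapping_path() -> Path:
    return Path(__file__).parent / "data" / "default_mapping.csv"


# ---------------------------------------------------------------------------
# Stage 1: dialect readers

def _check_header(fieldnames, required, path) -> None:
    missing = set(required) - set(fieldnames or ())
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def _parse_coord(text: str, lo: float, hi: float, name: str) -> float:
    value = float(text)
    if not lo <= value <= hi:
        raise ValueError(f"{name} {value} outside [{lo}, {hi}]")
    return value


def read_status_csv(path: str | Path) -> ParseResult:
    """Parse a status-dialect CSV; bad rows become rejects, not errors."""
    result = ParseResult(records=[])
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, STATUS_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            try:
                status = row["status"].strip().lower()
                if status not in ("yes", "no", "unknown"):
                    raise ValueError(f"bad status {row['status']!r}")
                lower_txt = (row["intensity_lower"] or "").strip()
                upper_txt = (row["intensity_upper"] or "").strip()
                lower = float(lower_txt) if lower_txt else None
                upper = float(upper_txt) if upper_txt else None
                if status == "unknown" and (lower is not None or upper is not None):
                    raise ValueError("unknown status with intensity values")
                record = StatusRecord(
                    record_id=row["record_id"].strip(),
                    plant_id=row["plant_id"].strip(),
                    genus=row["genus"].strip(),
                    species=row["species"].strip(),
                    latitude=_parse_coord(row["latitude"], -90, 90, "latitude"),
                    longitude=_parse_coord(row["longitude"], -180, 180, "longitude"),
                    date=dt.date.fromisoformat(row["date"].strip()),
                    phenophase_code=row["phenophase_code"].strip(),
                    status=status,
                    intensity_lower=lower,
                    intensity_upper=upper,
                )
            except (ValueError, KeyError, AttributeError) as exc:
                result.rejects.append(Reject(line_no, str(exc)))
                continue
            result.records.append(record)
    return result


def _year_length(year: int) -> int:
    return 366 if (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)) else 365


def read_event_csv(path: str | Path) -> ParseResult:
    """Parse an event-dialect CSV; bad rows become rejects, not errors."""
    result = ParseResult(records=[])
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, EVENT_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            try:
                year = int(row["year"])
                doy = int(row["day_of_year"])
                if not 1 <= doy <= _year_length(year):
                    raise ValueError(f"day_of_year {doy} outside year {year}")
                record = EventRecord(
                    record_id=row["record_id"].strip(),
                    plant_or_station_id=row["plant_or_station_id"].strip(),
                    genus=row["genus"].strip(),
                    species=row["species"].strip(),
                    latitude=_parse_coord(row["latitude"], -90, 90, "latitude"),
                    longitude=_parse_coord(row["longitude"], -180, 180, "longitude"),
                    year=year,
                    event_code=row["event_code"].strip(),
                    day_of_year=doy,
                )
            except (ValueError, KeyError, AttributeError) as exc:
                result.rejects.append(Reject(line_no, str(exc)))
                continue
            result.records.append(record)
    return result


# ---------------------------------------------------------------------------
# Stage 2: mapping to the data model

@dataclass(frozen=True)
class MapResult:
    """Either a mapped observation (+ subject) or a skip notice."""

    record_id: str
    observation: Observation | None = None
    subject: PlantSubject | None = None
    skip_reason: str | None = None

    @property
    def mapped(self) -> bool:
        return self.observation is not None


def map_record(
    record: StatusRecord | EventRecord,
    mapping: MappingTable,
    catalog: TraitCatalog,
) -> MapResult:
    """Translate one source record into a model observation.

    Status semantics: "yes" with an intensity range becomes that range;
    "yes" without one becomes the unbounded count [1, +inf) (presence
    asserted, magnitude unknown); "no" becomes the exact zero range [0, 0];
    "unknown" is skipped.  Event records assert presence (count [1, +inf))
    on the event date only.  Unmapped and agricultural codes yield skip
    notices, never exceptions.
    """
    if isinstance(record, StatusRecord):
        dialect, code = STATUS_DIALECT, record.phenophase_code
    else:
        dialect, code = EVENT_DIALECT, record.event_code
    rule = mapping.lookup(dialect, code)
    if rule is None:
        return MapResult(record.record_id, skip_reason="unmapped")
    if rule.value_rule == "excluded_agricultural":
        return MapResult(record.record_id, skip_reason="agricultural")

    if isinstance(record, StatusRecord):
        if record.status == "unknown":
            return MapResult(record.record_id, skip_reason="unknown_status")
        if record.status == "no":
            datum = make_measurement(rule.trait_id, COUNT, 0, 0, catalog)
        elif record.intensity_lower is not None or record.intensity_upper is not None:
            lower = record.intensity_lower if record.intensity_lower is not None else 0
            datum = make_measurement(
                rule.trait_id, rule.value_kind, lower, record.intensity_upper, catalog
            )
        else:
            datum = make_measurement(rule.trait_id, COUNT, 1, None, catalog)
        subject = PlantSubject(
            subject_id=record.plant_id,
            taxon_genus=record.genus,
            taxon_species=record.species,
            latitude=record.latitude,
            longitude=record.longitude,
            subject_kind="population"
            if record.plant_id.startswith(STATION_PREFIX)
            else "individual",
        )
        obs = Observation(
            observation_id=f"{STATUS_DIALECT}:{record.record_id}",
            subject=subject.subject_id,
            date=record.date,
            measurements=(datum,),
            source="status_network",
            source_record_id=record.record_id,
        )
        return MapResult(record.record_id, observation=obs, subject=subject)

    # event record: one presence assertion on the event date
    date = dt.date(record.year, 1, 1) + dt.timedelta(days=record.day_of_year - 1)
    datum = make_measurement(rule.trait_id, COUNT, 1, None, catalog)
    sid = record.plant_or_station_id
    subject = PlantSubject(
        subject_id=sid,
        taxon_genus=record.genus,
        taxon_species=record.species,
        latitude=record.latitude,
        longitude=record.longitude,
        subject_kind="population" if sid.startswith(STATION_PREFIX) else "individual",
    )
    obs = Observation(
        observation_id=f"{EVENT_DIALECT}:{record.record_id}",
        subject=sid,
        date=date,
        measurements=(datum,),
        source="event_network",
        source_record_id=record.record_id,
    )
    return MapResult(record.record_id, observation=obs, subject=subject)


# ---------------------------------------------------------------------------
# Stages 3-4: reasoning + tabular export

def run_pipeline(
    sources: list[tuple[str, str | Path]],
    mapping: MappingTable,
    catalog: TraitCatalog,
    out_path: str | Path,
) -> dict:
    """Run normalize → map → reason → export over a list of sources.

    ``sources`` is a list of ``(dialect, path)`` pairs with dialect
    ``status`` or ``event``.  Writes the harmonized CSV to ``out_path`` and
    returns a JSON-serializable report with per-source counts.  Output row
    order is source order, then record_id, so identical inputs give
    byte-identical output.
    """
    issues = mapping.validate(catalog)
    if issues:
        raise UnresolvedReferenceError("; ".join(issues))

    report: dict = {"sources": [], "totals": {}}
    all_rows: list[dict] = []
    totals = {"read": 0, "rejected": 0, "skipped": 0, "harmonized": 0, "conflicts": 0}

    for dialect, path in sources:
        if dialect == STATUS_DIALECT:
            parsed = read_status_csv(path)
        elif dialect == EVENT_DIALECT:
            parsed = read_event_csv(path)
        else:
            raise SchemaError(f"unknown dialect {dialect!r}")

        skip_counts: dict[str, int] = {}
        mapped: list[MapResult] = []
        for record in sorted(parsed.records, key=lambda r: r.record_id):
            result = map_record(record, mapping, catalog)
            if result.mapped:
                mapped.append(result)
            else:
                skip_counts[result.skip_reason] = skip_counts.get(result.skip_reason, 0) + 1

        observations = [m.observation for m in mapped]
        subjects = {m.subject.subject_id: m.subject for m in mapped}
        inferred = materialize(observations, catalog)
        conflicts = check_consistency(inferred)
        conflicted_ids = {c.observation_id for c in conflicts}

        n_source_rows = 0
        for obs, inf in zip(observations, inferred):
            if obs.observation_id in conflicted_ids:
                continue
            subject = subjects[obs.subject]
            all_rows.append(
                {
                    "observation_id": obs.observation_id,
                    "subject_id": subject.subject_id,
                    "genus": subject.taxon_genus,
                    "species": subject.taxon_species,
                    "latitude": subject.latitude,
                    "longitude": subject.longitude,
                    "date": obs.date.isoformat(),
                    "inferred_classes": "|".join(sorted(inf.inferred_classes)),
                    "source": obs.source,
                }
            )
            n_source_rows += 1

        n_read = len(parsed.records) + len(parsed.rejects)
        source_report = {
            "dialect": dialect,
            "path": str(path),
            "read": n_read,
            "rejected": len(parsed.rejects),
            "reject_reasons": [
                {"line": r.line_no, "reason": r.reason} for r in parsed.rejects
            ],
            "skipped": skip_counts,
            "conflicts": len(conflicts),
            "harmonized": n_source_rows,
        }
        report["sources"].append(source_report)
        totals["read"] += n_read
        totals["rejected"] += len(parsed.rejects)
        totals["skipped"] += sum(skip_counts.values())
        totals["conflicts"] += len(conflicts)
        totals["harmonized"] += n_source_rows

    with Path(out_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=HARMONIZED_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for row in all_rows:
            out = dict(row)
            out["latitude"] = repr(float(row["latitude"]))
            out["longitude"] = repr(float(row["longitude"]))
            writer.writerow(out)

    report["totals"] = totals
    for source_report in report["sources"]:
        source_report["share_of_rows"] = (
            source_report["harmonized"] / totals["harmonized"]
            if totals["harmonized"]
            else 0.0
        )
    return report


def load_harmonized(path: str | Path) -> pd.DataFrame:
    """Load a harmonized CSV with ``inferred_classes`` parsed to frozensets
    and ``date`` parsed to datetime — the in-memory form the analyses use."""
    df = pd.read_csv(
        path,
        dtype={"observation_id": str, "subject_id": str, "genus": str, "species": str},
        keep_default_na=False,
    )
    df["latitude"] = pd.to_numeric(df["latitude"])
    df["longitude"] = pd.to_numeric(df["longitude"])
    df["date"] = pd.to_datetime(df["date"])
    df["inferred_classes"] = df["inferred_classes"].map(
        lambda s: frozenset(s.split("|")) if s else frozenset()
    )
    return df


def write_report(report: dict, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
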