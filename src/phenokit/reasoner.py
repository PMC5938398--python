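"""Materialize present/absent trait classes from measurement ranges.

The classification rule mirrors how a reasoner treats count/percentage
axioms on presence traits:

* a count with ``lower >= 1``, or a percentage with ``lower > 0``, proves
  the structure is there — the trait's *present* class holds, together with
  every superclass in the derived hierarchy ("one or more unfolded true
  leaves" entails "unfolded true leaves present" and "true leaves present");
* an ``upper == 0`` range proves it is not — the *absent* class holds, plus
  its (inverted-hierarchy) superclasses;
* a range straddling zero (``lower == 0 < upper``) proves neither, and
  yields no assertions at all.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import ABSENT, PRESENT, TraitCatalog, presence_superclasses
from .errors import UnknownTermError
from .observations import COUNT, MeasurementDatum, Observation

INDETERMINATE = "indeterminate"
CONFLICT = "conflict"


@dataclass(frozen=True)
class InferredTraitSet:
    """All classes entailed by one observation's measurements.

    ``asserted`` maps each measured trait to its polarity classification
    (``present``/``absent``/``indeterminate``, or ``conflict`` when
    duplicate measurements of a trait disagree).  ``inferred_classes`` is
    closed under the presence-class hierarchy.
    """

    observation_id: str
    asserted: dict[str, str]
    inferred_classes: frozenset[str]
    inconsistent_traits: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConflictRecord:
    """One (observation, trait) pair inferred both present and absent."""

    observation_id: str
    trait: str


def classify_polarity(datum: MeasurementDatum) -> str:
    """Classify a measurement range as present, absent or indeterminate."""
    if datum.value_kind == COUNT:
        if datum.lower >= 1:
            return PRESENT
    elif datum.lower > 0:
        return PRESENT
    if datum.upper == 0:
        return ABSENT
    return INDETERMINATE


def infer_types(datum: MeasurementDatum, catalog: TraitCatalog) -> set[str]:
    """Presence classes entailed by one datum: polarity class plus closure.

    Returns the empty set for indeterminate ranges.  Requires presence
    classes to have been derived on the catalog.
    """
    if datum.trait not in catalog.traits:
        raise UnknownTermError(datum.trait)
    polarity = classify_polarity(datum)
    if polarity == INDETERMINATE:
        return set()
    cls = catalog.presence_class_for(datum.trait, polarity)
    return set(presence_superclasses(cls.class_id, catalog))


def materialize(
    observations: list[Observation],
    catalog: TraitCatalog,
    problems: list[dict] | None = None,
) -> list[InferredTraitSet]:
    """Eagerly compute the inferred class set for every observation.

    One :class:`InferredTraitSet` per input observation, in input order;
    observations whose measurements entail nothing still appear (with an
    empty set).  Per-record problems (unknown traits) are appended to
    ``problems`` when a list is supplied, never raised.
    """
    results: list[InferredTraitSet] = []
    for obs in observations:
        asserted: dict[str, str] = {}
        classes: set[str] = set()
        inconsistent: list[str] = []
        for datum in obs.measurements:
            if datum.trait not in catalog.traits:
                if problems is not None:
                    problems.append(
                        {
                            "observation_id": obs.observation_id,
                            "reason": "unknown_trait",
                            "trait": datum.trait,
                        }
                    )
                continue
            polarity = classify_polarity(datum)
            previous = asserted.get(datum.trait)
            if previous is not None and previous != polarity and {
                previous,
                polarity,
            } == {PRESENT, ABSENT}:
                asserted[datum.trait] = CONFLICT
                inconsistent.append(datum.trait)
            elif previous is None or previous == INDETERMINATE:
                asserted[datum.trait] = polarity
            classes |= infer_types(datum, catalog)
        results.append(
            InferredTraitSet(
                observation_id=obs.observation_id,
                asserted=asserted,
                inferred_classes=frozenset(classes),
                inconsistent_traits=tuple(sorted(set(inconsistent))),
            )
        )
    return results


def check_consistency(inferred: list[InferredTraitSet]) -> list[ConflictRecord]:
    """One conflict record per (observation, trait) with both polarities."""
    conflicts: list[ConflictRecord] = []
    for item in inferred:
        for trait in item.inconsistent_traits:
            conflicts.append(ConflictRecord(item.observation_id, trait))
        for trait, polarity in item.asserted.items():
            if polarity == CONFLICT and trait not in item.inconsistent_traits:
                conflicts.append(ConflictRecord(item.observation_id, trait))
    return conflicts


def write_inferred_csv(inferred: list[InferredTraitSet], path) -> None:
    """Write (observation_id, class_id) long-format CSV, rows sorted within
    each observation so output is diffable against expected-assertion files."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(("observation_id", "class_id"))
        for item in inferred:
            for cid in sorted(item.inferred_classes):
                writer.writerow((item.observation_id, cid))


def read_assertions_csv(path) -> set[tuple[str, str]]:
    """Read an (observation_id, class_id) assertion file as a set of pairs."""
    import csv
    from pathlib import Path

    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return {(row["observation_id"], row["class_id"]) for row in reader}
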