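"""Trait catalog: plant structures, phenological traits, and the derived
present/absent convenience-class hierarchies.

The catalog holds a graph of plant-structure terms (subclass and
visible-parthood links) and the phenological traits measured on them
("X presence" traits, measured by the count or percentage of structure X).
From that graph, :func:`derive_presence_classes` machine-derives two
qualitative convenience classes per trait — "Xs present" and "Xs absent" —
and the subsumption edges between them:

* structure subclass edge ``child ⊑ parent`` (same trait modality) yields
  ``present(child) ⊑ present(parent)`` and, inverted,
  ``absent(parent) ⊑ absent(child)``: a plant with dormant leaf buds has
  leaf buds, and a plant with no leaf buds at all has no dormant ones;
* parthood edge ``whole has-visible-part part`` yields
  ``present(whole) ⊑ present(part)`` and ``absent(part) ⊑ absent(whole)``
  (the contrapositive of the existential visibility requirement).

The absent-class hierarchy is therefore the exact mirror of the present-class
hierarchy with every edge reversed — the duality the tests assert.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

from .errors import (
    AlreadyDerivedError,
    CycleError,
    DuplicateTermError,
    UnknownTermError,
    UnresolvedReferenceError,
)

PRESENT = "present"
ABSENT = "absent"
MODALITIES = ("attached", "abscised")

#: words whose plural is irregular, used when labelling presence classes
_IRREGULAR_PLURALS = {"leaf": "leaves", "calyx": "calyces"}


@dataclass(frozen=True)
class StructureTerm:
    """An anatomical plant structure (leaf bud, true leaf, flower, ...)."""

    term_id: str
    label: str
    parents: frozenset[str] = frozenset()        # subclass links (child -> parents)
    visible_parts: frozenset[str] = frozenset()  # has-visible-part links


@dataclass(frozen=True)
class TraitTerm:
    """A presence trait, measured by the count/percentage of one structure.

    ``modality`` distinguishes structures still attached to the plant from
    abscised (dropped or removed) ones: "abscised leaf presence" counts
    leaves the plant has shed, so it must never mix with attached-leaf
    subsumption.
    """

    trait_id: str
    label: str
    structure: str
    modality: str = "attached"


@dataclass(frozen=True)
class PresenceClass:
    """A derived qualitative class: trait's structures present or absent.

    ``superclasses`` holds only the *direct* derived edges; use
    :func:`presence_superclasses` for the full closure.  These edges are
    machine-derived, never authored.
    """

    class_id: str
    label: str
    trait: str
    polarity: str  # PRESENT | ABSENT
    superclasses: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Violation:
    """One catalog-invariant violation found by :func:`validate_catalog`."""

    code: str
    subject: str
    message: str


@dataclass
class TraitCatalog:
    """The structure/trait graph plus (optionally) derived presence classes."""

    structures: dict[str, StructureTerm] = field(default_factory=dict)
    traits: dict[str, TraitTerm] = field(default_factory=dict)
    presence_classes: dict[str, PresenceClass] = field(default_factory=dict)

    @property
    def derived(self) -> bool:
        return bool(self.presence_classes)

    def presence_class_for(self, trait_id: str, polarity: str) -> PresenceClass:
        """The present- or absent-class of a trait."""
        if trait_id not in self.traits:
            raise UnknownTermError(trait_id)
        return self.presence_classes[presence_class_id(trait_id, polarity)]

    def presence_class_by_label(self, label: str) -> PresenceClass:
        for cls in self.presence_classes.values():
            if cls.label == label:
                return cls
        raise UnknownTermError(label)

    def trait_by_label(self, label: str) -> TraitTerm:
        for trait in self.traits.values():
            if trait.label == label:
                return trait
        raise UnknownTermError(label)


def presence_class_id(trait_id: str, polarity: str) -> str:
    """Deterministic id of the derived presence class of a trait."""
    if polarity not in (PRESENT, ABSENT):
        raise ValueError(f"polarity must be present|absent, got {polarity!r}")
    return f"{trait_id}:{polarity}"


def _pluralize(word: str) -> str:
    if word in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[word]
    if word.endswith(("s", "x", "z", "ch", "sh")):
        return word + "es"
    if word.endswith("y") and len(word) > 1 and word[-2] not in "aeiou":
        return word[:-1] + "ies"
    return word + "s"


def presence_class_label(trait_label: str, polarity: str) -> str:
    """Human label for a presence class, e.g. ``'true leaf presence'`` ->
    ``'true leaves present'`` / ``'true leaves absent'``."""
    base = trait_label
    if base.endswith(" presence"):
        base = base[: -len(" presence")]
    words = base.split(" ")
    words[-1] = _pluralize(words[-1])
    return " ".join(words) + " " + polarity


# ---------------------------------------------------------------------------
# Loading and validation

_CATALOG_COLUMNS = ("record_kind", "subject_id", "object_id", "label", "modality")


def load_catalog(path: str | Path) -> TraitCatalog:
    """Read a catalog TSV into a validated :class:`TraitCatalog`.

    The file is an edge list with columns
    ``record_kind, subject_id, object_id, label, modality`` where
    ``record_kind`` is one of ``structure`` (declares a structure term),
    ``subclass`` (subject ⊑ object between structures), ``part``
    (subject has-visible-part object) or ``trait`` (declares a trait
    measured by structure ``object_id``).  Row order never affects the
    result.  Presence classes are *not* derived here.

    Raises
    ------
    DuplicateTermError, UnresolvedReferenceError, CycleError
        On hard structural defects; use :func:`validate_catalog` to collect
        violations as data instead.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or reader.fieldnames[0] != "record_kind":
            raise UnresolvedReferenceError(
                f"{path}: missing catalog header (expected columns {_CATALOG_COLUMNS})"
            )
        rows = list(reader)

    structures: dict[str, dict] = {}
    traits: dict[str, TraitTerm] = {}
    subclass_edges: list[tuple[str, str]] = []
    part_edges: list[tuple[str, str]] = []

    for row in rows:
        kind = (row.get("record_kind") or "").strip()
        subj = (row.get("subject_id") or "").strip()
        obj = (row.get("object_id") or "").strip()
        label = (row.get("label") or "").strip()
        modality = (row.get("modality") or "").strip() or "attached"
        if kind == "structure":
            if subj in structures:
                raise DuplicateTermError(f"structure {subj!r} declared twice")
            structures[subj] = {"label": label or subj, "parents": set(), "parts": set()}
        elif kind == "subclass":
            subclass_edges.append((subj, obj))
        elif kind == "part":
            part_edges.append((subj, obj))
        elif kind == "trait":
            if subj in traits:
                raise DuplicateTermError(f"trait {subj!r} declared twice")
            if modality not in MODALITIES:
                raise UnresolvedReferenceError(
                    f"trait {subj!r}: unknown modality {modality!r}"
                )
            traits[subj] = TraitTerm(subj, label or subj, obj, modality)
        else:
            raise UnresolvedReferenceError(f"{path}: unknown record_kind {kind!r}")

    for child, parent in subclass_edges:
        for term in (child, parent):
            if term not in structures:
                raise UnresolvedReferenceError(
                    f"subclass edge {child!r} -> {parent!r}: {term!r} not declared"
                )
        structures[child]["parents"].add(parent)
    for whole, part in part_edges:
        for term in (whole, part):
            if term not in structures:
                raise UnresolvedReferenceError(
                    f"part edge {whole!r} -> {part!r}: {term!r} not declared"
                )
        structures[whole]["parts"].add(part)
    for trait in traits.values():
        if trait.structure not in structures:
            raise UnresolvedReferenceError(
                f"trait {trait.trait_id!r}: structure {trait.structure!r} not declared"
            )

    graph = nx.DiGraph()
    graph.add_nodes_from(structures)
    graph.add_edges_from((c, p) for c, p in subclass_edges)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise CycleError(f"subclass cycle: {' -> '.join(e[0] for e in cycle)}")

    catalog = TraitCatalog(
        structures={
            sid: StructureTerm(
                sid, info["label"], frozenset(info["parents"]), frozenset(info["parts"])
            )
            for sid, info in structures.items()
        },
        traits=traits,
    )
    return catalog


def validate_catalog(catalog: TraitCatalog) -> list[Violation]:
    """Collect every invariant violation in a catalog (never raises).

    Checks dangling references, subclass cycles, trait modality values, and
    (if derived) that each trait has exactly one presence class per polarity
    and presence superclass edges resolve.  An empty list means the catalog
    satisfies all type invariants.
    """
    violations: list[Violation] = []
    structures = catalog.structures

    for sid in sorted(structures):
        term = structures[sid]
        for ref in sorted(term.parents):
            if ref not in structures:
                violations.append(
                    Violation("dangling_parent", sid, f"parent {ref!r} not declared")
                )
        for ref in sorted(term.visible_parts):
            if ref not in structures:
                violations.append(
                    Violation("dangling_part", sid, f"part {ref!r} not declared")
                )

    graph = nx.DiGraph()
    graph.add_nodes_from(structures)
    for sid, term in structures.items():
        graph.add_edges_from((sid, p) for p in term.parents if p in structures)
    if not nx.is_directed_acyclic_graph(graph):
        for cycle in nx.simple_cycles(graph):
            violations.append(
                Violation("cycle", cycle[0], f"subclass cycle through {cycle}")
            )

    for tid in sorted(catalog.traits):
        trait = catalog.traits[tid]
        if trait.structure not in structures:
            violations.append(
                Violation(
                    "dangling_structure", tid, f"structure {trait.structure!r} not declared"
                )
            )
        if trait.modality not in MODALITIES:
            violations.append(
                Violation("bad_modality", tid, f"unknown modality {trait.modality!r}")
            )

    if catalog.derived:
        by_trait: dict[tuple[str, str], int] = {}
        for cls in catalog.presence_classes.values():
            by_trait[(cls.trait, cls.polarity)] = by_trait.get((cls.trait, cls.polarity), 0) + 1
            for sup in sorted(cls.superclasses):
                if sup not in catalog.presence_classes:
                    violations.append(
                        Violation(
                            "dangling_superclass", cls.class_id, f"superclass {sup!r} missing"
                        )
                    )
        for tid in sorted(catalog.traits):
            for pol in (PRESENT, ABSENT):
                n = by_trait.get((tid, pol), 0)
                if n != 1:
                    violations.append(
                        Violation(
                            "polarity_count", tid, f"{n} {pol}-classes (expected 1)"
                        )
                    )
    return violations


# ---------------------------------------------------------------------------
# Presence-class derivation

def derive_presence_classes(
    catalog: TraitCatalog, *, include_parthood: bool = True
) -> TraitCatalog:
    """Return a new catalog with the present/absent hierarchies materialized.

    For each trait two classes are created; superclass edges follow the
    subclass-inversion and parthood-contrapositive rules described in the
    module docstring.  Both rules apply only between traits of the same
    modality.  ``include_parthood=False`` disables the parthood rule, which
    is useful when a source catalog's parthood links are decorative rather
    than existential.
    """
    if catalog.derived:
        raise AlreadyDerivedError("presence classes already derived")

    # trait ids measuring each structure, per modality, in stable order
    measuring: dict[tuple[str, str], list[str]] = {}
    for tid in sorted(catalog.traits):
        trait = catalog.traits[tid]
        measuring.setdefault((trait.structure, trait.modality), []).append(tid)

    present_edges: set[tuple[str, str]] = set()  # (sub, super) among present classes

    def add_present_edge(sub_trait: str, super_trait: str) -> None:
        present_edges.add(
            (
                presence_class_id(sub_trait, PRESENT),
                presence_class_id(super_trait, PRESENT),
            )
        )

    for sid in sorted(catalog.structures):
        term = catalog.structures[sid]
        for modality in MODALITIES:
            child_traits = measuring.get((sid, modality), [])
            if not child_traits:
                continue
            for parent in sorted(term.parents):
                for pt in measuring.get((parent, modality), []):
                    for ct in child_traits:
                        add_present_edge(ct, pt)  # present(child) ⊑ present(parent)
            if include_parthood:
                for part in sorted(term.visible_parts):
                    for part_trait in measuring.get((part, modality), []):
                        for wt in child_traits:
                            add_present_edge(wt, part_trait)  # present(whole) ⊑ present(part)

    # absent edges are the polarity-flipped reverse of the present edges
    supers: dict[str, set[str]] = {}
    for sub, sup in present_edges:
        supers.setdefault(sub, set()).add(sup)
        a_sub = sup.replace(f":{PRESENT}", f":{ABSENT}")
        a_sup = sub.replace(f":{PRESENT}", f":{ABSENT}")
        supers.setdefault(a_sub, set()).add(a_sup)

    presence_classes: dict[str, PresenceClass] = {}
    for tid in sorted(catalog.traits):
        trait = catalog.traits[tid]
        for pol in (PRESENT, ABSENT):
            cid = presence_class_id(tid, pol)
            presence_classes[cid] = PresenceClass(
                class_id=cid,
                label=presence_class_label(trait.label, pol),
                trait=tid,
                polarity=pol,
                superclasses=frozenset(supers.get(cid, ())),
            )

    return replace(catalog, presence_classes=presence_classes)


def presence_superclasses(class_id: str, catalog: TraitCatalog) -> list[str]:
    """Reflexive-transitive superclass closure of a presence class.

    Breadth-first from the query class, ties broken by lexicographic
    class id, so output order is deterministic.
    """
    if class_id not in catalog.presence_classes:
        raise UnknownTermError(class_id)
    seen = {class_id}
    order = [class_id]
    queue = deque([class_id])
    while queue:
        current = queue.popleft()
        for sup in sorted(catalog.presence_classes[current].superclasses):
            if sup not in seen:
                seen.add(sup)
                order.append(sup)
                queue.append(sup)
    return order


def presence_edges(catalog: TraitCatalog, polarity: str | None = None) -> set[tuple[str, str]]:
    """All direct (subclass, superclass) presence edges, optionally one polarity."""
    edges = set()
    for cls in catalog.presence_classes.values():
        if polarity is not None and cls.polarity != polarity:
            continue
        for sup in cls.superclasses:
            edges.add((cls.class_id, sup))
    return edges


def export_presence_edges(catalog: TraitCatalog, path: str | Path) -> None:
    """Write the derived hierarchy as a TSV edge list for inspection."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("class_id", "superclass_id", "polarity"))
        for cid in sorted(catalog.presence_classes):
            cls = catalog.presence_classes[cid]
            for sup in sorted(cls.superclasses):
                writer.writerow((cid, sup, cls.polarity))


def default_catalog_path() -> Path:
    """Path of the shipped leaf-bud/leaf/flower/fruit/cone catalog subset."""
    return Path(__file__).parent / "data" / "ppo_subset_catalog.tsv"


def load_default_catalog(*, derive: bool = True) -> TraitCatalog:
    """Load (and by default derive) the shipped catalog subset."""
    catalog = load_catalog(default_catalog_path())
    return derive_presence_classes(catalog) if derive else catalog
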