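"""Shared fixtures: hand-built catalogs, random catalog generation, and
brute-force reachability oracles kept independent of the library's own
closure code."""

from pathlib import Path

import numpy as np
import pytest

from phenokit.catalog import (
    StructureTerm,
    TraitCatalog,
    TraitTerm,
    derive_presence_classes,
    load_default_catalog,
)

DATA_DIR = Path(__file__).parent / "data"


def make_catalog(
    structures,
    subclass=(),
    parts=(),
    traits=(),
) -> TraitCatalog:
    """Build an (underived) catalog from terse tuples.

    ``structures``: iterable of ids; ``subclass``: (child, parent) pairs;
    ``parts``: (whole, part) pairs; ``traits``: (trait_id, structure_id)
    or (trait_id, structure_id, modality) tuples.
    """
    parents: dict[str, set] = {s: set() for s in structures}
    part_map: dict[str, set] = {s: set() for s in structures}
    for child, parent in subclass:
        parents[child].add(parent)
    for whole, part in parts:
        part_map[whole].add(part)
    struct_terms = {
        s: StructureTerm(s, s.replace("_", " "), frozenset(parents[s]), frozenset(part_map[s]))
        for s in structures
    }
    trait_terms = {}
    for spec in traits:
        tid, sid = spec[0], spec[1]
        modality = spec[2] if len(spec) > 2 else "attached"
        trait_terms[tid] = TraitTerm(tid, tid.replace("_", " "), sid, modality)
    return TraitCatalog(structures=struct_terms, traits=trait_terms)


def random_catalog(rng: np.random.Generator, max_structures: int = 50) -> TraitCatalog:
    """A random acyclic structure graph with traits on most structures.

    Subclass and parthood edges both point from higher to lower indices, so
    the combined graph is a DAG by construction.
    """
    n = int(rng.integers(1, max_structures + 1))
    ids = [f"s{i:02d}" for i in range(n)]
    subclass = []
    parts = []
    for i in range(1, n):
        for j in rng.choice(i, size=min(i, int(rng.integers(0, 3))), replace=False):
            subclass.append((ids[i], ids[int(j)]))
        if i >= 1 and rng.random() < 0.15:
            j = int(rng.integers(0, i))
            if (ids[i], ids[j]) not in subclass:
                parts.append((ids[i], ids[j]))
    traits = []
    for sid in ids:
        if rng.random() < 0.85:
            traits.append((f"t_{sid}", sid, "attached"))
        if rng.random() < 0.2:
            traits.append((f"t_{sid}_abs", sid, "abscised"))
    if not traits:  # keep at least one trait so derivation is non-trivial
        traits.append((f"t_{ids[0]}", ids[0], "attached"))
    return make_catalog(ids, subclass, parts, traits)


def brute_force_closure(catalog: TraitCatalog, class_id: str) -> set:
    """Reflexive-transitive reachability by plain DFS over direct edges."""
    seen = set()
    stack = [class_id]
    while stack:
        current = stack.pop()
        if current in seen:
            continue
        seen.add(current)
        stack.extend(catalog.presence_classes[current].superclasses)
    return seen


@pytest.fixture(scope="session")
def default_catalog() -> TraitCatalog:
    return load_default_catalog()


@pytest.fixture(scope="session")
def raw_default_catalog() -> TraitCatalog:
    return load_default_catalog(derive=False)


@pytest.fixture()
def leafbud_catalog() -> TraitCatalog:
    """The minimal inversion example: dormant leaf bud under leaf bud."""
    cat = make_catalog(
        structures=["leaf_bud", "dormant_leaf_bud"],
        subclass=[("dormant_leaf_bud", "leaf_bud")],
        traits=[("leaf_bud_presence", "leaf_bud"), ("dormant_leaf_bud_presence", "dormant_leaf_bud")],
    )
    return derive_presence_classes(cat)
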