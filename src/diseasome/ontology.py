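"""Ontology handling: OBO loading, transitive closures, and text-matching term sets.

The pipeline treats an ontology as a rooted DAG of classes connected by
asserted ``is_a`` edges.  Two closures drive everything downstream:

* the *subclass* closure of a class collects the class and all of its
  descendants and defines the lexicon ``Terms(C)`` used to find mentions of
  the class in text (a mention of any subclass counts as a mention of the
  class);
* the *superclass* closure of an annotation set ``Cl(X)`` extends a set of
  classes with all their ancestors, making annotation profiles comparable
  across levels of abstraction.

Closures are computed over the asserted hierarchy of the supplied
(pre-reasoned) ontology files; no logical reasoning is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyClass",
    "Ontology",
    "TermSet",
    "MissingClassError",
    "load_obo",
    "merge_ontologies",
    "subclass_closure",
    "superclass_closure",
    "term_set",
    "write_closure_tsv",
]


class MissingClassError(KeyError):
    """Raised when a class identifier does not resolve in the ontology."""


@dataclass(frozen=True)
class OntologyClass:
    """A single ontology class with its lexical and hierarchical context."""

    id: str
    primary_label: str
    synonyms: frozenset[str] = frozenset()
    parent_ids: frozenset[str] = frozenset()

    @property
    def labels(self) -> frozenset[str]:
        """All labels and synonyms of the class (``Lab(C)``)."""
        return self.synonyms | {self.primary_label}


@dataclass(frozen=True)
class TermSet:
    """The normalized text-matching lexicon of one class, ``Terms(C)``.

    Each term is a tuple of normalized tokens; matching a term means finding
    that token sequence contiguously in a document.
    """

    class_id: str
    terms: frozenset[tuple[str, ...]]

    def __bool__(self) -> bool:
        return bool(self.terms)


class Ontology:
    """A rooted DAG of :class:`OntologyClass` objects keyed by identifier.

    Parameters
    ----------
    classes
        Mapping from class id to :class:`OntologyClass`.  Every parent id
        must itself be a key of the mapping and the ``is_a`` graph must be
        acyclic.
    """

    def __init__(self, classes: Mapping[str, OntologyClass]):
        self.classes: dict[str, OntologyClass] = dict(classes)
        for cls in self.classes.values():
            missing = cls.parent_ids - self.classes.keys()
            if missing:
                raise ValueError(
                    f"class {cls.id!r} references unknown parents: {sorted(missing)}"
                )
        self._children: dict[str, set[str]] = {cid: set() for cid in self.classes}
        for cls in self.classes.values():
            for pid in cls.parent_ids:
                self._children[pid].add(cls.id)
        self.roots: frozenset[str] = frozenset(
            cid for cid, cls in self.classes.items() if not cls.parent_ids
        )
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for cls in self.classes.values():
            g.add_edges_from((cls.id, pid) for pid in cls.parent_ids)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a hierarchy contains a cycle")

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, class_id: str) -> OntologyClass:
        try:
            return self.classes[class_id]
        except KeyError:
            raise MissingClassError(class_id) from None

    def children(self, class_id: str) -> set[str]:
        if class_id not in self._children:
            raise MissingClassError(class_id)
        return set(self._children[class_id])

    def parents(self, class_id: str) -> set[str]:
        return set(self[class_id].parent_ids)


def subclass_closure(ontology: Ontology, class_id: str) -> set[str]:
    """Return ``class_id`` plus all of its transitive descendants.

    The closure is reflexive: a leaf maps to the singleton of itself.
    """
    if class_id not in ontology:
        raise MissingClassError(class_id)
    seen = {class_id}
    stack = [class_id]
    while stack:
        for child in ontology.children(stack.pop()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return seen


def superclass_closure(ontology: Ontology, class_ids: Iterable[str]) -> set[str]:
    """Close a set of classes against the superclass relation (``Cl(X)``).

    Returns the input ids together with all their transitive ancestors; the
    result is a fixed point (re-applying the closure is the identity).
    """
    seen: set[str] = set()
    stack = list(class_ids)
    for cid in stack:
        if cid not in ontology:
            raise MissingClassError(cid)
    seen.update(stack)
    while stack:
        for parent in ontology[stack.pop()].parent_ids:
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


def term_set(
    ontology: Ontology,
    class_id: str,
    normalizer: Callable[[str], list[str]],
) -> TermSet:
    """Build ``Terms(C)``: normalized labels/synonyms of ``C`` and all subclasses.

    Labels that normalize to an empty token sequence (e.g. pure stop-word
    labels) are dropped; duplicates collapse.  An empty term set is returned
    as-is — the caller decides whether that warrants a warning.
    """
    terms: set[tuple[str, ...]] = set()
    for cid in subclass_closure(ontology, class_id):
        for label in ontology[cid].labels:
            tokens = tuple(normalizer(label))
            if tokens:
                terms.add(tokens)
    return TermSet(class_id=class_id, terms=frozenset(terms))


_SYNONYM_RE = re.compile(r'^"(?P<text>.*)"\s*(?:EXACT|BROAD|NARROW|RELATED)?')


def _parse_synonym(raw: str) -> str | None:
    m = _SYNONYM_RE.match(raw)
    return m.group("text") if m else None


def load_obo(path: str | Path) -> Ontology:
    """Load an OBO flat file into an :class:`Ontology`.

    Only the ``id``, ``name``, ``synonym`` and ``is_a`` tags are consumed.
    Synonyms of every scope (EXACT/BROAD/NARROW/RELATED) are kept as terms.
    Obsolete classes and non-``is_a`` relationships are ignored, as are
    dangling ``is_a`` targets (e.g. references to obsolete classes).
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    classes: dict[str, OntologyClass] = {}
    for node, data in graph.nodes(data=True):
        name = data.get("name", node)
        synonyms = frozenset(
            s for s in (_parse_synonym(raw) for raw in data.get("synonym", [])) if s
        )
        parents = frozenset(
            v for _, v, key in graph.out_edges(node, keys=True)
            if key == "is_a" and v in graph
        )
        classes[node] = OntologyClass(
            id=node, primary_label=name, synonyms=synonyms, parent_ids=parents
        )
    return Ontology(classes)


def merge_ontologies(*ontologies: Ontology) -> Ontology:
    """Merge ontologies into one, keyed by class id.

    Identifiers must not collide across inputs; no cross-ontology edges are
    invented, so the merged DAG has one root per input ontology (at least).
    """
    classes: dict[str, OntologyClass] = {}
    for ont in ontologies:
        overlap = classes.keys() & ont.classes.keys()
        if overlap:
            raise ValueError(f"duplicate class ids across ontologies: {sorted(overlap)[:5]}")
        classes.update(ont.classes)
    return Ontology(classes)


def write_obo(ontology: Ontology, path: str | Path, name: str = "ontology") -> None:
    """Write the ontology as a minimal OBO flat file (id, name, synonym, is_a)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {name}\n")
        for cid in sorted(ontology.classes):
            cls = ontology.classes[cid]
            fh.write(f"\n[Term]\nid: {cls.id}\nname: {cls.primary_label}\n")
            for syn in sorted(cls.synonyms):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for pid in sorted(cls.parent_ids):
                fh.write(f"is_a: {pid}\n")


def write_closure_tsv(ontology: Ontology, path: str | Path) -> None:
    """Dump the superclass closure of every class as (class_id, ancestor_id) rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("class_id\tancestor_id\n")
        for cid in sorted(ontology.classes):
            for anc in sorted(superclass_closure(ontology, [cid])):
                fh.write(f"{cid}\t{anc}\n")
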