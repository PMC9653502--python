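"""In-memory terminology model with a JSON lexicon reader and graph queries.

The JSON lexicon dialect is the canonical internal format::

    {"classes":   [{"id","label","synonyms":[...],"parents":[...],"annotations":{...}}],
     "relations": [{"property","source","target","quantifier"}],
     "compositions": [{"defined_class","components":[["prop","class"],...],"connective"}]}

OWL import (see :mod:`ontofeat.owl_io`) is a best-effort projection onto this
model: subclass axioms, labels, annotation synonyms, and quantified
restrictions only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from ._text import normalize

GRADING_KEY = "grading_value"
WILDCARD = "*"


class OntologyError(ValueError):
    """Raised for structurally invalid terminologies or lexicon files."""


@dataclass(frozen=True)
class OntClass:
    """A named class with its lexical forms and isA parents."""

    id: str
    preferred_label: str
    synonyms: frozenset[str] = frozenset()
    parents: frozenset[str] = frozenset()
    annotations: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("class id must be nonempty")
        if not self.preferred_label.strip():
            raise OntologyError(f"class {self.id!r}: preferred_label must be nonempty")
        grade = self.annotations.get(GRADING_KEY)
        if grade is not None and grade not in (0, 1, 2):
            raise OntologyError(f"class {self.id!r}: grading_value {grade!r} not in {{0,1,2}}")

    @property
    def grading_value(self) -> int | None:
        value = self.annotations.get(GRADING_KEY)
        return int(value) if value is not None else None

    def labels(self) -> set[str]:
        return {self.preferred_label, *self.synonyms}


@dataclass(frozen=True)
class Relation:
    """A quantified object-property edge between two classes."""

    property_id: str
    source: str
    target: str
    quantifier: str = "some"

    def __post_init__(self) -> None:
        if self.quantifier not in ("some", "only"):
            raise OntologyError(f"relation quantifier must be 'some' or 'only', got {self.quantifier!r}")


@dataclass(frozen=True)
class CompositionAxiom:
    """A defined class equated with an AND/OR combination of quantified fillers."""

    defined_class: str
    components: tuple[tuple[str, str], ...]
    connective: str = "AND"

    def __post_init__(self) -> None:
        if not self.components:
            raise OntologyError(f"composition for {self.defined_class!r}: components must be nonempty")
        if self.connective not in ("AND", "OR"):
            raise OntologyError(f"composition connective must be AND or OR, got {self.connective!r}")


class Ontology:
    """Validated class graph plus a normalized label index.

    The label index maps every normalized preferred label and synonym to the
    set of class ids carrying that surface form.
    """

    def __init__(
        self,
        classes: Iterable[OntClass],
        relations: Iterable[Relation] = (),
        compositions: Iterable[CompositionAxiom] = (),
    ) -> None:
        self.classes: dict[str, OntClass] = {}
        for cls in classes:
            if cls.id in self.classes:
                raise OntologyError(f"duplicate class id {cls.id!r}")
            self.classes[cls.id] = cls
        if not self.classes:
            raise OntologyError("empty ontology")
        self.relations: list[Relation] = list(relations)
        self.compositions: list[CompositionAxiom] = list(compositions)
        self._validate_references()
        self._check_acyclic()
        self.label_index: dict[str, set[str]] = {}
        self._build_label_index()

    # -- construction helpers -------------------------------------------------

    def _validate_references(self) -> None:
        for cls in self.classes.values():
            for parent in cls.parents:
                if parent not in self.classes:
                    raise OntologyError(f"class {cls.id!r}: dangling parent reference {parent!r}")
        for rel in self.relations:
            for endpoint in (rel.source, rel.target):
                if endpoint not in self.classes:
                    raise OntologyError(
                        f"relation {rel.property_id!r}: dangling class reference {endpoint!r}"
                    )
        for comp in self.compositions:
            if comp.defined_class not in self.classes:
                raise OntologyError(f"composition: dangling class reference {comp.defined_class!r}")
            for _, filler in comp.components:
                if filler not in self.classes:
                    raise OntologyError(f"composition: dangling class reference {filler!r}")

    def _check_acyclic(self) -> None:
        # iterative DFS over the isA graph; any back edge is a hard error
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {cid: WHITE for cid in self.classes}
        for start in self.classes:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(sorted(self.classes[start].parents)))]
            color[start] = GRAY
            while stack:
                node, parents = stack[-1]
                advanced = False
                for parent in parents:
                    if color[parent] == GRAY:
                        raise OntologyError(f"isA cycle involving {parent!r}")
                    if color[parent] == WHITE:
                        color[parent] = GRAY
                        stack.append((parent, iter(sorted(self.classes[parent].parents))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def _build_label_index(self) -> None:
        self.label_index.clear()
        for cls in self.classes.values():
            for label in cls.labels():
                key = normalize(label)
                if key:
                    self.label_index.setdefault(key, set()).add(cls.id)

    # -- queries --------------------------------------------------------------

    def _require(self, class_id: str) -> OntClass:
        try:
            return self.classes[class_id]
        except KeyError:
            raise OntologyError(f"unknown class id {class_id!r}") from None

    def ancestors(self, class_id: str) -> set[str]:
        """Transitive isA closure of ``class_id``, excluding itself."""
        self._require(class_id)
        seen: set[str] = set()
        frontier = list(self.classes[class_id].parents)
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(self.classes[node].parents)
        return seen

    def related(self, class_id: str, property_id: str = WILDCARD) -> set[str]:
        """One-hop relation targets of ``class_id`` under a property filter."""
        self._require(class_id)
        return {
            rel.target
            for rel in self.relations
            if rel.source == class_id and (property_id == WILDCARD or rel.property_id == property_id)
        }

    def lookup(self, surface: str) -> set[str]:
        """Class ids whose normalized label/synonym equals the normalized surface."""
        return set(self.label_index.get(normalize(surface), ()))


# -- lexicon I/O --------------------------------------------------------------

def load_lexicon(path: str | Path) -> Ontology:
    """Read the JSON lexicon dialect into a validated :class:`Ontology`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise OntologyError(f"{path}: parse error at line {exc.lineno}: {exc.msg}") from exc
    return ontology_from_dict(payload, source=str(path))


def ontology_from_dict(payload: Mapping[str, object], source: str = "<dict>") -> Ontology:
    raw_classes = payload.get("classes")
    if not raw_classes:
        raise OntologyError(f"{source}: empty ontology")
    classes = []
    for i, entry in enumerate(raw_classes):
        try:
            classes.append(
                OntClass(
                    id=str(entry["id"]),
                    preferred_label=str(entry["label"]),
                    synonyms=frozenset(entry.get("synonyms", ())),
                    parents=frozenset(entry.get("parents", ())),
                    annotations=dict(entry.get("annotations", {})),
                )
            )
        except KeyError as exc:
            raise OntologyError(f"{source}: classes[{i}] missing field {exc.args[0]!r}") from None
    relations = [
        Relation(
            property_id=str(entry["property"]),
            source=str(entry["source"]),
            target=str(entry["target"]),
            quantifier=str(entry.get("quantifier", "some")),
        )
        for entry in payload.get("relations", ())
    ]
    compositions = [
        CompositionAxiom(
            defined_class=str(entry["defined_class"]),
            components=tuple((str(p), str(c)) for p, c in entry["components"]),
            connective=str(entry.get("connective", "AND")),
        )
        for entry in payload.get("compositions", ())
    ]
    return Ontology(classes, relations, compositions)


def ontology_to_dict(ontology: Ontology) -> dict:
    return {
        "classes": [
            {
                "id": cls.id,
                "label": cls.preferred_label,
                "synonyms": sorted(cls.synonyms),
                "parents": sorted(cls.parents),
                "annotations": dict(cls.annotations),
            }
            for cls in sorted(ontology.classes.values(), key=lambda c: c.id)
        ],
        "relations": [
            {
                "property": rel.property_id,
                "source": rel.source,
                "target": rel.target,
                "quantifier": rel.quantifier,
            }
            for rel in ontology.relations
        ],
        "compositions": [
            {
                "defined_class": comp.defined_class,
                "components": [list(pair) for pair in comp.components],
                "connective": comp.connective,
            }
            for comp in ontology.compositions
        ],
    }


def write_lexicon(ontology: Ontology, path: str | Path) -> None:
    """Serialize to the JSON lexicon dialect; round-trips through :func:`load_lexicon`."""
    Path(path).write_text(
        json.dumps(ontology_to_dict(ontology), indent=1, sort_keys=False) + "\n",
        encoding="utf-8",
    )
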