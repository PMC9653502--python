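"""Best-effort OWL 2 import (RDF/XML and Turtle) onto the lexicon model.

Only the constructs the terminology model uses are read: ``owl:Class``
declarations, ``rdfs:label``, annotation synonyms, ``rdfs:subClassOf`` (named
parents and quantified restrictions), and intersection/union class expressions
made of restrictions. Everything else is skipped with a log message, never
fatally. Both serializations are reduced to triples first and share one
projection step.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from pathlib import Path

from .ontology import CompositionAxiom, OntClass, Ontology, OntologyError, Relation

log = logging.getLogger(__name__)

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"

_TYPE = RDF + "type"
_CLASS = OWL + "Class"
_RESTRICTION = OWL + "Restriction"
_NIL = RDF + "nil"

Triple = tuple[str, str, tuple[str, str]]  # (subject, predicate, ("iri"|"lit"|"bnode", value))


def local_name(iri: str) -> str:
    """Fragment after '#', else the last path segment."""
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


# --------------------------------------------------------------------------
# RDF/XML → triples
# --------------------------------------------------------------------------

def _split_tag(tag: str) -> str:
    return tag[1:].replace("}", "") if tag.startswith("{") else tag


class _RdfXmlReader:
    def __init__(self) -> None:
        self.triples: list[Triple] = []
        self._bnode_counter = 0

    def _bnode(self) -> str:
        self._bnode_counter += 1
        return f"_:b{self._bnode_counter}"

    def read(self, text: str) -> list[Triple]:
        root = ET.fromstring(text)
        for child in root:
            self._node_element(child)
        return self.triples

    def _node_element(self, elem: ET.Element) -> str:
        subject = (
            elem.get(f"{{{RDF}}}about")
            or elem.get(f"{{{RDF}}}ID")
            or self._bnode()
        )
        tag = _split_tag(elem.tag)
        if tag != RDF + "Description":
            self.triples.append((subject, _TYPE, ("iri", tag)))
        for prop in elem:
            self._property_element(subject, prop)
        return subject

    def _property_element(self, subject: str, prop: ET.Element) -> None:
        predicate = _split_tag(prop.tag)
        resource = prop.get(f"{{{RDF}}}resource")
        if resource is not None:
            self.triples.append((subject, predicate, ("iri", resource)))
            return
        if prop.get(f"{{{RDF}}}parseType") == "Collection":
            members = [self._node_element(child) for child in prop]
            self._emit_list(subject, predicate, members)
            return
        children = list(prop)
        if children:
            obj = self._node_element(children[0])
            kind = "bnode" if obj.startswith("_:") else "iri"
            self.triples.append((subject, predicate, (kind, obj)))
            return
        text = (prop.text or "").strip()
        self.triples.append((subject, predicate, ("lit", text)))

    def _emit_list(self, subject: str, predicate: str, members: list[str]) -> None:
        if not members:
            self.triples.append((subject, predicate, ("iri", _NIL)))
            return
        head = self._bnode()
        self.triples.append((subject, predicate, ("bnode", head)))
        for i, member in enumerate(members):
            kind = "bnode" if member.startswith("_:") else "iri"
            self.triples.append((head, RDF + "first", (kind, member)))
            if i + 1 < len(members):
                nxt = self._bnode()
                self.triples.append((head, RDF + "rest", ("bnode", nxt)))
                head = nxt
            else:
                self.triples.append((head, RDF + "rest", ("iri", _NIL)))


# --------------------------------------------------------------------------
# Turtle → triples (simple subset: prefixes, ; and , separators, [] bnodes,
# () collections, IRIs, prefixed names, plain/typed/lang string literals)
# --------------------------------------------------------------------------

_TTL_TOKEN = re.compile(
    r"""
      (?P<comment>\#[^\n]*)
    | (?P<iri><[^>]*>)
    | (?P<literal>"(?:[^"\\]|\\.)*"(?:@[\w-]+|\^\^\S+)?)
    | (?P<punct>[;,.\[\]()])
    | (?P<name>[^\s;,.\[\]()]+)
    """,
    re.VERBOSE,
)


class _TurtleReader:
    def __init__(self) -> None:
        self.triples: list[Triple] = []
        self.prefixes: dict[str, str] = {}
        self._bnode_counter = 0
        self._tokens: list[str] = []
        self._pos = 0

    def _bnode(self) -> str:
        self._bnode_counter += 1
        return f"_:t{self._bnode_counter}"

    def read(self, text: str) -> list[Triple]:
        self._tokens = [
            m.group(0)
            for m in _TTL_TOKEN.finditer(text)
            if not m.group("comment")
        ]
        self._pos = 0
        while self._pos < len(self._tokens):
            tok = self._peek()
            if tok.lower() in ("@prefix", "prefix"):
                self._read_prefix()
            elif tok.lower() in ("@base", "base"):
                self._next(), self._next()
                if self._peek() == ".":
                    self._next()
            else:
                self._read_statement()
        return self.triples

    def _peek(self) -> str:
        return self._tokens[self._pos]

    def _next(self) -> str:
        tok = self._tokens[self._pos]
        self._pos += 1
        return tok

    def _read_prefix(self) -> None:
        self._next()  # @prefix
        name = self._next().rstrip(":")
        iri = self._next()
        self.prefixes[name] = iri[1:-1]
        if self._pos < len(self._tokens) and self._peek() == ".":
            self._next()

    def _resolve(self, tok: str) -> tuple[str, str]:
        if tok.startswith("<"):
            return ("iri", tok[1:-1])
        if tok.startswith('"'):
            value = re.match(r'"((?:[^"\\]|\\.)*)"', tok).group(1)
            return ("lit", value.replace('\\"', '"'))
        if tok == "a":
            return ("iri", _TYPE)
        if ":" in tok:
            prefix, local = tok.split(":", 1)
            base = self.prefixes.get(prefix)
            if base is None:
                raise OntologyError(f"turtle: undeclared prefix {prefix!r}")
            return ("iri", base + local)
        raise OntologyError(f"turtle: cannot parse token {tok!r}")

    def _read_statement(self) -> None:
        subject = self._read_node()
        self._read_predicate_object_list(subject)
        if self._pos < len(self._tokens) and self._peek() == ".":
            self._next()

    def _read_node(self) -> str:
        tok = self._peek()
        if tok == "[":
            self._next()
            node = self._bnode()
            if self._peek() != "]":
                self._read_predicate_object_list(node)
            self._next()  # ]
            return node
        if tok == "(":
            self._next()
            members = []
            while self._peek() != ")":
                members.append(self._read_node())
            self._next()  # )
            return self._emit_list(members)
        kind, value = self._resolve(self._next())
        if kind == "lit":
            raise OntologyError("turtle: literal in subject/node position")
        return value

    def _emit_list(self, members: list[str]) -> str:
        if not members:
            return _NIL
        head = first = self._bnode()
        for i, member in enumerate(members):
            kind = "bnode" if member.startswith("_:") else "iri"
            self.triples.append((head, RDF + "first", (kind, member)))
            if i + 1 < len(members):
                nxt = self._bnode()
                self.triples.append((head, RDF + "rest", ("bnode", nxt)))
                head = nxt
            else:
                self.triples.append((head, RDF + "rest", ("iri", _NIL)))
        return first

    def _read_predicate_object_list(self, subject: str) -> None:
        while True:
            _, predicate = self._resolve(self._next())
            while True:
                tok = self._peek()
                if tok in ("[", "("):
                    node = self._read_node()
                    kind = "bnode" if node.startswith("_:") else "iri"
                    self.triples.append((subject, predicate, (kind, node)))
                else:
                    kind, value = self._resolve(self._next())
                    if kind == "iri" and value.startswith("_:"):
                        kind = "bnode"
                    self.triples.append((subject, predicate, (kind, value)))
                if self._pos < len(self._tokens) and self._peek() == ",":
                    self._next()
                    continue
                break
            if self._pos < len(self._tokens) and self._peek() == ";":
                self._next()
                if self._pos < len(self._tokens) and self._peek() in (".", "]"):
                    break
                continue
            break


# --------------------------------------------------------------------------
# triples → Ontology
# --------------------------------------------------------------------------

def _iter_list(index: dict, head: str) -> list[str]:
    members = []
    while head and head != _NIL:
        node = index.get(head, {})
        first = node.get(RDF + "first", [])
        if first:
            members.append(first[0][1])
        rest = node.get(RDF + "rest", [(None, _NIL)])
        head = rest[0][1]
    return members


def _project(triples: list[Triple], source: str) -> Ontology:
    index: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for s, p, o in triples:
        index.setdefault(s, {}).setdefault(p, []).append(o)

    # property labels, for the synonym-annotation heuristic
    prop_labels: dict[str, str] = {}
    for subj, props in index.items():
        for _, label in props.get(RDFS + "label", []):
            prop_labels[subj] = label

    def is_synonym_property(predicate: str) -> bool:
        if "synonym" in local_name(predicate).lower():
            return True
        return "synonym" in prop_labels.get(predicate, "").lower()

    def restriction_parts(node: str) -> tuple[str, str, str] | None:
        props = index.get(node, {})
        types = {o[1] for o in props.get(_TYPE, [])}
        if _RESTRICTION not in types and OWL + "onProperty" not in props:
            return None
        on_prop = props.get(OWL + "onProperty")
        some = props.get(OWL + "someValuesFrom")
        only = props.get(OWL + "allValuesFrom")
        if not on_prop or not (some or only):
            return None
        filler_kind, filler = (some or only)[0]
        if filler_kind != "iri":
            return None  # nested anonymous filler: skipped
        quantifier = "some" if some else "only"
        return local_name(on_prop[0][1]), filler, quantifier

    class_iris = sorted(
        subj
        for subj, props in index.items()
        if not subj.startswith("_:")
        and any(o == ("iri", _CLASS) for o in props.get(_TYPE, []))
    )
    if not class_iris:
        raise OntologyError(f"{source}: no classes found")
    ids = {iri: local_name(iri) for iri in class_iris}

    classes: list[OntClass] = []
    relations: list[Relation] = []
    compositions: list[CompositionAxiom] = []
    for iri in class_iris:
        props = index[iri]
        labels = [o[1] for o in props.get(RDFS + "label", []) if o[0] == "lit"]
        preferred = labels[0] if labels else ids[iri]
        synonyms: set[str] = set(labels[1:])
        parents: set[str] = set()
        for predicate, objects in props.items():
            if is_synonym_property(predicate):
                synonyms.update(o[1] for o in objects if o[0] == "lit")
        for kind, obj in props.get(RDFS + "subClassOf", []):
            if kind == "iri":
                if obj in ids:
                    parents.add(ids[obj])
                else:
                    log.info("skipping subclass axiom %s -> undeclared %s", iri, obj)
            else:  # restriction bnode
                parts = restriction_parts(obj)
                if parts and parts[1] in ids:
                    relations.append(
                        Relation(parts[0], ids[iri], ids[parts[1]], quantifier=parts[2])
                    )
                else:
                    log.info("skipping unparseable subclass expression on %s", iri)
        for kind, obj in props.get(OWL + "equivalentClass", []):
            if kind != "bnode":
                continue
            eq_props = index.get(obj, {})
            for connective, key in (("AND", OWL + "intersectionOf"), ("OR", OWL + "unionOf")):
                for list_kind, head in eq_props.get(key, []):
                    members = _iter_list(index, head)
                    components = []
                    for member in members:
                        parts = restriction_parts(member) if member.startswith("_:") else None
                        if parts and parts[1] in ids:
                            components.append((parts[0], ids[parts[1]]))
                        else:
                            log.info("skipping non-restriction member in expression on %s", iri)
                    if components:
                        compositions.append(
                            CompositionAxiom(ids[iri], tuple(components), connective=connective)
                        )
        classes.append(
            OntClass(
                id=ids[iri],
                preferred_label=preferred,
                synonyms=frozenset(synonyms),
                parents=frozenset(parents),
            )
        )
    return Ontology(classes, relations, compositions)


def load_owl(path: str | Path) -> Ontology:
    """Read an OWL 2 file (RDF/XML or Turtle, sniffed by content) into an Ontology."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise OntologyError(f"cannot read {path}: {exc}") from exc
    stripped = text.lstrip()
    if stripped.startswith("<"):
        try:
            triples = _RdfXmlReader().read(text)
        except ET.ParseError as exc:
            raise OntologyError(f"{path}: RDF/XML parse error: {exc}") from exc
    else:
        triples = _TurtleReader().read(text)
    return _project(triples, source=str(path))
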