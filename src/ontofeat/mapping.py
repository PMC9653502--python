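"""Three-step term-to-ontology mapping cascade with reviewable audit tables.

Order is fixed: syntactic (whole-phrase label/synonym match), compositional
(greedy leftmost-longest span consumption), semantic (suffix-stripped stem
anchors expanded one hop along isA parents and relation targets). The first
step that succeeds wins; results carry step provenance and residual tokens so
every automatic decision can be audited and overridden via the review table.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from ._text import DEFAULT_STOPWORDS, DEFAULT_STRIP_SUFFIXES, normalize, singularize, stem, tokenize
from .ontology import Ontology, OntologyError

CATEGORIES = ("microscopy", "immunohistochemistry", "imaging", "anatomy", "diagnosis")

STEP_SYNTACTIC = "syntactic"
STEP_COMPOSITIONAL = "compositional"
STEP_SEMANTIC = "semantic"
STEP_UNMAPPED = "unmapped"


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class RawTerm:
    """A category-tagged surface string from a patient report."""

    text: str
    category: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise MappingError("raw term text must be nonempty")
        if self.category not in CATEGORIES:
            raise MappingError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")


@dataclass(frozen=True)
class MappingConfig:
    """Tunables of the cascade; defaults reproduce the reference behaviour."""

    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    max_residual: float = 0.5
    strip_suffixes: tuple[str, ...] = DEFAULT_STRIP_SUFFIXES
    semantic_expand: tuple[str, ...] = ("isa", "relations")
    max_expansion: int = 3


@dataclass(frozen=True)
class MappingResult:
    raw: RawTerm
    classes: frozenset[str]
    step: str
    residual_tokens: tuple[str, ...] = ()
    reviewed: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.step == STEP_SYNTACTIC and len(self.classes) != 1:
            raise MappingError("syntactic result must carry exactly one class")
        if (self.step == STEP_UNMAPPED) != (not self.classes):
            raise MappingError("step=unmapped iff class set empty")


def _unmapped(term: RawTerm, residual: Sequence[str] = (), note: str = "") -> MappingResult:
    return MappingResult(term, frozenset(), STEP_UNMAPPED, tuple(residual), note=note)


# --------------------------------------------------------------------------
# the three matchers
# --------------------------------------------------------------------------

def _resolve_ambiguous(key: str, hits: set[str], ontology: Ontology) -> str | None:
    """Preferred-label priority for multi-class surface collisions."""
    preferred = [cid for cid in hits if normalize(ontology.classes[cid].preferred_label) == key]
    if len(preferred) == 1:
        return preferred[0]
    return None


def match_syntactic(term: RawTerm, ontology: Ontology, config: MappingConfig = MappingConfig()) -> MappingResult:
    """Whole-phrase match: succeeds iff the normalized term is a label/synonym of one class."""
    key = normalize(term.text, config.stopwords)
    hits = ontology.label_index.get(key)
    if not hits:
        return _unmapped(term, tokenize(term.text, config.stopwords))
    if len(hits) == 1:
        return MappingResult(term, frozenset(hits), STEP_SYNTACTIC)
    winner = _resolve_ambiguous(key, hits, ontology)
    if winner is not None:
        return MappingResult(term, frozenset({winner}), STEP_SYNTACTIC)
    return _unmapped(
        term,
        tokenize(term.text, config.stopwords),
        note=f"ambiguous: {key!r} names classes {sorted(hits)}; flagged for review",
    )


def _span_lookup(span: Sequence[str], ontology: Ontology) -> set[str]:
    hits = ontology.label_index.get(" ".join(span))
    if hits:
        return hits
    # depluralized fallback so trivial plural variants still consume their span
    fallback = " ".join(singularize(tok) for tok in span)
    return ontology.label_index.get(fallback, set())


def match_compositional(term: RawTerm, ontology: Ontology, config: MappingConfig = MappingConfig()) -> MappingResult:
    """Greedy leftmost-longest span consumption over the normalized token sequence."""
    tokens = tokenize(term.text, config.stopwords)
    if not tokens:
        return _unmapped(term)
    consumed = [False] * len(tokens)
    found: list[str] = []
    for length in range(len(tokens), 0, -1):
        start = 0
        while start + length <= len(tokens):
            if any(consumed[start : start + length]):
                start += 1
                continue
            span = tokens[start : start + length]
            hits = _span_lookup(span, ontology)
            if hits:
                if len(hits) > 1:
                    winner = _resolve_ambiguous(" ".join(span), hits, ontology)
                    if winner is None:
                        start += 1
                        continue
                    hit = winner
                else:
                    (hit,) = hits
                if hit not in found:
                    found.append(hit)
                for i in range(start, start + length):
                    consumed[i] = True
                start += length
            else:
                start += 1
    residual = tuple(tok for tok, used in zip(tokens, consumed) if not used)
    residual_fraction = len(residual) / len(tokens)
    if len(found) >= 2 or (found and residual_fraction <= config.max_residual):
        return MappingResult(term, frozenset(found), STEP_COMPOSITIONAL, residual)
    return _unmapped(term, residual)


def transform_semantic(term: RawTerm, ontology: Ontology, config: MappingConfig = MappingConfig()) -> MappingResult:
    """Stem-level anchor matching plus a capped one-hop neighborhood expansion."""
    tokens = tokenize(term.text, config.stopwords)
    if not tokens:
        return _unmapped(term)
    stem_index = _stem_index(ontology, config.strip_suffixes)
    anchors: list[str] = []
    residual: list[str] = []
    for token in tokens:
        hits = stem_index.get(stem(token, config.strip_suffixes), ())
        if len(hits) == 1 and hits[0] not in anchors:
            anchors.append(hits[0])
        elif not hits:
            residual.append(token)
        else:
            residual.append(token)  # ambiguous stems never anchor
    if not anchors:
        return _unmapped(term, residual)
    expanded: list[str] = list(anchors)
    budget = config.max_expansion
    for anchor in anchors:
        neighbors: list[str] = []
        if "isa" in config.semantic_expand:
            neighbors.extend(sorted(ontology.classes[anchor].parents))
        if "relations" in config.semantic_expand:
            neighbors.extend(sorted(ontology.related(anchor)))
        for neighbor in neighbors:
            if budget == 0:
                break
            if neighbor not in expanded:
                expanded.append(neighbor)
                budget -= 1
    return MappingResult(term, frozenset(expanded), STEP_SEMANTIC, tuple(residual))


_STEM_CACHE: dict[tuple[int, tuple[str, ...]], dict[str, tuple[str, ...]]] = {}


def _stem_index(ontology: Ontology, suffixes: tuple[str, ...]) -> dict[str, tuple[str, ...]]:
    """stem → class ids, over single-token labels/synonyms only (anchor candidates)."""
    key = (id(ontology), suffixes)
    cached = _STEM_CACHE.get(key)
    if cached is not None:
        return cached
    index: dict[str, set[str]] = {}
    for label_key, cids in ontology.label_index.items():
        if " " in label_key:
            continue
        index.setdefault(stem(label_key, suffixes), set()).update(cids)
    frozen = {s: tuple(sorted(cids)) for s, cids in index.items()}
    if len(_STEM_CACHE) > 8:
        _STEM_CACHE.clear()
    _STEM_CACHE[key] = frozen
    return frozen


def map_term(term: RawTerm, ontology: Ontology, config: MappingConfig = MappingConfig()) -> MappingResult:
    """Apply the cascade in fixed order; the first successful step wins."""
    result = match_syntactic(term, ontology, config)
    if result.step != STEP_UNMAPPED:
        return result
    ambiguous_note = result.note
    result = match_compositional(term, ontology, config)
    if result.step != STEP_UNMAPPED:
        return result
    result = transform_semantic(term, ontology, config)
    if result.step == STEP_UNMAPPED and ambiguous_note:
        return replace(result, note=ambiguous_note)
    return result


# --------------------------------------------------------------------------
# corpus-level mapping and review round-trip
# --------------------------------------------------------------------------

@dataclass
class MappingTable:
    """Distinct (normalized text, category) → result, with an audit log."""

    entries: dict[tuple[str, str], MappingResult] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    frequencies: Counter = field(default_factory=Counter)

    def key(self, term: RawTerm, stopwords: frozenset[str] = DEFAULT_STOPWORDS) -> tuple[str, str]:
        return (normalize(term.text, stopwords), term.category)

    def get(self, term: RawTerm, stopwords: frozenset[str] = DEFAULT_STOPWORDS) -> MappingResult | None:
        return self.entries.get(self.key(term, stopwords))

    def unmapped_report(self) -> list[tuple[str, str, int]]:
        """(normalized text, category, frequency) of unmapped entries, most frequent first."""
        rows = [
            (key[0], key[1], self.frequencies[key])
            for key, result in self.entries.items()
            if result.step == STEP_UNMAPPED
        ]
        return sorted(rows, key=lambda row: (-row[2], row[0], row[1]))

    def vocabulary_counts(self) -> dict[str, tuple[int, int]]:
        """category → (distinct raw terms, distinct mapped feature keys).

        Unmapped entries count themselves as raw fallback keys on the mapped side.
        """
        raw: Counter = Counter()
        mapped: dict[str, set[str]] = {c: set() for c in CATEGORIES}
        for (text, category), result in self.entries.items():
            raw[category] += 1
            if result.classes:
                mapped[category].update(result.classes)
            else:
                mapped[category].add(f"raw:{text}")
        return {c: (raw[c], len(mapped[c])) for c in CATEGORIES if raw[c]}


def map_corpus(
    reports: Iterable,
    ontology: Ontology,
    config: MappingConfig = MappingConfig(),
    table: MappingTable | None = None,
) -> MappingTable:
    """Map every distinct (normalized text, category) in the corpus exactly once.

    ``reports`` may be :class:`~ontofeat.features.Report` objects or plain
    ``(category → [terms], diagnoses)``-shaped objects exposing ``iter_terms``.
    Reviewed entries in a pre-seeded ``table`` are never overwritten.
    """
    table = table if table is not None else MappingTable()
    for report in reports:
        for term in report.iter_terms():
            key = table.key(term, config.stopwords)
            table.frequencies[key] += 1
            if key in table.entries:
                # reviewed entries are never overwritten; automatic entries need
                # no remap (the cascade is deterministic)
                continue
            result = map_term(term, ontology, config)
            table.entries[key] = result
            table.provenance.append(f"auto\t{key[0]}\t{key[1]}\t{result.step}")
    return table


REVIEW_COLUMNS = ("raw_text", "category", "class_ids", "step", "approved")


def export_review_table(
    table: MappingTable, path: str | Path, extra_header: dict[str, str] | None = None
) -> None:
    if not table.entries:
        raise MappingError("cannot export an empty mapping table")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REVIEW_COLUMNS)
        for (text, category), result in sorted(table.entries.items()):
            writer.writerow(
                [
                    text,
                    category,
                    ";".join(sorted(result.classes)),
                    result.step,
                    "yes" if result.reviewed else "no",
                ]
            )


def import_review_table(path: str | Path, table: MappingTable, ontology: Ontology) -> MappingTable:
    """Merge a reviewed TSV back in; approved rows override automatic results."""
    steps = {STEP_SYNTACTIC, STEP_COMPOSITIONAL, STEP_SEMANTIC, STEP_UNMAPPED, "reviewed"}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        while header and header[0].startswith("#"):  # metadata comment lines
            header = next(reader, None)
        if header is None or tuple(header) != REVIEW_COLUMNS:
            raise MappingError(f"{path}: expected header {REVIEW_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(REVIEW_COLUMNS):
                raise MappingError(f"{path}:{lineno}: expected {len(REVIEW_COLUMNS)} columns, got {len(row)}")
            text, category, class_ids, step, approved = row
            if category not in CATEGORIES:
                raise MappingError(f"{path}:{lineno}: unknown category {category!r}")
            if step not in steps:
                raise MappingError(f"{path}:{lineno}: unknown step {step!r}")
            if approved not in ("yes", "no"):
                raise MappingError(f"{path}:{lineno}: approved must be yes|no, got {approved!r}")
            classes = frozenset(c for c in class_ids.split(";") if c)
            for cid in classes:
                if cid not in ontology.classes:
                    raise MappingError(f"{path}:{lineno}: unknown class id {cid!r}")
            key = (text, category)
            if approved == "yes":
                term = RawTerm(text or "?", category)
                result_step = step if classes or step == STEP_UNMAPPED else STEP_UNMAPPED
                if classes and step == STEP_UNMAPPED:
                    result_step = "reviewed"
                if result_step == STEP_SYNTACTIC and len(classes) != 1:
                    result_step = "reviewed"
                table.entries[key] = MappingResult(
                    term, classes, result_step if classes else STEP_UNMAPPED, reviewed=True
                )
                table.provenance.append(f"reviewed\t{text}\t{category}\t{result_step}")
    return table
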