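"""Report → binary feature/label matrices at a chosen mapping level.

A "mapped" category contributes one binary column per ontology class appearing
in any of its terms' mapped sets (bag of classes); a "raw" category contributes
one column per distinct normalized surface term. Unmapped terms in a mapped
category fall back to raw columns rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._text import normalize
from .mapping import MappingTable, RawTerm

INPUT_CATEGORIES = ("microscopy", "immunohistochemistry", "imaging", "anatomy")

KIND_RAW = "raw_term"
KIND_CLASS = "ontology_class"


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class Report:
    """One patient: free-text term lists per category plus ≥1 raw diagnosis."""

    patient_id: str
    terms: Mapping[str, Sequence[str]]
    diagnoses: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.diagnoses:
            raise FeatureError(f"patient {self.patient_id!r}: diagnoses must be nonempty")
        for category in self.terms:
            if category not in INPUT_CATEGORIES:
                raise FeatureError(f"patient {self.patient_id!r}: unknown category {category!r}")

    def iter_terms(self) -> Iterator[RawTerm]:
        for category in INPUT_CATEGORIES:
            for text in self.terms.get(category, ()):
                yield RawTerm(text, category)
        for text in self.diagnoses:
            yield RawTerm(text, "diagnosis")


@dataclass(frozen=True)
class MappingMask:
    """Which categories are consolidated to ontology classes vs left raw."""

    mapped_categories: frozenset[str] = frozenset()
    labels_mapped: bool = False

    def __post_init__(self) -> None:
        unknown = self.mapped_categories - set(INPUT_CATEGORIES)
        if unknown:
            raise FeatureError(f"unknown categories in mask: {sorted(unknown)}")

    @classmethod
    def all_raw(cls) -> "MappingMask":
        return cls()

    @classmethod
    def all_mapped(cls) -> "MappingMask":
        return cls(frozenset(INPUT_CATEGORIES), labels_mapped=True)

    @classmethod
    def inputs_mapped(cls) -> "MappingMask":
        return cls(frozenset(INPUT_CATEGORIES), labels_mapped=False)


@dataclass
class FeatureMatrix:
    """Binary indicator matrix with per-column (category, kind) metadata."""

    values: pd.DataFrame  # rows: patient ids; columns: feature keys
    column_meta: dict[str, tuple[str, str]] = field(default_factory=dict)  # key → (category, kind)

    def category_columns(self, category: str) -> list[str]:
        return [k for k, (cat, _) in self.column_meta.items() if cat == category]

    def to_tsv(self, path, extra_header: Mapping[str, str] | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in (extra_header or {}).items():
                fh.write(f"# {key}: {value}\n")
            for col, (cat, kind) in self.column_meta.items():
                fh.write(f"# column\t{col}\t{cat}\t{kind}\n")
            self.values.to_csv(fh, sep="\t", index_label="patient_id")


@dataclass
class LabelMatrix:
    values: pd.DataFrame

    def __post_init__(self) -> None:
        row_sums = self.values.sum(axis=1)
        if (row_sums < 1).any():
            bad = self.values.index[row_sums < 1][0]
            raise FeatureError(f"patient {bad!r}: no positive diagnosis label")

    def label_sets(self) -> list[frozenset[str]]:
        cols = np.asarray(self.values.columns)
        mask = self.values.to_numpy(dtype=bool)
        return [frozenset(cols[row]) for row in mask]


def _term_keys(
    term: RawTerm, mapping_table: MappingTable, mapped: bool, fallbacks: list[str]
) -> set[str]:
    """Feature keys one term contributes under the mask."""
    norm = normalize(term.text)
    if not mapped:
        return {f"{term.category}:raw:{norm}"} if norm else set()
    result = mapping_table.get(term)
    if result is not None and result.classes:
        return {f"{term.category}:{cid}" for cid in sorted(result.classes)}
    fallbacks.append(f"{term.category}\t{norm}")
    return {f"{term.category}:raw:{norm}"} if norm else set()


def build_features(
    reports: Sequence[Report],
    mapping_table: MappingTable,
    mask: MappingMask,
) -> FeatureMatrix:
    """Binary bag-of-classes / bag-of-terms matrix over the four input categories."""
    row_keys: list[set[str]] = []
    fallbacks: list[str] = []
    for report in reports:
        keys: set[str] = set()
        for category in INPUT_CATEGORIES:
            mapped = category in mask.mapped_categories
            for text in report.terms.get(category, ()):
                keys |= _term_keys(RawTerm(text, category), mapping_table, mapped, fallbacks)
        row_keys.append(keys)
    columns = sorted(set().union(*row_keys)) if row_keys else []
    data = np.zeros((len(reports), len(columns)), dtype=np.int8)
    col_pos = {c: i for i, c in enumerate(columns)}
    for i, keys in enumerate(row_keys):
        for key in keys:
            data[i, col_pos[key]] = 1
    frame = pd.DataFrame(data, index=[r.patient_id for r in reports], columns=columns)
    meta = {}
    for col in columns:
        category, rest = col.split(":", 1)
        kind = KIND_RAW if rest.startswith("raw:") else KIND_CLASS
        meta[col] = (category, kind)
    return FeatureMatrix(frame, meta)


def build_labels(
    reports: Sequence[Report],
    mapping_table: MappingTable,
    mask: MappingMask,
) -> LabelMatrix:
    """Multilabel diagnosis indicators; mapped mode merges synonymous raw diagnoses."""
    row_keys: list[set[str]] = []
    for report in reports:
        keys: set[str] = set()
        for text in report.diagnoses:
            term = RawTerm(text, "diagnosis")
            norm = normalize(text)
            if mask.labels_mapped:
                result = mapping_table.get(term)
                if result is not None and result.classes:
                    keys |= set(result.classes)
                elif norm:
                    keys.add(f"raw:{norm}")
            elif norm:
                keys.add(norm)
        if not keys:
            raise FeatureError(f"patient {report.patient_id!r}: all diagnoses failed mapping and fallback")
        row_keys.append(keys)
    columns = sorted(set().union(*row_keys)) if row_keys else []
    data = np.zeros((len(reports), len(columns)), dtype=np.int8)
    col_pos = {c: i for i, c in enumerate(columns)}
    for i, keys in enumerate(row_keys):
        for key in keys:
            data[i, col_pos[key]] = 1
    frame = pd.DataFrame(data, index=[r.patient_id for r in reports], columns=columns)
    return LabelMatrix(frame)


def reduction_stats(
    raw_vocab: Mapping[str, int], mapped_vocab: Mapping[str, int]
) -> dict[str, float]:
    """Per-category percent decrease in vocabulary size, truncated to 2 decimals.

    Truncation (not rounding) reproduces the reference table exactly:
    (218, 82) → 62.38, (149, 80) → 46.30.
    """
    stats: dict[str, float] = {}
    for category, raw in raw_vocab.items():
        mapped = mapped_vocab[category]
        if raw <= 0 or mapped < 0:
            raise FeatureError(f"{category}: counts must be positive")
        if mapped > raw:
            raise FeatureError(f"{category}: mapped count {mapped} exceeds raw count {raw}")
        stats[category] = ((raw - mapped) * 10000 // raw) / 100
    return stats


# --------------------------------------------------------------------------
# report I/O: long-format TSV (patient_id, category, term) and JSON
# --------------------------------------------------------------------------

def reports_to_records(reports: Iterable[Report]) -> list[dict]:
    return [
        {
            "patient_id": r.patient_id,
            "terms": {c: list(r.terms.get(c, ())) for c in INPUT_CATEGORIES if r.terms.get(c)},
            "diagnoses": list(r.diagnoses),
        }
        for r in reports
    ]


def reports_from_records(records: Iterable[Mapping]) -> list[Report]:
    reports = []
    seen: set[str] = set()
    for rec in records:
        pid = str(rec["patient_id"])
        if pid in seen:
            raise FeatureError(f"duplicate patient_id {pid!r}")
        seen.add(pid)
        reports.append(
            Report(
                patient_id=pid,
                terms={c: tuple(v) for c, v in rec.get("terms", {}).items()},
                diagnoses=tuple(rec["diagnoses"]),
            )
        )
    return reports


def write_reports_tsv(
    reports: Iterable[Report], path, extra_header: Mapping[str, str] | None = None
) -> None:
    rows = []
    for report in reports:
        for category in INPUT_CATEGORIES:
            for text in report.terms.get(category, ()):
                rows.append((report.patient_id, category, text))
        for text in report.diagnoses:
            rows.append((report.patient_id, "diagnosis", text))
    frame = pd.DataFrame(rows, columns=["patient_id", "category", "term"])
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_reports_tsv(path) -> list[Report]:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    expected = {"patient_id", "category", "term"}
    if not expected.issubset(frame.columns):
        raise FeatureError(f"{path}: expected columns {sorted(expected)}")
    reports = []
    for pid, group in frame.groupby("patient_id", sort=False):
        terms: dict[str, list[str]] = {}
        diagnoses: list[str] = []
        for _, row in group.iterrows():
            category = row["category"]
            if category == "diagnosis":
                diagnoses.append(row["term"])
            elif category in INPUT_CATEGORIES:
                terms.setdefault(category, []).append(row["term"])
            else:
                raise FeatureError(f"{path}: unknown category {category!r} for patient {pid!r}")
        reports.append(Report(str(pid), {c: tuple(v) for c, v in terms.items()}, tuple(diagnoses)))
    return reports
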