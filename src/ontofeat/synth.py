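"""Synthetic cohort generator with a packaged mini-ontology and oracle ground truth.

Reproduces the statistical structure the pipeline assumes without restricted
data: multilabel diagnoses at the source cohort's prevalences, diagnosis-
conditioned canonical findings, and heterogeneous surface forms. Every surface
the generator emits is recorded in an oracle table, so mapping recovery is
exactly testable; surface heterogeneity is produced by (a) sampling from
per-concept synonym pools (augmented with deterministic lexical decorations
that are also written into the returned ontology) and (b) optional lexical
noise that the cascade is expected to absorb.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._text import normalize
from .features import Report
from .mapping import REVIEW_COLUMNS
from .ontology import Ontology, ontology_from_dict

CATEGORY_ORDER = ("microscopy", "immunohistochemistry", "imaging", "anatomy", "diagnosis")

#: Deterministic lexical decorations used to synthesize extra synonyms.
_ADJ = (
    "focal", "prominent", "diffuse", "patchy", "extensive", "subtle",
    "widespread", "pronounced", "scattered", "conspicuous", "marked",
    "bilateral", "multifocal", "isolated",
)
_NOUN = ("pattern", "changes", "features", "noted", "observed", "present", "evident", "seen")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ontofeat").joinpath("data", name)))


def mini_ontology() -> Ontology:
    """The packaged ~100-class fixture terminology."""
    payload = json.loads(_data_path("mini_ontology.json").read_text(encoding="utf-8"))
    return ontology_from_dict(payload, source="mini_ontology.json")


def load_concept_tables(path: str | Path | None = None) -> dict:
    source = Path(path) if path is not None else _data_path("concepts.yaml")
    return yaml.safe_load(source.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults emulate the source cohort."""

    n_patients: int = 312
    label_prevalence: Mapping[str, float] | None = None  # None → packaged defaults
    dual_pathology_rate: float = 5 / 312
    synonyms_per_concept: float = 4.0
    category_synonym_scale: Mapping[str, float] = field(
        default_factory=lambda: {
            "microscopy": 1.0,
            "immunohistochemistry": 1.0,
            "imaging": 1.0,
            "anatomy": 1.0,
            "diagnosis": 1.0,
        }
    )
    lexical_noise_rate: float = 0.2
    location_rate: float = 0.5
    target_vocab: int | None = 1328
    vocab_tolerance: float = 0.15
    seed: int = 0
    concepts_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, p in (
            ("dual_pathology_rate", self.dual_pathology_rate),
            ("lexical_noise_rate", self.lexical_noise_rate),
            ("location_rate", self.location_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")

    @classmethod
    def table2_tuned(cls, seed: int = 0) -> "GeneratorConfig":
        """Per-category synonym scales chosen so vocabulary reductions land near
        the reference per-category percentages (vocab steering disabled)."""
        return cls(
            seed=seed,
            target_vocab=None,
            synonyms_per_concept=4.0,
            category_synonym_scale={
                "microscopy": 3.5,
                "immunohistochemistry": 0.42,
                "imaging": 0.85,
                "anatomy": 0.7,
                "diagnosis": 0.6,
            },
            lexical_noise_rate=0.05,
            location_rate=0.5,
        )


@dataclass
class GroundTruth:
    """Oracle mapping table and per-patient canonical truth."""

    oracle: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)  # (normalized, category)
    surfaces: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)  # (raw, category)
    patient_truth: dict[str, dict] = field(default_factory=dict)

    def covers(self, surface: str, category: str) -> bool:
        return (surface, category) in self.surfaces

    def write_review_tsv(self, path: str | Path, extra_header: Mapping[str, str] | None = None) -> None:
        """Oracle in the reviewable-mapping TSV dialect (all rows pre-approved)."""
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in (extra_header or {}).items():
                fh.write(f"# {key}: {value}\n")
            fh.write("\t".join(REVIEW_COLUMNS) + "\n")
            for (text, category), classes in sorted(self.oracle.items()):
                fh.write(f"{text}\t{category}\t{';'.join(sorted(classes))}\treviewed\tyes\n")


# --------------------------------------------------------------------------
# sampling primitives
# --------------------------------------------------------------------------

def sample_labels(config: GeneratorConfig, rng: np.random.Generator, prevalence: Mapping[str, float]) -> list[frozenset[str]]:
    """Primary diagnosis ~ categorical(prevalence); dual pathology adds a second."""
    labels = sorted(prevalence)
    weights = np.array([float(prevalence[l]) for l in labels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("prevalences must sum to a positive value")
    if len(labels) < 2 and config.dual_pathology_rate > 0:
        raise ValueError("dual pathology requires at least two distinct labels")
    weights = weights / weights.sum()
    out: list[frozenset[str]] = []
    for _ in range(config.n_patients):
        primary = labels[rng.choice(len(labels), p=weights)]
        chosen = {primary}
        if rng.random() < config.dual_pathology_rate:
            rest = [l for l in labels if l != primary]
            rest_w = np.array([float(prevalence[l]) for l in rest])
            chosen.add(rest[rng.choice(len(rest), p=rest_w / rest_w.sum())])
        out.append(frozenset(chosen))
    return out


def sample_concepts(
    diagnoses: frozenset[str],
    tables: Mapping,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> dict[str, list[dict]]:
    """Independent inclusion draws of diagnosis-associated and background concepts."""
    for diagnosis in diagnoses:
        if diagnosis not in tables["diagnoses"]:
            raise ValueError(f"no concept table for diagnosis {diagnosis!r}")
    for _ in range(max_retries):
        chosen: dict[str, list[dict]] = {c: [] for c in CATEGORY_ORDER if c != "diagnosis"}
        seen: set[tuple[str, str]] = set()
        sources = [tables["diagnoses"][d] for d in sorted(diagnoses)] + [tables.get("background", {})]
        for source in sources:
            for category, entries in source.items():
                for entry in entries:
                    key = (category, entry["concept"])
                    if key in seen:
                        continue
                    if rng.random() < float(entry["p"]):
                        seen.add(key)
                        chosen[category].append(dict(entry))
        if any(chosen.values()):
            return chosen
    # bounded retries exhausted: force the primary diagnosis's first signature concept
    primary = sorted(diagnoses)[0]
    for category, entries in tables["diagnoses"][primary].items():
        if entries:
            chosen[category].append(dict(entries[0]))
            return chosen
    raise ValueError(f"diagnosis {primary!r} has an empty concept table")


def _apply_noise(surface: str, rng: np.random.Generator) -> str:
    """One of filler-word insertion, adjacent-token swap, or pluralization."""
    tokens = surface.split()
    op = rng.choice(["filler", "swap", "plural"], p=[0.7, 0.15, 0.15])
    if op == "swap" and len(tokens) < 2:
        op = "filler"
    if op == "filler":
        filler = ["of", "in", "at", "the"][rng.integers(0, 4)]
        pos = int(rng.integers(1, len(tokens) + 1)) if len(tokens) > 1 else 1
        tokens.insert(pos, filler)
    elif op == "swap":
        pos = int(rng.integers(0, len(tokens) - 1))
        tokens[pos], tokens[pos + 1] = tokens[pos + 1], tokens[pos]
    else:
        if not tokens[-1].endswith("s"):
            tokens[-1] = tokens[-1] + "s"
    return " ".join(tokens)


def render_surface(
    concept: str,
    category: str,
    pools: Mapping[tuple[str, str], Sequence[str]],
    config: GeneratorConfig,
    rng: np.random.Generator,
    location: str | None = None,
) -> tuple[str, frozenset[str]]:
    """One surface string plus the canonical class set it denotes."""
    pool = pools[(concept, category)]
    surface = pool[rng.integers(0, len(pool))]
    classes = {concept}
    if location is not None:
        loc_pool = pools[(location, "anatomy")]
        surface = f"{surface} in {loc_pool[rng.integers(0, len(loc_pool))]}"
        classes.add(location)
    if rng.random() < config.lexical_noise_rate:
        surface = _apply_noise(surface, rng)
    return surface, frozenset(classes)


# --------------------------------------------------------------------------
# synonym-pool augmentation
# --------------------------------------------------------------------------

def _candidate_variants(base_forms: Sequence[str], rng: np.random.Generator) -> list[str]:
    """Deterministically ordered decoration products of the base lexical forms."""
    variants: list[str] = []
    for base in base_forms:
        low = base.lower()
        variants.extend(f"{adj} {low}" for adj in _ADJ)
        variants.extend(f"{low} {noun}" for noun in _NOUN)
    for base in base_forms:
        low = base.lower()
        variants.extend(f"{adj} {low} {noun}" for adj in _ADJ for noun in _NOUN)
    order = rng.permutation(len(variants))
    return [variants[i] for i in order]


def _build_pools(
    ontology: Ontology,
    concept_categories: dict[tuple[str, str], None],
    config: GeneratorConfig,
    multiplier: float,
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str], list[str]], dict[str, set[str]]]:
    """Synonym pool per (concept, category); returns pools plus extra synonyms
    to graft onto the ontology so every pool member maps syntactically."""
    taken: set[str] = set(ontology.label_index)  # normalized forms already in use
    pools: dict[tuple[str, str], list[str]] = {}
    extra_synonyms: dict[str, set[str]] = {}
    for concept, category in sorted(concept_categories):
        cls = ontology.classes[concept]
        base = [cls.preferred_label] + sorted(cls.synonyms)
        scale = float(config.category_synonym_scale.get(category, 1.0))
        # diagnosis pools stay fixed: vocab steering inflates input-term
        # heterogeneity only, keeping the raw label space learnably sized
        effective = multiplier if category != "diagnosis" else 1.0
        exact = config.synonyms_per_concept * effective * scale
        # stochastic remainder keeps fractional mean pool sizes achievable
        size = max(1, int(exact) + (1 if rng.random() < exact - int(exact) else 0))
        pool = list(base[:size])
        if size > len(pool):
            for variant in _candidate_variants(base, rng):
                if len(pool) >= size:
                    break
                key = normalize(variant)
                if not key or key in taken:
                    continue
                taken.add(key)
                pool.append(variant)
                extra_synonyms.setdefault(concept, set()).add(variant)
        pools[(concept, category)] = pool
    return pools, extra_synonyms


def _augment_ontology(ontology: Ontology, extra_synonyms: Mapping[str, set[str]]) -> Ontology:
    if not extra_synonyms:
        return ontology
    classes = []
    for cls in ontology.classes.values():
        extras = extra_synonyms.get(cls.id)
        if extras:
            classes.append(replace(cls, synonyms=cls.synonyms | frozenset(extras)))
        else:
            classes.append(cls)
    return Ontology(classes, ontology.relations, ontology.compositions)


# --------------------------------------------------------------------------
# full corpus generation
# --------------------------------------------------------------------------

def _generate_once(
    config: GeneratorConfig,
    ontology: Ontology,
    tables: Mapping,
    prevalence: Mapping[str, float],
    multiplier: float,
) -> tuple[list[Report], GroundTruth, Ontology]:
    rng_pool = np.random.default_rng([config.seed, 1])
    rng_labels = np.random.default_rng([config.seed, 2])
    rng_corpus = np.random.default_rng([config.seed, 3])

    concept_categories: dict[tuple[str, str], None] = {}
    for block in list(tables["diagnoses"].values()) + [tables.get("background", {})]:
        for category, entries in block.items():
            for entry in entries:
                concept_categories[(entry["concept"], category)] = None
                for loc in entry.get("locations", ()):
                    concept_categories[(loc, "anatomy")] = None
    for label in prevalence:
        concept_categories[(label, "diagnosis")] = None

    pools, extra = _build_pools(ontology, concept_categories, config, multiplier, rng_pool)
    augmented = _augment_ontology(ontology, extra)

    label_sets = sample_labels(config, rng_labels, prevalence)
    reports: list[Report] = []
    truth = GroundTruth()
    width = len(str(config.n_patients))
    for i, diagnoses in enumerate(label_sets):
        pid = f"P{i + 1:0{width}d}"
        chosen = sample_concepts(diagnoses, tables, rng_corpus)
        terms: dict[str, list[str]] = {}
        canonical: dict[str, set[str]] = {}
        for category in ("microscopy", "immunohistochemistry", "imaging", "anatomy"):
            for entry in chosen.get(category, ()):
                concept = entry["concept"]
                location = None
                locations = entry.get("locations", ())
                if locations and rng_corpus.random() < config.location_rate:
                    location = locations[rng_corpus.integers(0, len(locations))]
                surface, classes = render_surface(
                    concept, category, pools, config, rng_corpus, location
                )
                terms.setdefault(category, []).append(surface)
                canonical.setdefault(category, set()).update(classes)
                truth.surfaces[(surface, category)] = classes
                truth.oracle.setdefault((normalize(surface), category), classes)
        diagnosis_surfaces = []
        for label in sorted(diagnoses):
            surface, classes = render_surface(label, "diagnosis", pools, config, rng_corpus)
            diagnosis_surfaces.append(surface)
            truth.surfaces[(surface, "diagnosis")] = classes
            truth.oracle.setdefault((normalize(surface), "diagnosis"), classes)
        reports.append(
            Report(pid, {c: tuple(v) for c, v in terms.items()}, tuple(diagnosis_surfaces))
        )
        truth.patient_truth[pid] = {
            "diagnoses": set(diagnoses),
            "concepts": {c: set(v) for c, v in canonical.items()},
        }
    return reports, truth, augmented


def distinct_vocabulary(reports: Sequence[Report]) -> int:
    """Number of distinct raw surface strings across all categories incl. diagnosis."""
    seen: set[tuple[str, str]] = set()
    for report in reports:
        for term in report.iter_terms():
            seen.add((term.text, term.category))
    return len(seen)


def generate(config: GeneratorConfig = GeneratorConfig()) -> tuple[list[Report], GroundTruth, Ontology]:
    """Full corpus + oracle + (augmented) mini-ontology, reproducible from seed.

    When ``config.target_vocab`` is set, the synonym-pool size is scaled
    iteratively until the realized distinct-surface count lands within
    ``vocab_tolerance`` of the target (warning if infeasible).
    """
    ontology = mini_ontology()
    tables = load_concept_tables(config.concepts_path)
    prevalence = dict(
        config.label_prevalence
        if config.label_prevalence is not None
        else tables["label_prevalence"]
    )
    unknown = set(prevalence) - set(tables["diagnoses"])
    if unknown:
        raise ValueError(f"labels without concept tables: {sorted(unknown)}")

    multiplier = 1.0
    result = _generate_once(config, ontology, tables, prevalence, multiplier)
    if config.target_vocab is None:
        return result
    target = config.target_vocab
    for _ in range(8):
        achieved = distinct_vocabulary(result[0])
        # steer to half the advertised tolerance so results sit inside the band
        if abs(achieved - target) <= 0.5 * config.vocab_tolerance * target:
            return result
        multiplier *= target / max(achieved, 1)
        multiplier = min(multiplier, 400.0)
        result = _generate_once(config, ontology, tables, prevalence, multiplier)
    achieved = distinct_vocabulary(result[0])
    if abs(achieved - target) > config.vocab_tolerance * target:
        warnings.warn(
            f"target_vocab {target} infeasible with the packaged concept inventory; "
            f"achieved {achieved} distinct surface terms",
            stacklevel=2,
        )
    return result
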