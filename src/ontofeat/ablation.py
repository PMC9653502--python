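"""Experiment grids: baseline/inputs/inputs+outputs comparison and Cases I–V.

Cases I–V cumulatively map microscopy, immunohistochemistry, imaging,
anatomy, and finally the diagnosis labels, in that fixed order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .features import MappingMask, Report, build_features, build_labels
from .mapping import MappingTable
from .models import (
    CVConfig,
    EvalResult,
    ModelSpec,
    cross_validate,
    relative_improvement,
    runtime_benchmark,
)

CASE_ORDER = ("baseline", "case_I", "case_II", "case_III", "case_IV", "case_V")
_CUMULATIVE = ("microscopy", "immunohistochemistry", "imaging", "anatomy")

COMPARISON_CONDITIONS = ("baseline", "inputs_mapped", "inputs_outputs_mapped")


def case_mask(name: str) -> MappingMask:
    """MappingMask for one ablation case; masks are cumulative along CASE_ORDER."""
    if name not in CASE_ORDER:
        raise ValueError(f"unknown case {name!r}; expected one of {CASE_ORDER}")
    position = CASE_ORDER.index(name)
    return MappingMask(
        mapped_categories=frozenset(_CUMULATIVE[:position]),
        labels_mapped=(name == "case_V"),
    )


def comparison_mask(condition: str) -> MappingMask:
    masks = {
        "baseline": MappingMask.all_raw(),
        "inputs_mapped": MappingMask.inputs_mapped(),
        "inputs_outputs_mapped": MappingMask.all_mapped(),
    }
    try:
        return masks[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None


@dataclass(frozen=True)
class AblationCase:
    name: str
    mask: MappingMask

    @classmethod
    def of(cls, name: str) -> "AblationCase":
        return cls(name, case_mask(name))


@dataclass
class ExperimentReport:
    """(condition/case, model kind) → EvalResult, plus derived tables."""

    grid: dict[tuple[str, str], EvalResult] = field(default_factory=dict)
    improvements: dict[str, float] = field(default_factory=dict)
    failures: dict[tuple[str, str], str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def metric_table(self, metric: str) -> pd.DataFrame:
        cases = sorted({c for c, _ in self.grid}, key=_cell_order)
        kinds = sorted({m for _, m in self.grid})
        frame = pd.DataFrame(index=cases, columns=kinds, dtype=float)
        for (case, kind), result in self.grid.items():
            frame.loc[case, kind] = getattr(result, metric)
        return frame

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "improvements": self.improvements,
            "failures": {f"{c}/{m}": msg for (c, m), msg in self.failures.items()},
            "grid": {f"{c}/{m}": r.to_dict() for (c, m), r in self.grid.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    def to_tsv(self, path, metrics: Sequence[str] = ("hamming_loss", "balanced_accuracy", "recall", "correct_count", "partially_correct_count", "runtime_seconds")) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key}: {value}\n")
            fh.write("case\tmodel\t" + "\t".join(metrics) + "\n")
            for (case, kind), result in sorted(self.grid.items(), key=lambda kv: (_cell_order(kv[0][0]), kv[0][1])):
                values = "\t".join(f"{getattr(result, m):.6g}" for m in metrics)
                fh.write(f"{case}\t{kind}\t{values}\n")


def _cell_order(case: str) -> int:
    ordering = CASE_ORDER + COMPARISON_CONDITIONS
    return ordering.index(case) if case in ordering else len(ordering)


def _evaluate_cell(
    reports: Sequence[Report],
    table: MappingTable,
    mask: MappingMask,
    spec: ModelSpec,
    cv: CVConfig,
    benchmark_executions: int = 0,
) -> EvalResult:
    features = build_features(reports, table, mask)
    labels = build_labels(reports, table, mask)
    X = features.values.to_numpy(dtype=float)
    Y = labels.values.to_numpy()
    names = list(labels.values.columns)
    result = cross_validate(X, Y, spec, cv, label_names=names)
    if benchmark_executions > 0:
        # mean-of-n wall-clock protocol over the full fit+predict CV loop
        bench = runtime_benchmark(
            lambda: cross_validate(X, Y, spec, cv, label_names=names),
            executions=benchmark_executions,
        )
        result.runtime_seconds = bench.mean_seconds
    return result


def run_comparison(
    reports: Sequence[Report],
    table: MappingTable,
    specs: Sequence[ModelSpec],
    cv: CVConfig,
) -> ExperimentReport:
    """Three-condition × three-model grid with correct-count relative improvements."""
    report = ExperimentReport(metadata={"conditions": list(COMPARISON_CONDITIONS), "cv_seed": cv.seed})
    for condition in COMPARISON_CONDITIONS:
        mask = comparison_mask(condition)
        for spec in specs:
            try:
                report.grid[(condition, spec.kind)] = _evaluate_cell(reports, table, mask, spec, cv)
            except Exception as exc:  # record failed cells with context
                report.failures[(condition, spec.kind)] = str(exc)
    for spec in specs:
        base = report.grid.get(("baseline", spec.kind))
        mapped = report.grid.get(("inputs_outputs_mapped", spec.kind))
        if base and mapped and base.correct_count > 0:
            report.improvements[spec.kind] = relative_improvement(
                base.correct_count, mapped.correct_count
            )
    return report


def run_cases(
    reports: Sequence[Report],
    table: MappingTable,
    specs: Sequence[ModelSpec],
    cv: CVConfig,
    benchmark_executions: int = 0,
) -> ExperimentReport:
    """Baseline + Cases I–V × models grid (metrics and fit+predict runtime per cell).

    With ``benchmark_executions > 0`` each cell's runtime is the mean of that
    many repeated fit+predict CV passes instead of a single timing.
    """
    report = ExperimentReport(metadata={"cases": list(CASE_ORDER), "cv_seed": cv.seed})
    for name in CASE_ORDER:
        mask = case_mask(name)
        for spec in specs:
            try:
                report.grid[(name, spec.kind)] = _evaluate_cell(
                    reports, table, mask, spec, cv, benchmark_executions
                )
            except Exception as exc:
                report.failures[(name, spec.kind)] = str(exc)
    return report
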