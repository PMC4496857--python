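"""Pre-filters applied before inheritance analysis.

Three stages, in order: functional-region triage (exonic protein-changing or
canonical splice-site), population-frequency filter (every reported frequency
must be rare), and call-quality filter. A variant survives only if it passes
all three. Variants absent from all three population databases pass the
frequency stage — rarity cannot be vetoed by absence of evidence, and novel
variants must survive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .models import (
    AnnotationRow,
    Consequence,
    VariantRecord,
)


@dataclass(frozen=True)
class FilterConfig:
    max_af: float = 0.01
    min_qual: float = 20.0
    functional_consequences: frozenset[Consequence] = frozenset(
        {
            Consequence.NONSYNONYMOUS,
            Consequence.NONSENSE,
            Consequence.FRAMESHIFT_DELETION,
            Consequence.FRAMESHIFT_INSERTION,
            Consequence.SPLICING,
        }
    )
    splice_window: int = 2

    def __post_init__(self):
        if not (0.0 < self.max_af < 1.0):
            raise ValueError("max_af must lie in (0, 1)")
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if self.splice_window < 0:
            raise ValueError("splice_window must be >= 0")


@dataclass(frozen=True)
class StageResult:
    stage: str
    passed: bool
    reason: str


@dataclass
class FilterTrace:
    variant_key: tuple
    stage_results: list[StageResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(s.passed for s in self.stage_results)


_INTRON_OFFSET = re.compile(r"c\.[\d_]+([+-])(\d+)")


def splice_offset(hgvs_c: str) -> int | None:
    """Distance from the exon boundary encoded in an intronic HGVS.c string
    (c.421-1G>A -> 1); None for purely exonic descriptions."""
    m = _INTRON_OFFSET.match(hgvs_c)
    if m is None:
        return None
    return int(m.group(2))


def filter_functional(annotation: AnnotationRow, config: FilterConfig) -> StageResult:
    """Keep exonic protein-affecting variants and canonical splice variants."""
    cons = annotation.consequence
    if cons is Consequence.SPLICING:
        offset = splice_offset(annotation.hgvs_c)
        if offset is not None and offset > config.splice_window:
            return StageResult(
                "functional", False,
                f"splice offset {offset} outside +/-{config.splice_window} bp window",
            )
        return StageResult("functional", True, "canonical splice site")
    if cons in config.functional_consequences:
        return StageResult("functional", True, cons.value)
    return StageResult("functional", False, f"non-functional consequence {cons.value}")


def filter_frequency(annotation: AnnotationRow, config: FilterConfig) -> StageResult:
    """Every *reported* population frequency must be below max_af.

    Frequencies absent from a database carry no veto: a variant unseen in all
    three databases (a novel variant) passes.
    """
    for name, af in annotation.frequencies.items():
        if af is not None and af >= config.max_af:
            return StageResult("frequency", False, f"af_{name}={af} >= {config.max_af}")
    return StageResult("frequency", True, "all reported frequencies rare or absent")


def filter_quality(record: VariantRecord, config: FilterConfig) -> StageResult:
    """Site quality must reach min_qual; qual exactly at the threshold passes."""
    if record.qual is None:
        return StageResult("quality", False, "no quality")
    if record.qual >= config.min_qual:
        return StageResult("quality", True, f"qual {record.qual:g}")
    return StageResult("quality", False, f"qual {record.qual:g} < {config.min_qual:g}")


def run_cascade(
    records: list[VariantRecord],
    annotations,
    config: FilterConfig = FilterConfig(),
    audit: bool = False,
) -> tuple[list[VariantRecord], list[FilterTrace]]:
    """Run all three stages over every record.

    Returns the surviving records (input order preserved; the survivor *set*
    is order-independent) and, in audit mode, a full per-record trace.
    Unannotated records fail with reason "unannotated" and are never dropped
    silently.
    """
    survivors: list[VariantRecord] = []
    traces: list[FilterTrace] = []
    for rec in records:
        trace = FilterTrace(variant_key=rec.key)
        ann = annotations.get(rec.key) if hasattr(annotations, "get") else None
        if ann is None:
            trace.stage_results.append(StageResult("functional", False, "unannotated"))
        else:
            stages = [
                lambda: filter_functional(ann, config),
                lambda: filter_frequency(ann, config),
                lambda: filter_quality(rec, config),
            ]
            for stage in stages:
                result = stage()
                trace.stage_results.append(result)
                if not result.passed and not audit:
                    break
        if trace.passed:
            survivors.append(rec)
        traces.append(trace)
    return survivors, (traces if audit else [t for t in traces if not t.passed])
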