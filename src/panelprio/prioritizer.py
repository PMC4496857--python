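"""Per-case-unit prioritization and cohort-level orchestration.

For a familial unit, inheritance models are inferred from the pedigree and
iterated in precedence order (AD, XL, AR); for each model, candidate
variants (or in-trans pairs) in panel genes supporting that model are
classified, and a call is emitted only when every member allele is Class
I/II and the candidate cosegregates with affection. The first model yielding
a consistent call wins. Simplex units have no pedigree information, so the
model label follows what the genotypes suggest: a qualifying heterozygote in
a dominant-capable gene, a homozygote or in-trans pair in a recessive gene,
or a hemizygote in an X-linked gene.

A single qualifying allele in a recessive-only gene is a carrier finding,
never a solving call. Every cascade survivor ends up in exactly one of:
a call, a carrier record, or a discard trace with a reason.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io_formats
from .filter_cascade import FilterConfig, run_cascade
from .inheritance_engine import (
    CompoundHetPair,
    InheritancePolicy,
    find_compound_hets,
    cosegregates,
    infer_modes,
)
from .io_formats import AnnotationTable, VcfSource
from .models import (
    Affection,
    AnnotationRow,
    CandidateCall,
    CarrierFinding,
    CaseUnit,
    Classification,
    CohortSummary,
    Genotype,
    InheritanceModel,
    PanelGene,
    PathogenicityClass,
    Pedigree,
    PhaseStatus,
    SegregationResult,
    Sex,
    TRUNCATING_CONSEQUENCES,
    UnitKind,
    VariantKey,
    VariantRecord,
    truncate_pct,
)
from .pathogenicity_classifier import ClassifierConfig, classify_members

logger = logging.getLogger("panelprio")


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterConfig = FilterConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    inheritance: InheritancePolicy = InheritancePolicy()


@dataclass(frozen=True)
class DiscardedSurvivor:
    unit_id: str
    variant_key: VariantKey
    reason: str


@dataclass
class Cohort:
    """In-memory cohort: one variant-record list per case unit plus shared
    annotation table, known-pathogenic DB and panel definition."""

    units: list[CaseUnit]
    records: dict[str, list[VariantRecord]]
    annotations: AnnotationTable
    known_db: list
    panel: dict[str, PanelGene]


# ---------------------------------------------------------------------------
# Candidate collection helpers
# ---------------------------------------------------------------------------


def _qualifying(classes: tuple[Classification, ...]) -> bool:
    return all(c.value in (PathogenicityClass.I, PathogenicityClass.II) for c in classes)


def _rank_key(call: CandidateCall):
    best = min(c.value for c in call.member_classes)
    truncating = any(a.consequence in TRUNCATING_CONSEQUENCES for a in call.variants)
    max_af = max(
        (af for a in call.variants for af in a.frequencies.values() if af is not None),
        default=0.0,
    )
    return (best, 0 if truncating else 1, max_af, call.gene)


def _genotype_label(model: InheritanceModel, n_variants: int, gt: Genotype) -> str:
    if n_variants == 2:
        return "Compound hetero"
    if gt is Genotype.HEMI:
        return "Hemi"
    if gt is Genotype.HOM_ALT:
        return "Homo"
    return "Hetero"


def _affected_genotyped(unit: CaseUnit, records: list[VariantRecord]) -> list[str]:
    sampled = set()
    for rec in records:
        sampled.update(s for s, g in rec.genotypes.items() if g is not Genotype.MISSING)
    return [
        i.iid
        for i in unit.pedigree.individuals.values()
        if i.affection is Affection.AFFECTED and (i.iid in sampled or i.iid == unit.proband_id)
    ]


def _survivors_by_gene(
    survivors: list[VariantRecord], annotations: AnnotationTable
) -> dict[str, list[VariantRecord]]:
    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in survivors:
        ann = annotations.rows.get(rec.key)
        if ann is not None:
            by_gene.setdefault(ann.gene, []).append(rec)
    return by_gene


def _model_candidates(
    model: InheritanceModel,
    unit: CaseUnit,
    by_gene: dict[str, list[VariantRecord]],
    annotations: AnnotationTable,
    panel: dict[str, PanelGene],
) -> list[tuple[str, tuple[VariantRecord, ...], Optional[PhaseStatus]]]:
    """Collect (gene, member records, phase) candidates supporting a model."""
    out = []
    affecteds = [
        i for i in unit.pedigree.individuals.values() if i.affection is Affection.AFFECTED
    ]
    for gene in sorted(by_gene):
        pg = panel.get(gene)
        if pg is None or not pg.supports(model):
            continue
        recs = by_gene[gene]
        if model is InheritanceModel.AD:
            for rec in recs:
                if any(
                    rec.genotypes.get(a.iid) in (Genotype.HET, Genotype.HOM_ALT)
                    for a in affecteds
                ):
                    out.append((gene, (rec,), None))
        elif model is InheritanceModel.XL:
            for rec in recs:
                carried = any(
                    rec.genotypes.get(a.iid)
                    in (Genotype.HEMI, Genotype.HET, Genotype.HOM_ALT)
                    for a in affecteds
                )
                if carried:
                    out.append((gene, (rec,), None))
        else:  # AR: hom-alt singles, then in-trans pairs
            rec_map = {r.key: r for r in recs}
            for rec in recs:
                if any(rec.genotypes.get(a.iid) is Genotype.HOM_ALT for a in affecteds):
                    out.append((gene, (rec,), None))
            pairs = find_compound_hets({gene: recs}, unit.proband_id, panel, unit.pedigree)
            for pair in pairs:
                if pair.phase_status is PhaseStatus.RESOLVED_CIS:
                    continue
                out.append(
                    (gene, (rec_map[pair.keys[0]], rec_map[pair.keys[1]]), pair.phase_status)
                )
    return out


# ---------------------------------------------------------------------------
# Per-unit prioritization
# ---------------------------------------------------------------------------


def prioritize_unit(
    unit: CaseUnit,
    survivors: list[VariantRecord],
    annotations: AnnotationTable,
    panel: dict[str, PanelGene],
    known_db: list,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[CandidateCall], list[CarrierFinding], list[DiscardedSurvivor]]:
    if not _affected_genotyped(unit, survivors) and not unit.pedigree.affected():
        raise ContractError(f"{unit.unit_id}: no genotyped affected individual")

    by_gene = _survivors_by_gene(survivors, annotations)
    calls: list[CandidateCall] = []

    if unit.kind is UnitKind.FAMILIAL:
        inference = infer_modes(unit.pedigree, config.inheritance)
        models = inference.models
    else:
        models = (InheritanceModel.AD, InheritanceModel.AR, InheritanceModel.XL)

    rec_index = {r.key: r for r in survivors}
    collected: list[CandidateCall] = []
    for model in models:
        model_calls: list[CandidateCall] = []
        for gene, members, phase in _model_candidates(model, unit, by_gene, annotations, panel):
            anns = tuple(annotations.rows[m.key] for m in members)
            classes = classify_members(anns, annotations, known_db, config.classifier)
            if not _qualifying(classes):
                continue
            seg: Optional[SegregationResult] = None
            if unit.kind is UnitKind.FAMILIAL:
                seg = cosegregates(
                    tuple(m.key for m in members),
                    rec_index,
                    unit.pedigree,
                    model,
                    config.inheritance,
                )
                if not seg.consistent:
                    continue
            else:
                # simplex sanity: proband genotype must fit the model shape
                gt = members[0].genotypes.get(unit.proband_id)
                sex = unit.pedigree.individuals[unit.proband_id].sex
                if model is InheritanceModel.AD and gt not in (Genotype.HET, Genotype.HOM_ALT):
                    continue
                if model is InheritanceModel.XL and gt is not Genotype.HEMI:
                    continue
                if model is InheritanceModel.AR and len(members) == 1 and gt is not Genotype.HOM_ALT:
                    continue
            gt = members[0].genotypes.get(unit.proband_id, Genotype.MISSING)
            model_calls.append(
                CandidateCall(
                    unit_id=unit.unit_id,
                    gene=gene,
                    model=model,
                    variants=anns,
                    member_classes=classes,
                    genotype_label=_genotype_label(model, len(members), gt),
                    phase_status=phase,
                    segregation=seg,
                )
            )
        if unit.kind is UnitKind.FAMILIAL:
            if model_calls:
                model_calls.sort(key=_rank_key)
                calls = [
                    dataclasses.replace(c, primary=(i == 0))
                    for i, c in enumerate(model_calls)
                ]
                break  # first model with a consistent call wins
        else:
            collected.extend(model_calls)

    if unit.kind is UnitKind.SIMPLEX and collected:
        # the genotypes, not the pedigree, suggest the model: a single-variant
        # call whose allele belongs to a recessive call in the same gene is
        # subsumed by it (two qualifying hets in one gene read as in trans)
        ar_keys = {
            (c.gene, a.variant_key)
            for c in collected
            if c.model is InheritanceModel.AR
            for a in c.variants
        }
        kept = [
            c
            for c in collected
            if not (
                c.model is not InheritanceModel.AR
                and len(c.variants) == 1
                and (c.gene, c.variants[0].variant_key) in ar_keys
            )
        ]
        kept.sort(key=_rank_key)
        calls = [dataclasses.replace(c, primary=(i == 0)) for i, c in enumerate(kept)]

    called_keys = {a.variant_key for c in calls for a in c.variants}

    # carrier findings: qualifying single alleles in recessive-only genes
    carriers: list[CarrierFinding] = []
    for gene in sorted(by_gene):
        pg = panel.get(gene)
        if pg is None or not pg.supports(InheritanceModel.AR):
            continue
        for rec in by_gene[gene]:
            if rec.key in called_keys:
                continue
            gt = rec.genotypes.get(unit.proband_id)
            if gt is not Genotype.HET:
                continue
            ann = annotations.rows[rec.key]
            cls = classify_members((ann,), annotations, known_db, config.classifier)[0]
            if cls.value in (PathogenicityClass.I, PathogenicityClass.II):
                carriers.append(
                    CarrierFinding(
                        unit_id=unit.unit_id,
                        gene=gene,
                        variant=ann,
                        classification=cls,
                        reason="single qualifying allele without a qualifying counter-allele",
                    )
                )

    carrier_keys = {c.variant.variant_key for c in carriers}
    discarded = [
        DiscardedSurvivor(
            unit_id=unit.unit_id,
            variant_key=rec.key,
            reason="no qualifying class/model/segregation support",
        )
        for rec in survivors
        if rec.key not in called_keys and rec.key not in carrier_keys
    ]
    return calls, carriers, discarded


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


def summarize_cohort(
    calls: list[CandidateCall],
    carriers: list[CarrierFinding],
    units: list[CaseUnit],
) -> CohortSummary:
    if not units:
        raise ContractError("cohort has zero case units")
    primaries = {c.unit_id: c for c in calls if c.primary}
    n_familial = sum(1 for u in units if u.kind is UnitKind.FAMILIAL)
    n_simplex = len(units) - n_familial
    solved_familial = sum(
        1 for u in units if u.kind is UnitKind.FAMILIAL and u.unit_id in primaries
    )
    solved_simplex = sum(
        1 for u in units if u.kind is UnitKind.SIMPLEX and u.unit_id in primaries
    )
    solved = solved_familial + solved_simplex

    distinct: dict[VariantKey, AnnotationRow] = {}
    for call in calls:
        for ann in call.variants:
            distinct[ann.variant_key] = ann
    n_novel = sum(1 for a in distinct.values() if a.reference_status.is_novel)
    novel_fraction = truncate_pct(100.0 * n_novel / len(distinct)) if distinct else 0.0

    def gene_shares(model: Optional[InheritanceModel]) -> dict[str, float]:
        pool = [
            c for c in primaries.values() if model is None or c.model is model
        ]
        if not pool:
            return {}
        return {
            gene: truncate_pct(100.0 * sum(1 for c in pool if c.gene == gene) / len(pool))
            for gene in sorted({c.gene for c in pool})
        }

    per_gene = {
        "overall": gene_shares(None),
        "AD": gene_shares(InheritanceModel.AD),
        "AR": gene_shares(InheritanceModel.AR),
        "XL": gene_shares(InheritanceModel.XL),
    }
    compound_het_count = sum(1 for c in primaries.values() if len(c.variants) == 2)
    simplex_solved_calls = [
        primaries[u.unit_id]
        for u in units
        if u.kind is UnitKind.SIMPLEX and u.unit_id in primaries
    ]
    simplex_ar_share = (
        truncate_pct(
            100.0
            * sum(1 for c in simplex_solved_calls if c.model is InheritanceModel.AR)
            / len(simplex_solved_calls)
        )
        if simplex_solved_calls
        else 0.0
    )
    overall_rate = truncate_pct(100.0 * solved / len(units))
    return CohortSummary(
        n_familial=n_familial,
        n_simplex=n_simplex,
        solved_familial=solved_familial,
        solved_simplex=solved_simplex,
        overall_rate=overall_rate,
        novel_fraction=novel_fraction,
        per_gene_counts=per_gene,
        compound_het_count=compound_het_count,
        single_allele_carriers=tuple(carriers),
        n_candidate_variants=len(distinct),
        simplex_ar_share=simplex_ar_share,
    )


# ---------------------------------------------------------------------------
# End-to-end runs
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    calls: list[CandidateCall]
    carriers: list[CarrierFinding]
    discarded: list[DiscardedSurvivor]
    summary: CohortSummary
    survivor_counts: dict[str, int] = field(default_factory=dict)


def run_cohort(cohort: Cohort, config: PipelineConfig = PipelineConfig()) -> CohortResult:
    """Cascade -> per-unit prioritization -> classification -> summary."""
    all_calls: list[CandidateCall] = []
    all_carriers: list[CarrierFinding] = []
    all_discarded: list[DiscardedSurvivor] = []
    survivor_counts: dict[str, int] = {}
    for unit in cohort.units:
        records = cohort.records.get(unit.unit_id, [])
        survivors, _ = run_cascade(records, cohort.annotations, config.filter)
        survivor_counts[unit.unit_id] = len(survivors)
        logger.info(
            "%s: %d records, %d cascade survivors", unit.unit_id, len(records), len(survivors)
        )
        calls, carriers, discarded = prioritize_unit(
            unit, survivors, cohort.annotations, cohort.panel, cohort.known_db, config
        )
        all_calls.extend(calls)
        all_carriers.extend(carriers)
        all_discarded.extend(discarded)
    summary = summarize_cohort(all_calls, all_carriers, cohort.units)
    logger.info(
        "cohort: %d/%d familial, %d/%d simplex solved",
        summary.solved_familial,
        summary.n_familial,
        summary.solved_simplex,
        summary.n_simplex,
    )
    return CohortResult(all_calls, all_carriers, all_discarded, summary, survivor_counts)


_CONFIG_KEYS = {"inputs", "filter", "classifier", "inheritance", "output"}
_INPUT_KEYS = {"vcf", "ped", "annotations", "known_db", "panel"}


class ConfigError(ValueError):
    pass


def _build_section(cls, block: dict, name: str):
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigError(f"config section {name!r}: {exc}") from exc


def load_config(path: str | Path) -> tuple[dict, PipelineConfig]:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    inputs = raw.get("inputs", {})
    missing = {"vcf", "ped", "annotations", "known_db", "panel"} - set(inputs)
    if missing:
        raise ConfigError(f"{path}: inputs missing keys {sorted(missing)}")
    fcfg = dict(raw.get("filter", {}))
    if "functional_consequences" in fcfg:
        from .models import Consequence

        fcfg["functional_consequences"] = frozenset(
            Consequence(c) for c in fcfg["functional_consequences"]
        )
    config = PipelineConfig(
        filter=_build_section(FilterConfig, fcfg, "filter"),
        classifier=_build_section(ClassifierConfig, raw.get("classifier", {}), "classifier"),
        inheritance=_build_section(InheritancePolicy, raw.get("inheritance", {}), "inheritance"),
    )
    return raw, config


def _unit_from_files(vcf_path: str, ped_path: str) -> tuple[CaseUnit, list[VariantRecord]]:
    ped = io_formats.read_ped(ped_path)
    source = VcfSource.from_path(vcf_path)
    io_formats.reconcile_samples(source, ped)
    records = io_formats.read_vcf(source)
    records = io_formats.normalize_hemizygous(records, ped)
    affected = ped.affected()
    proband = affected[0].iid if affected else next(iter(ped.individuals))
    kind = UnitKind.FAMILIAL if len(ped.individuals) > 1 else UnitKind.SIMPLEX
    unit = CaseUnit(
        unit_id=ped.family_id, kind=kind, pedigree=ped, proband_id=proband
    )
    return unit, records


def run_pipeline(config_path: str | Path) -> tuple[Path, CohortSummary]:
    """File-driven end-to-end run. Returns (report path, summary)."""
    raw, config = load_config(config_path)
    inputs = raw["inputs"]
    base = Path(config_path).parent

    def resolve(p) -> str:
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    vcfs = inputs["vcf"] if isinstance(inputs["vcf"], list) else [inputs["vcf"]]
    peds = inputs["ped"] if isinstance(inputs["ped"], list) else [inputs["ped"]]
    vcfs, peds = [resolve(p) for p in vcfs], [resolve(p) for p in peds]
    ann_path, known_path, panel_path = (
        resolve(inputs["annotations"]),
        resolve(inputs["known_db"]),
        resolve(inputs["panel"]),
    )
    if len(vcfs) != len(peds):
        raise ConfigError("inputs.vcf and inputs.ped must pair up one-to-one")
    for p in [*vcfs, *peds, ann_path, known_path, panel_path]:
        if not Path(p).exists():
            raise ConfigError(f"input file missing: {p}")

    annotations = io_formats.read_annotations(ann_path)
    known_db = io_formats.read_known_db(known_path)
    panel = io_formats.read_panel(panel_path)

    units, records = [], {}
    for vcf_path, ped_path in zip(vcfs, peds):
        unit, recs = _unit_from_files(vcf_path, ped_path)
        units.append(unit)
        records[unit.unit_id] = recs

    cohort = Cohort(units, records, annotations, known_db, panel)
    result = run_cohort(cohort, config)

    out_dir = Path(resolve(raw.get("output", {}).get("dir", ".")))
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "report.tsv"
    io_formats.write_report(result.calls, result.summary, report_path)
    if raw.get("output", {}).get("audit_trace"):
        trace_path = out_dir / "discarded.tsv"
        lines = ["unit_id\tchrom\tpos\tref\talt\treason"]
        for d in sorted(result.discarded, key=lambda d: (d.unit_id, d.variant_key)):
            k = d.variant_key
            lines.append(f"{d.unit_id}\t{k[0]}\t{k[1]}\t{k[2]}\t{k[3]}\t{d.reason}")
        trace_path.write_text("\n".join(lines) + "\n")
    return report_path, result.summary
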