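"""Readers and writers for the pipeline's external representations.

Formats handled: VCF 4.2 (via pysam), 6-column PED, the annotation TSV
(fixed header, one row per normalized variant key), the known-pathogenic TSV,
the panel TSV, and the report TSV + JSON summary. All writers are
deterministic: identical inputs produce identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam

from .models import (
    Affection,
    AnnotationRow,
    CandidateCall,
    CohortSummary,
    Consequence,
    Genotype,
    Individual,
    KnownPathogenicEntry,
    PanelGene,
    Pedigree,
    PedigreeError,
    PolyPhen2,
    PredictorOutputs,
    ReferenceStatus,
    Sex,
    Sift,
    VariantKey,
    VariantRecord,
    normalize_variant,
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VcfSource:
    """Handle on one VCF file plus the header facts the pipeline needs."""

    path: str
    sample_ids: tuple[str, ...]
    contig_names: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.sample_ids:
            raise FormatError(f"{self.path}: VCF declares no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"{self.path}: duplicate sample ids")

    @classmethod
    def from_path(cls, path: str | Path) -> "VcfSource":
        path = str(path)
        try:
            with pysam.VariantFile(path) as vf:
                return cls(
                    path=path,
                    sample_ids=tuple(vf.header.samples),
                    contig_names=tuple(vf.header.contigs),
                )
        except (ValueError, OSError) as exc:
            raise FormatError(f"{path}: malformed VCF header ({exc})") from exc


def _map_genotype(alleles: Optional[tuple], alt_index: int) -> Genotype:
    """Map a pysam GT tuple onto the decomposed record for one alt allele."""
    if alleles is None or all(a is None for a in alleles):
        return Genotype.MISSING
    called = [a for a in alleles if a is not None]
    n_alt = sum(1 for a in called if a == alt_index)
    if len(called) == 1:  # haploid call => hemizygous context
        return Genotype.HEMI if n_alt == 1 else Genotype.HOM_REF
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(called):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(source: VcfSource) -> list[VariantRecord]:
    """Read a VCF into decomposed, minimally-represented variant records.

    Multi-allelic sites yield one record per alt allele, all sharing the
    site's chrom/pos/ref before normalization; QUAL is carried verbatim.
    """
    records: list[VariantRecord] = []
    try:
        vf = pysam.VariantFile(source.path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{source.path}: malformed VCF header ({exc})") from exc
    with vf:
        for site in vf:
            alts = site.alts or ()
            for i, alt in enumerate(alts, start=1):
                if alt is None or alt.startswith("<"):
                    continue  # symbolic alleles are out of scope
                pos, ref, alt_n = normalize_variant(site.pos, site.ref, alt)
                genotypes = {
                    s: _map_genotype(site.samples[s].get("GT"), i)
                    for s in source.sample_ids
                }
                records.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt_n,
                        qual=site.qual,
                        genotypes=genotypes,
                    )
                )
    return records


def normalize_hemizygous(records: Iterable[VariantRecord], ped: Pedigree) -> list[VariantRecord]:
    """Recode male X-chromosome hom_alt calls ("1/1") as hemizygous."""
    out = []
    for rec in records:
        if rec.chrom in ("X", "chrX"):
            genotypes = dict(rec.genotypes)
            for sid, gt in genotypes.items():
                ind = ped.individuals.get(sid)
                if ind is not None and ind.sex is Sex.MALE and gt is Genotype.HOM_ALT:
                    genotypes[sid] = Genotype.HEMI
            rec = VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt, rec.qual, genotypes)
        out.append(rec)
    return out


def reconcile_samples(source: VcfSource, ped: Pedigree) -> None:
    """Fail loudly when VCF samples and pedigree members disagree."""
    vcf_only = set(source.sample_ids) - set(ped.individuals)
    if vcf_only:
        raise FormatError(
            f"{source.path}: VCF samples absent from pedigree "
            f"{ped.family_id}: {sorted(vcf_only)}"
        )


def write_vcf(
    path: str | Path,
    sample_ids: list[str],
    records: list[VariantRecord],
    contigs: tuple[str, ...] = tuple([str(c) for c in range(1, 23)] + ["X"]),
) -> VcfSource:
    """Write records as an uncompressed VCF 4.2 text file (deterministic)."""
    gt_repr = {
        Genotype.HOM_REF: "0/0",
        Genotype.HET: "0/1",
        Genotype.HOM_ALT: "1/1",
        Genotype.HEMI: "1",
        Genotype.MISSING: "./.",
    }
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    order = {c: i for i, c in enumerate(contigs)}
    for rec in sorted(records, key=lambda r: (order.get(r.chrom, 99), r.pos, r.ref, r.alt)):
        qual = "." if rec.qual is None else f"{rec.qual:.2f}"
        gts = "\t".join(gt_repr[rec.genotypes.get(s, Genotype.MISSING)] for s in sample_ids)
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t{qual}\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return VcfSource(path=str(path), sample_ids=tuple(sample_ids), contig_names=contigs)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFF_CODE = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}


def read_ped(path: str | Path) -> Pedigree:
    """Parse a 6-column whitespace-delimited PED file into one pedigree."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise PedigreeError(f"{path}: empty pedigree file")
    family_id = None
    individuals: dict[str, Individual] = {}
    for n, line in enumerate(lines, start=1):
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}:{n}: expected 6 PED columns, got {len(fields)}")
        fid, iid, father, mother, sex, aff = fields[:6]
        if family_id is None:
            family_id = fid
        elif fid != family_id:
            raise FormatError(f"{path}:{n}: multiple family ids in one file")
        if iid in individuals:
            raise FormatError(f"{path}:{n}: duplicate individual id {iid}")
        individuals[iid] = Individual(
            iid=iid,
            father=None if father == "0" else father,
            mother=None if mother == "0" else mother,
            sex=_SEX_CODE.get(sex, Sex.UNKNOWN),
            affection=_AFF_CODE.get(aff, Affection.UNKNOWN),
        )
    return Pedigree(family_id=family_id, individuals=individuals)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_code = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}
    lines = [
        "\t".join(
            [
                ped.family_id,
                ind.iid,
                ind.father or "0",
                ind.mother or "0",
                sex_code[ind.sex],
                aff_code[ind.affection],
            ]
        )
        for ind in ped.individuals.values()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "exon",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "reference",
    "af_evs",
    "af_1kg",
    "af_inhouse",
    "polyphen2",
    "sift",
    "mutpred",
]


@dataclass
class AnnotationTable(Mapping):
    """Annotation rows keyed by normalized variant key, plus the in-silico
    predictor outputs consumed by the classifier."""

    rows: dict[VariantKey, AnnotationRow] = field(default_factory=dict)
    predictors: dict[VariantKey, PredictorOutputs] = field(default_factory=dict)

    def __getitem__(self, key: VariantKey) -> AnnotationRow:
        return self.rows[key]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def add(self, row: AnnotationRow, pred: PredictorOutputs = PredictorOutputs()) -> None:
        if row.variant_key in self.rows:
            raise FormatError(f"duplicate annotation key {row.variant_key}")
        self.rows[row.variant_key] = row
        self.predictors[row.variant_key] = pred

    def predictors_for(self, key: VariantKey) -> PredictorOutputs:
        return self.predictors.get(key, PredictorOutputs())


def _parse_freq(cell, path, n) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return None
    value = float(cell)
    if not (0.0 <= value <= 1.0):
        raise FormatError(f"{path}: row {n}: frequency {value} outside [0, 1]")
    return value


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read the annotation TSV; duplicate variant keys are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    table = AnnotationTable()
    for n, row in enumerate(df.itertuples(index=False), start=2):
        key: VariantKey = (row.chrom, int(row.pos), row.ref, row.alt)
        ann = AnnotationRow(
            variant_key=key,
            gene=row.gene,
            exon=int(row.exon),
            hgvs_c=row.hgvs_c,
            hgvs_p=row.hgvs_p,
            consequence=Consequence(row.consequence),
            af_evs=_parse_freq(row.af_evs, path, n),
            af_1kg=_parse_freq(row.af_1kg, path, n),
            af_inhouse=_parse_freq(row.af_inhouse, path, n),
            reference_status=ReferenceStatus(row.reference),
        )
        pred = PredictorOutputs(
            polyphen2=PolyPhen2(row.polyphen2) if row.polyphen2 else PolyPhen2.MISSING,
            sift=Sift(row.sift) if row.sift else Sift.MISSING,
            mutpred=float(row.mutpred) if str(row.mutpred).strip() else None,
        )
        table.add(ann, pred)
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for key in sorted(table.rows):
        ann = table.rows[key]
        pred = table.predictors_for(key)
        lines.append(
            "\t".join(
                [
                    key[0],
                    str(key[1]),
                    key[2],
                    key[3],
                    ann.gene,
                    str(ann.exon),
                    ann.hgvs_c,
                    ann.hgvs_p,
                    ann.consequence.value,
                    ann.reference_status.label or "novel",
                    "" if ann.af_evs is None else repr(ann.af_evs),
                    "" if ann.af_1kg is None else repr(ann.af_1kg),
                    "" if ann.af_inhouse is None else repr(ann.af_inhouse),
                    "" if pred.polyphen2 is PolyPhen2.MISSING else pred.polyphen2.value,
                    "" if pred.sift is Sift.MISSING else pred.sift.value,
                    "" if pred.mutpred is None else repr(pred.mutpred),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Known-pathogenic DB and panel
# ---------------------------------------------------------------------------


def read_known_db(path: str | Path) -> list[KnownPathogenicEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        KnownPathogenicEntry(
            gene=r.gene, hgvs_c=r.hgvs_c, hgvs_p=r.hgvs_p, rsid=r.rsid, citation=r.citation
        )
        for r in df.itertuples(index=False)
    ]


_MODE_WORDS = {
    "AD": frozenset({"AD"}),
    "AR": frozenset({"AR"}),
    "AR/AD": frozenset({"AD", "AR"}),
    "AD/AR": frozenset({"AD", "AR"}),
    "X-linked": frozenset({"XL"}),
    "XL": frozenset({"XL"}),
    "digenic": frozenset({"digenic"}),
}


def read_panel(path: str | Path) -> dict[str, PanelGene]:
    """Read the panel TSV (gene, inheritance, refseq, cytoband, exon_count)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    panel: dict[str, PanelGene] = {}
    for n, r in enumerate(df.itertuples(index=False), start=2):
        if r.gene in panel:
            raise FormatError(f"{path}: row {n}: duplicate panel gene {r.gene}")
        if r.inheritance not in _MODE_WORDS:
            raise FormatError(f"{path}: row {n}: unknown inheritance {r.inheritance!r}")
        panel[r.gene] = PanelGene(
            gene=r.gene,
            modes=_MODE_WORDS[r.inheritance],
            refseq=r.refseq,
            cytoband=r.cytoband,
            exon_count=int(r.exon_count),
        )
    return panel


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "unit_id",
    "gene",
    "model",
    "genotype",
    "chrom",
    "pos",
    "ref",
    "alt",
    "exon",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "reference",
    "class",
    "phase",
    "cosegregation",
    "confirmed",
    "primary",
]


def summary_dict(summary: CohortSummary) -> dict:
    return {
        "n_familial": summary.n_familial,
        "n_simplex": summary.n_simplex,
        "solved_familial": summary.solved_familial,
        "solved_simplex": summary.solved_simplex,
        "familial_rate_pct": summary.familial_rate,
        "simplex_rate_pct": summary.simplex_rate,
        "overall_rate_pct": summary.overall_rate,
        "novel_fraction_pct": summary.novel_fraction,
        "n_candidate_variants": summary.n_candidate_variants,
        "compound_het_count": summary.compound_het_count,
        "simplex_ar_share_pct": summary.simplex_ar_share,
        "per_gene_counts": summary.per_gene_counts,
        "single_allele_carriers": [
            {
                "unit_id": c.unit_id,
                "gene": c.gene,
                "hgvs_c": c.variant.hgvs_c,
                "class": c.classification.value.roman,
                "reason": c.reason,
            }
            for c in summary.single_allele_carriers
        ],
    }


def write_report(calls: list[CandidateCall], summary: CohortSummary, path: str | Path) -> None:
    """Write the candidate-call TSV plus a JSON summary next to it.

    Rows are ordered by (unit id, gene, position); re-running on identical
    input is byte-identical.
    """
    path = Path(path)
    lines = ["\t".join(REPORT_COLUMNS)]
    entries = []
    for call in calls:
        for ann, cls in zip(call.variants, call.member_classes):
            entries.append((call.unit_id, call.gene, ann.variant_key[1], call, ann, cls))
    for unit_id, gene, pos, call, ann, cls in sorted(entries, key=lambda e: e[:3]):
        seg = "na" if call.segregation is None else ("consistent" if call.segregation.consistent else "inconsistent")
        lines.append(
            "\t".join(
                [
                    unit_id,
                    gene,
                    call.model.value,
                    call.genotype_label,
                    ann.variant_key[0],
                    str(ann.variant_key[1]),
                    ann.variant_key[2],
                    ann.variant_key[3],
                    str(ann.exon),
                    ann.hgvs_c,
                    ann.hgvs_p,
                    ann.consequence.value,
                    str(ann.reference_status),
                    cls.value.roman,
                    call.phase_status.value if call.phase_status else "na",
                    seg,
                    "yes" if call.confirmed else "no",
                    "yes" if call.primary else "no",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    summary_path = path.with_suffix(".summary.json")
    summary_path.write_text(json.dumps(summary_dict(summary), indent=2, sort_keys=True) + "\n")
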