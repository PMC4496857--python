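"""Packaged cohort fixtures: 18 familial and 16 simplex case units.

The ten solved families and seven solved simplex patients carry the
candidate variants shipped in the package's candidate tables (gene, exon,
HGVS, consequence, reference status and the one reported in-house frequency
are verbatim; genomic coordinates are synthetic, derived from per-gene locus
blocks plus the HGVS coding offset). The remaining eight families and nine
simplex patients carry deterministic synthetic background only.

Pedigree structures are minimal reconstructions consistent with the
affection patterns each family is described to show: dominant families have
affected carriers in every generation with male-to-male transmission; one
X-linked family has a skipped-generation carrier female; the other shows the
dominant-looking X-linked pattern with affected heterozygous females and no
male-to-male transmission.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from . import io_formats, synthetic_data
from .io_formats import AnnotationTable
from .models import (
    Affection,
    AnnotationRow,
    Consequence,
    Genotype,
    Individual,
    KnownPathogenicEntry,
    PanelGene,
    PathogenicityClass,
    Pedigree,
    PolyPhen2,
    PredictorOutputs,
    ReferenceStatus,
    Sex,
    Sift,
    UnitKind,
    VariantRecord,
    CaseUnit,
)
from .prioritizer import Cohort
from .synthetic_data import LocusAllocator, SimulationConfig

#: Seed recorded for the packaged cohort's background variation.
FIXTURE_SEED = 20150709

FIXTURE_NAMES = ("table1_families", "table2_simplex", "full_cohort")


class FixtureError(KeyError):
    pass


def _data_path(name: str):
    return resources.files("panelprio.data") / name


def load_default_panel() -> dict[str, PanelGene]:
    return io_formats.read_panel(str(_data_path("panel_genes.tsv")))


def load_default_known_db() -> list[KnownPathogenicEntry]:
    return io_formats.read_known_db(str(_data_path("known_pathogenic.tsv")))


# ---------------------------------------------------------------------------
# HGVS -> synthetic variant alleles
# ---------------------------------------------------------------------------

_SNV = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_DEL = re.compile(r"^c\.(\d+)_(\d+)del([ACGT]+)$")
_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


def hgvs_to_alleles(hgvs_c: str) -> tuple[int, str, str]:
    """Map an HGVS.c description to (coding offset, ref, alt).

    Indel anchor bases are synthetic (no transcript sequence is modelled);
    the offset is the first coding position named in the description.
    """
    hgvs = hgvs_c.replace(" ", "")
    m = _SNV.match(hgvs)
    if m:
        offset = int(m.group(1)) + (int(m.group(2)) if m.group(2) else 0)
        return offset, m.group(3), m.group(4)
    m = _DEL.match(hgvs)
    if m:
        return int(m.group(1)), "A" + m.group(3), "A"
    m = _INS.match(hgvs)
    if m:
        return int(m.group(1)), "G", "G" + m.group(3)
    raise ValueError(f"unsupported HGVS.c form: {hgvs_c!r}")


# ---------------------------------------------------------------------------
# Pedigree reconstructions
# ---------------------------------------------------------------------------


def _build(fid: str, rows) -> Pedigree:
    individuals = {}
    for iid, father, mother, sex, aff in rows:
        individuals[iid] = Individual(
            iid=iid,
            father=father,
            mother=mother,
            sex=sex,
            affection=aff,
        )
    return Pedigree(family_id=fid, individuals=individuals)


_M, _F = Sex.MALE, Sex.FEMALE
_A, _U = Affection.AFFECTED, Affection.UNAFFECTED


def _ad_family(fid: str) -> tuple[Pedigree, dict[str, Genotype]]:
    """Three generations, affected carriers in every one, male-to-male."""
    ped = _build(
        fid,
        [
            ("I-1", None, None, _M, _A),
            ("I-2", None, None, _F, _U),
            ("II-1", "I-1", "I-2", _M, _A),
            ("II-2", None, None, _F, _U),
            ("II-3", "I-1", "I-2", _F, _U),
            ("III-1", "II-1", "II-2", _M, _A),
            ("III-2", "II-1", "II-2", _F, _U),
        ],
    )
    gts = {
        "I-1": Genotype.HET,
        "II-1": Genotype.HET,
        "III-1": Genotype.HET,
    }
    return ped, {i: gts.get(i, Genotype.HOM_REF) for i in ped.individuals}


def _xl_skipped_family(fid: str) -> tuple[Pedigree, dict[str, Genotype]]:
    """Affected hemizygous males in alternating generations through an
    unaffected carrier female; no affected heterozygous females."""
    ped = _build(
        fid,
        [
            ("I-1", None, None, _M, _A),
            ("I-2", None, None, _F, _U),
            ("II-1", "I-1", "I-2", _F, _U),
            ("II-2", None, None, _M, _U),
            ("III-1", "II-1", "II-2", _M, _A),
            ("III-2", "II-1", "II-2", _M, _U),
        ],
    )
    gts = {
        "I-1": Genotype.HEMI,
        "II-1": Genotype.HET,
        "III-1": Genotype.HEMI,
    }
    return ped, {i: gts.get(i, Genotype.HOM_REF) for i in ped.individuals}


def _xl_manifesting_family(fid: str) -> tuple[Pedigree, dict[str, Genotype]]:
    """Dominant-looking X-linked pattern: affected hemizygous males plus
    affected heterozygous females, one unaffected carrier female, and no
    male-to-male transmission."""
    ped = _build(
        fid,
        [
            ("I-1", None, None, _M, _A),
            ("I-2", None, None, _F, _U),
            ("II-1", "I-1", "I-2", _F, _A),
            ("II-2", None, None, _M, _U),
            ("II-3", "I-1", "I-2", _F, _A),
            ("III-1", "II-1", "II-2", _M, _A),
            ("III-2", "II-1", "II-2", _F, _A),
            ("III-3", "II-1", "II-2", _F, _U),
        ],
    )
    gts = {
        "I-1": Genotype.HEMI,
        "II-1": Genotype.HET,
        "II-3": Genotype.HET,
        "III-1": Genotype.HEMI,
        "III-2": Genotype.HET,
        "III-3": Genotype.HET,  # unaffected carrier: variable penetrance
    }
    return ped, {i: gts.get(i, Genotype.HOM_REF) for i in ped.individuals}


def _negative_family(fid: str, shape: str) -> Pedigree:
    """Background-only families whose affection pattern matches the stated
    inheritance without any qualifying variant."""
    if shape == "AD":
        ped, _ = _ad_family(fid)
        return ped
    if shape == "XL":
        ped, _ = _xl_skipped_family(fid)
        return ped
    # AR shape: affected sibs of both sexes born to unaffected parents
    return _build(
        fid,
        [
            ("I-1", None, None, _M, _U),
            ("I-2", None, None, _F, _U),
            ("II-1", "I-1", "I-2", _M, _U),
            ("II-2", None, None, _F, _U),
            ("III-1", "II-1", "II-2", _M, _A),
            ("III-2", "II-1", "II-2", _F, _A),
            ("III-3", "II-1", "II-2", _F, _U),
        ],
    )


_FAMILY_SHAPES = {
    # solved (candidate tables)
    "F03": "AD", "F06": "AD", "F07": "AD", "F09": "AD", "F10": "AD",
    "F13": "AD", "XF1": "AD", "XF3": "AD",
    "F04": "XL-skipped", "F12": "XL-manifesting",
    # unsolved, background only; shapes chosen so the cohort keeps the
    # described 10 dominant / 5 recessive / 3 X-linked family mix
    "F01": "AR", "F02": "AR", "F05": "AR", "F08": "AR", "XF4": "AR",
    "F11": "AD", "F14": "AD", "XF2": "XL",
}

_FAMILIAL_ORDER = [
    "F01", "F02", "F03", "F04", "F05", "F06", "F07", "F08", "F09", "F10",
    "F11", "F12", "F13", "F14", "XF1", "XF2", "XF3", "XF4",
]

_SIMPLEX_SOLVED = ["430", "432", "436", "438", "439", "440", "445"]
_SIMPLEX_UNSOLVED = ["431", "433", "434", "435", "437", "441", "443", "444", "450"]
_SIMPLEX_ORDER = sorted(_SIMPLEX_SOLVED + _SIMPLEX_UNSOLVED)


def _family_pedigree(fid: str) -> tuple[Pedigree, Optional[dict[str, Genotype]]]:
    shape = _FAMILY_SHAPES[fid]
    if shape == "XL-skipped":
        ped, gts = _xl_skipped_family(fid)
    elif shape == "XL-manifesting":
        ped, gts = _xl_manifesting_family(fid)
    elif fid in ("F03", "F06", "F07", "F09", "F10", "F13", "XF1", "XF3"):
        ped, gts = _ad_family(fid)
    else:
        return _negative_family(fid, shape), None
    return ped, gts


# ---------------------------------------------------------------------------
# Candidate tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureCandidate:
    unit_id: str
    inheritance: str
    gene: str
    genotype: str
    chrom: str
    exon: int
    hgvs_c: str
    hgvs_p: str
    consequence: Consequence
    reference: str
    af_evs: Optional[float]
    af_1kg: Optional[float]
    af_inhouse: Optional[float]
    predictors: PredictorOutputs
    printed_class: PathogenicityClass


def _read_candidates(which: str) -> list[FixtureCandidate]:
    df = pd.read_csv(str(_data_path(which)), sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            FixtureCandidate(
                unit_id=r.unit_id,
                inheritance=r.inheritance,
                gene=r.gene,
                genotype=r.genotype,
                chrom=r.chrom,
                exon=int(r.exon),
                hgvs_c=r.hgvs_c,
                hgvs_p=r.hgvs_p,
                consequence=Consequence(r.consequence),
                reference=r.reference,
                af_evs=float(r.af_evs) if r.af_evs else None,
                af_1kg=float(r.af_1kg) if r.af_1kg else None,
                af_inhouse=float(r.af_inhouse) if r.af_inhouse else None,
                predictors=PredictorOutputs(
                    polyphen2=PolyPhen2(r.polyphen2) if r.polyphen2 else PolyPhen2.MISSING,
                    sift=Sift(r.sift) if r.sift else Sift.MISSING,
                    mutpred=float(r.mutpred) if r.mutpred else None,
                ),
                printed_class=PathogenicityClass[r.printed_class],
            )
        )
    return out


def familial_candidates() -> list[FixtureCandidate]:
    return _read_candidates("candidates_familial.tsv")


def simplex_candidates() -> list[FixtureCandidate]:
    return _read_candidates("candidates_simplex.tsv")


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class FixtureCohort:
    cohort: Cohort
    candidates: list[FixtureCandidate]

    def expected_class_by_key(self) -> dict:
        loci = LocusAllocator(self.cohort.panel)
        out = {}
        for cand in self.candidates:
            offset, ref, alt = hgvs_to_alleles(cand.hgvs_c)
            chrom, base = loci.base(cand.gene)
            out[(chrom, base + offset, ref, alt)] = cand.printed_class
        return out


def _candidate_key(cand: FixtureCandidate, loci: LocusAllocator):
    offset, ref, alt = hgvs_to_alleles(cand.hgvs_c)
    chrom, base = loci.base(cand.gene)
    return (chrom, base + offset, ref, alt)


def _candidate_annotation(cand: FixtureCandidate, key) -> AnnotationRow:
    return AnnotationRow(
        variant_key=key,
        gene=cand.gene,
        exon=cand.exon,
        hgvs_c=cand.hgvs_c,
        hgvs_p=cand.hgvs_p,
        consequence=cand.consequence,
        af_evs=cand.af_evs,
        af_1kg=cand.af_1kg,
        af_inhouse=cand.af_inhouse,
        reference_status=ReferenceStatus(cand.reference),
    )


def load_fixture_cohort(name: str) -> FixtureCohort:
    """Assemble a packaged fixture cohort deterministically.

    ``table1_families`` — the 18 familial units; ``table2_simplex`` — the 16
    simplex units; ``full_cohort`` — all 34. Background variation is
    regenerated from the recorded seed on every load, so two loads are
    identical.
    """
    if name not in FIXTURE_NAMES:
        raise FixtureError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    panel = load_default_panel()
    known_db = load_default_known_db()
    loci = LocusAllocator(panel)
    annotations = AnnotationTable()
    cfg = SimulationConfig(seed=FIXTURE_SEED)
    rng = np.random.default_rng(FIXTURE_SEED)

    units: list[CaseUnit] = []
    records: dict[str, list[VariantRecord]] = {}
    candidates: list[FixtureCandidate] = []

    fam_cands = familial_candidates()
    sim_cands = simplex_candidates()
    by_unit_fam: dict[str, list[FixtureCandidate]] = {}
    for c in fam_cands:
        by_unit_fam.setdefault(c.unit_id, []).append(c)
    by_unit_sim: dict[str, list[FixtureCandidate]] = {}
    for c in sim_cands:
        by_unit_sim.setdefault(c.unit_id, []).append(c)

    planted_keys: set = set()

    def plant(unit_id: str, cand: FixtureCandidate, carriers: dict[str, Genotype]) -> VariantRecord:
        key = _candidate_key(cand, loci)
        if key not in planted_keys:
            annotations.add(_candidate_annotation(cand, key), cand.predictors)
            loci.reserve(cand.gene, key[1] - loci.base(cand.gene)[1])
            planted_keys.add(key)
        qual = synthetic_data._draw_qual(rng, cfg, low_ok=False)
        return VariantRecord(key[0], key[1], key[2], key[3], qual, dict(carriers))

    if name in ("table1_families", "full_cohort"):
        for fid in _FAMILIAL_ORDER:
            ped, carrier_gts = _family_pedigree(fid)
            unit_records = synthetic_data.add_background(ped, cfg, rng, loci, annotations, panel)
            if carrier_gts is not None:
                for cand in by_unit_fam[fid]:
                    unit_records.append(plant(fid, cand, carrier_gts))
                    candidates.append(cand)
            units.append(
                CaseUnit(
                    unit_id=fid,
                    kind=UnitKind.FAMILIAL,
                    pedigree=ped,
                    proband_id=ped.affected()[0].iid,
                )
            )
            records[fid] = unit_records

    if name in ("table2_simplex", "full_cohort"):
        for sid in _SIMPLEX_ORDER:
            iid = f"P{sid}"
            ind = Individual(iid=iid, father=None, mother=None, sex=_M, affection=_A)
            ped = Pedigree(family_id=sid, individuals={iid: ind})
            unit_records = synthetic_data.add_background(ped, cfg, rng, loci, annotations, panel)
            for cand in by_unit_sim.get(sid, []):
                unit_records.append(plant(sid, cand, {iid: Genotype.HET}))
                candidates.append(cand)
            units.append(
                CaseUnit(unit_id=sid, kind=UnitKind.SIMPLEX, pedigree=ped, proband_id=iid)
            )
            records[sid] = unit_records

    cohort = Cohort(
        units=units, records=records, annotations=annotations, known_db=known_db, panel=panel
    )
    return FixtureCohort(cohort=cohort, candidates=candidates)


def materialize_fixture(name: str, out_dir) -> dict:
    fixture = load_fixture_cohort(name)
    return synthetic_data.materialize_cohort(fixture.cohort, out_dir)
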