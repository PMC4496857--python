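"""Fully synthetic cohorts with the statistical structure the pipeline assumes.

The generator builds multi-generation pedigrees segregating one planted
causal allele (or an in-trans pair) under AD, AR or XL, adds rare and common
background variation with Hardy-Weinberg founder genotypes dropped
Mendelianly through the pedigree, draws site qualities from a surrogate
normal scale, and synthesizes predictor outputs correlated with the planted
pathogenicity. Negative units are made negative by mechanism — the causal
gene is off-panel or the causal allele is non-coding — so they still carry
realistic background.

Background variants are deliberately never call-eligible: rare on-panel
background is non-truncating and receives fewer than two damaging predictor
votes. This encodes the defining property of an unsolved case (no
qualifying allele exists) and makes frozen fixtures deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io_formats
from .io_formats import AnnotationTable
from .models import (
    Affection,
    AnnotationRow,
    Consequence,
    Genotype,
    Individual,
    InheritanceModel,
    KnownPathogenicEntry,
    PanelGene,
    PathogenicityClass,
    Pedigree,
    PhaseStatus,
    PolyPhen2,
    PredictorOutputs,
    ReferenceStatus,
    Sex,
    Sift,
    UnitKind,
    VariantKey,
    VariantRecord,
    CaseUnit,
)
from .prioritizer import Cohort

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_families: int = 2
    n_simplex: int = 2
    generations_min: int = 3
    generations_max: int = 4
    sibship_mean: float = 2.5  # truncated-Poisson sibship size, >= 1
    model_mix: tuple[tuple[str, float], ...] = (("AD", 0.5), ("AR", 0.3), ("XL", 0.2))
    causal_class_mix: tuple[tuple[str, float], ...] = (
        ("known", 0.3),
        ("novel_truncating", 0.35),
        ("novel_missense", 0.35),
    )
    background_rate: float = 30.0  # background variant sites per case unit
    af_rare_weight: float = 0.2  # rare component of the background AF mixture
    af_rare_max: float = 0.009
    af_common_min: float = 0.05
    af_common_max: float = 0.5
    qual_mean: float = 146.2  # surrogate QUAL scale
    qual_sd: float = 26.2
    low_qual_fraction: float = 0.05  # background sites given QUAL below 20
    predictor_fidelity: float = 1.0  # P(planted missense gets >= 2 votes)
    female_penetrance: float = 0.5  # P(XL het female is affected)
    negative_fraction: float = 0.0  # fraction of units without an on-panel causal

    def __post_init__(self):
        for mix in (self.model_mix, self.causal_class_mix):
            total = sum(w for _, w in mix)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture weights sum to {total}, not 1")


@dataclass(frozen=True)
class PlantedTruth:
    unit_id: str
    gene: str
    model: Optional[InheritanceModel]  # None for negative units
    keys: tuple[VariantKey, ...]
    expected_classes: tuple[PathogenicityClass, ...]
    expected_phase: Optional[PhaseStatus]


@dataclass
class SimulatedCohort:
    cohort: Cohort
    truths: list[PlantedTruth]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Locus bookkeeping
# ---------------------------------------------------------------------------


class LocusAllocator:
    """Deterministic synthetic coordinates: each gene owns a disjoint
    1-Mb block on its cytoband's chromosome."""

    OFF_PANEL = {
        "OFFPANEL1": ("12", 200_000_000),
        "OFFPANEL2": ("5", 210_000_000),
    }

    def __init__(self, panel: dict[str, PanelGene]):
        self._base: dict[str, tuple[str, int]] = {}
        for i, (gene, pg) in enumerate(panel.items()):
            self._base[gene] = (pg.chrom, 1_000_000 * (i + 1))
        self._base.update(self.OFF_PANEL)
        self._used: set[tuple[str, int]] = set()

    def base(self, gene: str) -> tuple[str, int]:
        return self._base[gene]

    def reserve(self, gene: str, offset: int) -> tuple[str, int]:
        chrom, base = self._base[gene]
        pos = base + offset
        while (chrom, pos) in self._used:
            pos += 1
        self._used.add((chrom, pos))
        return chrom, pos

    def fresh(self, gene: str, rng: np.random.Generator) -> tuple[str, int]:
        return self.reserve(gene, int(rng.integers(1, 900_000)))


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    return str(ref), str(alt)


def _draw_qual(rng: np.random.Generator, cfg: SimulationConfig, low_ok: bool) -> float:
    if low_ok and rng.random() < cfg.low_qual_fraction:
        return float(rng.uniform(0.0, 19.9))
    return float(max(0.0, rng.normal(cfg.qual_mean, cfg.qual_sd)))


def _weighted_choice(rng: np.random.Generator, mix) -> str:
    labels = [l for l, _ in mix]
    weights = np.array([w for _, w in mix], dtype=float)
    return str(rng.choice(labels, p=weights / weights.sum()))


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

#: carrier state per individual: number of copies of allele "a" and "b"
#: (allele "b" only exists for compound-het AR plants).
CarrierState = dict[str, tuple[int, int]]


@dataclass
class SimulatedPedigree:
    pedigree: Pedigree
    carriers: CarrierState  # iid -> (copies of allele a, copies of allele b)
    model: InheritanceModel


def _sibship(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    return max(1, int(rng.poisson(cfg.sibship_mean)))


def simulate_pedigree(
    model: InheritanceModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    family_id: str = "SIM",
) -> SimulatedPedigree:
    """Build a connected multi-generation pedigree transmitting one planted
    allele under ``model``, and assign affection from carrier state.

    AD: heterozygous carriers are affected; one carrier is forced per
    generation so affecteds appear in every generation. AR: unaffected
    carrier parents produce an affected biallelic child in the last
    generation. XL: hemizygous males are affected, heterozygous females are
    affected with probability ``female_penetrance``; married-in spouses never
    carry, so the allele cannot produce male-to-male transmission.
    """
    generations = int(rng.integers(config.generations_min, config.generations_max + 1))
    members: dict[str, dict] = {}
    counter = [0]

    def add(sex: Sex, father=None, mother=None, a=0, b=0) -> str:
        counter[0] += 1
        iid = f"{family_id}-{counter[0]:02d}"
        members[iid] = dict(sex=sex, father=father, mother=mother, a=a, b=b)
        return iid

    def rand_sex() -> Sex:
        return Sex.MALE if rng.random() < 0.5 else Sex.FEMALE

    def drop_allele(parent: dict, which: str) -> int:
        copies = parent[which]
        if copies == 2:
            return 1
        if copies == 1:
            return 1 if rng.random() < 0.5 else 0
        return 0

    if model is InheritanceModel.AD:
        carrier = add(rand_sex(), a=1)
        spouse = add(Sex.FEMALE if members[carrier]["sex"] is Sex.MALE else Sex.MALE)
        for _ in range(generations - 1):
            kids = []
            n_kids = _sibship(rng, config)
            forced = int(rng.integers(0, n_kids))
            for k in range(n_kids):
                inherits = 1 if k == forced else drop_allele(members[carrier], "a")
                f, m = (carrier, spouse) if members[carrier]["sex"] is Sex.MALE else (spouse, carrier)
                kids.append(add(rand_sex(), father=f, mother=m, a=inherits))
            carrier = next(k for k in kids if members[k]["a"] == 1)
            spouse = add(Sex.FEMALE if members[carrier]["sex"] is Sex.MALE else Sex.MALE)

    elif model is InheritanceModel.AR:
        # ancestors: carrier lineage stays unaffected (het), affected
        # biallelic children appear only in the final sibship
        carrier = add(rand_sex(), a=1)
        spouse = add(Sex.FEMALE if members[carrier]["sex"] is Sex.MALE else Sex.MALE)
        for _ in range(generations - 2):
            kids = []
            n_kids = _sibship(rng, config)
            forced = int(rng.integers(0, n_kids))
            for k in range(n_kids):
                inherits = 1 if k == forced else drop_allele(members[carrier], "a")
                f, m = (carrier, spouse) if members[carrier]["sex"] is Sex.MALE else (spouse, carrier)
                kids.append(add(rand_sex(), father=f, mother=m, a=inherits))
            carrier = next(k for k in kids if members[k]["a"] == 1)
            spouse = add(
                Sex.FEMALE if members[carrier]["sex"] is Sex.MALE else Sex.MALE, b=1
            )  # married-in carrier of the counter-allele
        # final sibship: force one biallelic (in-trans) child
        f, m = (carrier, spouse) if members[carrier]["sex"] is Sex.MALE else (spouse, carrier)
        n_kids = max(2, _sibship(rng, config))
        forced = int(rng.integers(0, n_kids))
        for k in range(n_kids):
            if k == forced:
                add(rand_sex(), father=f, mother=m, a=1, b=1)
            else:
                a = drop_allele(members[carrier], "a")
                b = drop_allele(members[spouse], "b")
                if a and b:  # keep the forced child the unique affected
                    b = 0
                add(rand_sex(), father=f, mother=m, a=a, b=b)

    else:  # XL: track copies on X; males carry 0/1, females 0/1/2
        carrier = add(Sex.FEMALE, a=1)  # carrier female founder
        spouse = add(Sex.MALE)
        for g in range(generations - 1):
            last = g == generations - 2
            kids = []
            carrier_is_female = members[carrier]["sex"] is Sex.FEMALE
            f, m = (spouse, carrier) if carrier_is_female else (carrier, spouse)
            n_kids = _sibship(rng, config)
            forced = int(rng.integers(0, n_kids))
            for k in range(n_kids):
                sex = Sex.MALE if (k == forced and last) else rand_sex()
                if carrier_is_female:
                    inherits = 1 if k == forced else drop_allele(members[carrier], "a")
                else:  # carrier male: all daughters carry, sons never
                    inherits = 1 if sex is Sex.FEMALE else 0
                    if k == forced and sex is Sex.MALE:
                        sex = Sex.FEMALE  # forced transmission must be a daughter
                        inherits = 1
                kids.append(add(sex, father=f, mother=m, a=inherits))
            choices = [k for k in kids if members[k]["a"] >= 1]
            if last:
                break
            # prefer continuing through a carrier female (keeps male-to-male
            # impossible and generations connected)
            females = [k for k in choices if members[k]["sex"] is Sex.FEMALE]
            carrier = females[0] if females else choices[0]
            spouse = add(Sex.MALE if members[carrier]["sex"] is Sex.FEMALE else Sex.FEMALE)

    individuals: dict[str, Individual] = {}
    carriers: CarrierState = {}
    for iid, m in members.items():
        a, b = m["a"], m["b"]
        if model is InheritanceModel.AD:
            affected = a >= 1
        elif model is InheritanceModel.AR:
            affected = a >= 1 and b >= 1 or a == 2
        else:
            if m["sex"] is Sex.MALE:
                affected = a >= 1
            else:
                affected = a >= 1 and rng.random() < config.female_penetrance
        individuals[iid] = Individual(
            iid=iid,
            father=m["father"],
            mother=m["mother"],
            sex=m["sex"],
            affection=Affection.AFFECTED if affected else Affection.UNAFFECTED,
        )
        carriers[iid] = (a, b)
    ped = Pedigree(family_id=family_id, individuals=individuals)
    if not ped.affected():  # retry cap: regenerate once with split stream
        return simulate_pedigree(model, config, np.random.default_rng(rng.integers(2**31)), family_id)
    return SimulatedPedigree(pedigree=ped, carriers=carriers, model=model)


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


def _planted_annotation(
    gene: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    causal_class: str,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    known_db: list[KnownPathogenicEntry],
) -> tuple[AnnotationRow, PredictorOutputs, PathogenicityClass]:
    offset = pos % 1_000_000
    if causal_class == "novel_truncating":
        cons = Consequence.NONSENSE if rng.random() < 0.6 else (
            Consequence.FRAMESHIFT_DELETION if rng.random() < 0.5 else Consequence.FRAMESHIFT_INSERTION
        )
        hgvs_c = f"c.{offset}{ref}>{alt}"
        hgvs_p = f"p.X{offset // 3 + 1}fs" if cons is not Consequence.NONSENSE else f"p.Q{offset // 3 + 1}X"
        pred = PredictorOutputs()
        expected = PathogenicityClass.II
        status = ReferenceStatus("novel")
    elif causal_class == "novel_missense":
        cons = Consequence.NONSYNONYMOUS
        hgvs_c = f"c.{offset}{ref}>{alt}"
        hgvs_p = f"p.A{offset // 3 + 1}V"
        if rng.random() < cfg.predictor_fidelity:
            pred = PredictorOutputs(
                PolyPhen2.PROBABLY_DAMAGING, Sift.DAMAGING, float(rng.uniform(0.6, 0.95))
            )
            expected = PathogenicityClass.II
        else:
            pred = PredictorOutputs(
                PolyPhen2.BENIGN, Sift.DAMAGING, float(rng.uniform(0.0, 0.4))
            )
            expected = PathogenicityClass.III
        status = ReferenceStatus("novel")
    else:  # known: registered in the run's known-pathogenic DB copy
        cons = Consequence.NONSYNONYMOUS
        hgvs_c = f"c.{offset}{ref}>{alt}"
        hgvs_p = f"p.R{offset // 3 + 1}W"
        known_db.append(KnownPathogenicEntry(gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p, citation="synthetic prior report"))
        pred = PredictorOutputs(
            PolyPhen2.PROBABLY_DAMAGING, Sift.DAMAGING, float(rng.uniform(0.6, 0.95))
        )
        expected = PathogenicityClass.I
        status = ReferenceStatus(f"rs{int(rng.integers(10_000, 99_999))}")
    ann = AnnotationRow(
        variant_key=(chrom, pos, ref, alt),
        gene=gene,
        exon=int(rng.integers(1, 10)),
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        consequence=cons,
        af_evs=None,
        af_1kg=None,
        af_inhouse=None,
        reference_status=status,
    )
    return ann, pred, expected


def _carrier_genotype(copies: int, sex: Sex, on_x: bool) -> Genotype:
    if copies == 0:
        return Genotype.HOM_REF
    if on_x and sex is Sex.MALE:
        return Genotype.HEMI
    return Genotype.HOM_ALT if copies >= 2 else Genotype.HET


def plant_variants(
    sim: SimulatedPedigree,
    gene: str,
    causal_class: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    loci: LocusAllocator,
    annotations: AnnotationTable,
    known_db: list[KnownPathogenicEntry],
    pair_class: Optional[str] = None,
) -> tuple[list[VariantRecord], PlantedTruth]:
    """Materialize the planted carrier states as variant records + annotations.

    AR plants produce two alleles (classes ``causal_class`` and
    ``pair_class``) placed in trans by construction; AD/XL produce one.
    """
    ped = sim.pedigree
    on_x = loci.base(gene)[0] == "X"
    records = []
    keys, classes = [], []
    n_alleles = 2 if sim.model is InheritanceModel.AR and any(b for _, b in sim.carriers.values()) else 1
    for allele_idx in range(n_alleles):
        ref, alt = _snv_alleles(rng)
        chrom, pos = loci.fresh(gene, rng)
        cls_name = causal_class if allele_idx == 0 else (pair_class or causal_class)
        ann, pred, expected = _planted_annotation(
            gene, chrom, pos, ref, alt, cls_name, rng, config, known_db
        )
        annotations.add(ann, pred)
        genotypes = {
            iid: _carrier_genotype(sim.carriers[iid][allele_idx], ped.individuals[iid].sex, on_x)
            for iid in ped.individuals
        }
        records.append(
            VariantRecord(chrom, pos, ref, alt, _draw_qual(rng, config, low_ok=False), genotypes)
        )
        keys.append((chrom, pos, ref, alt))
        classes.append(expected)
    phase = PhaseStatus.RESOLVED_TRANS if n_alleles == 2 else None
    truth = PlantedTruth(
        unit_id=ped.family_id,
        gene=gene,
        model=sim.model,
        keys=tuple(keys),
        expected_classes=tuple(classes),
        expected_phase=phase,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Background variation
# ---------------------------------------------------------------------------


def _background_predictors(rng: np.random.Generator) -> PredictorOutputs:
    """Benign-biased predictor profile, capped below the ensemble quorum."""
    poly = PolyPhen2.POSSIBLY_DAMAGING if rng.random() < 0.15 else PolyPhen2.BENIGN
    sift = Sift.DAMAGING if rng.random() < 0.15 else Sift.TOLERATED
    mutpred = float(rng.uniform(0.0, 1.0))
    votes = (poly is not PolyPhen2.BENIGN) + (sift is Sift.DAMAGING) + (mutpred > 0.5)
    if votes >= 2:  # demote to keep background ensemble-benign
        sift = Sift.TOLERATED
        mutpred = float(rng.uniform(0.0, 0.45))
    return PredictorOutputs(poly, sift, mutpred)


def _drop_background_genotypes(
    ped: Pedigree, af: float, on_x: bool, rng: np.random.Generator
) -> dict[str, Genotype]:
    """Founders get Hardy-Weinberg genotypes at ``af``; descendants inherit
    one allele from each parent (Mendelian drop)."""
    copies: dict[str, int] = {}

    def transmit(parent_copies: int, parent_is_hemi: bool) -> int:
        if parent_is_hemi:
            return parent_copies  # a male's single X goes to daughters as-is
        if parent_copies == 2:
            return 1
        if parent_copies == 1:
            return 1 if rng.random() < 0.5 else 0
        return 0

    def resolve(iid: str) -> int:
        if iid in copies:
            return copies[iid]
        ind = ped.individuals[iid]
        male_x = on_x and ind.sex is Sex.MALE
        if ind.is_founder:
            if male_x:
                n = 1 if rng.random() < af else 0
            else:
                n = int((rng.random() < af) + (rng.random() < af))
        else:
            pf = resolve(ind.father)
            pm = resolve(ind.mother)
            from_m = transmit(pm, False)
            if male_x:
                n = from_m  # sons take only the maternal X
            elif on_x:
                n = transmit(pf, True) + from_m  # daughters get the paternal X
            else:
                n = transmit(pf, False) + from_m
        copies[iid] = n
        return n

    for iid in ped.individuals:
        resolve(iid)
    return {
        iid: _carrier_genotype(copies[iid], ped.individuals[iid].sex, on_x)
        for iid in ped.individuals
    }


def add_background(
    ped: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator,
    loci: LocusAllocator,
    annotations: AnnotationTable,
    panel: dict[str, PanelGene],
) -> list[VariantRecord]:
    """Draw background variant sites for one case unit.

    Common-component sites (frequency 5-50 %) exist to be removed by the
    frequency filter; a configurable fraction of sites get sub-threshold
    qualities to exercise the quality filter; rare on-panel sites are
    missense/synonymous/other with ensemble-benign predictor profiles.
    """
    genes = sorted(panel)
    n_sites = int(rng.poisson(config.background_rate))
    records = []
    for _ in range(n_sites):
        gene = genes[int(rng.integers(0, len(genes)))]
        chrom, pos = loci.fresh(gene, rng)
        ref, alt = _snv_alleles(rng)
        rare = rng.random() < config.af_rare_weight
        if rare:
            af = float(rng.uniform(1e-4, config.af_rare_max))
        else:
            af = float(rng.uniform(config.af_common_min, config.af_common_max))
        u = rng.random()
        cons = (
            Consequence.NONSYNONYMOUS
            if u < 0.5
            else (Consequence.SYNONYMOUS if u < 0.85 else Consequence.OTHER)
        )
        pred = (
            _background_predictors(rng)
            if cons is Consequence.NONSYNONYMOUS
            else PredictorOutputs()
        )
        present = lambda: rng.random() < (0.5 if rare else 0.95)  # noqa: E731
        ann = AnnotationRow(
            variant_key=(chrom, pos, ref, alt),
            gene=gene,
            exon=int(rng.integers(1, max(2, panel[gene].exon_count))),
            hgvs_c=f"c.{pos % 1_000_000}{ref}>{alt}",
            hgvs_p="" if cons is not Consequence.NONSYNONYMOUS else f"p.L{(pos % 99_999) // 3 + 1}F",
            consequence=cons,
            af_evs=af if present() else None,
            af_1kg=af if present() else None,
            af_inhouse=af if present() else None,
            reference_status=ReferenceStatus(
                f"rs9{int(rng.integers(10_000_000, 99_999_999))}" if rng.random() < 0.5 else "novel"
            ),
        )
        annotations.add(ann, pred)
        on_x = chrom == "X"
        genotypes = _drop_background_genotypes(ped, af, on_x, rng)
        qual = _draw_qual(rng, config, low_ok=True)
        records.append(VariantRecord(chrom, pos, ref, alt, qual, genotypes))
    return records


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------


def _default_panel() -> dict[str, PanelGene]:
    from .fixtures import load_default_panel

    return load_default_panel()


def _simplex_unit(
    unit_id: str,
    model: InheritanceModel,
    causal_class: str,
    pair_class: str,
    negative: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
    loci: LocusAllocator,
    annotations: AnnotationTable,
    known_db: list[KnownPathogenicEntry],
    panel: dict[str, PanelGene],
) -> tuple[CaseUnit, list[VariantRecord], Optional[PlantedTruth]]:
    sex = Sex.MALE if model is InheritanceModel.XL else (Sex.MALE if rng.random() < 0.5 else Sex.FEMALE)
    ind = Individual(iid=f"{unit_id}-01", father=None, mother=None, sex=sex, affection=Affection.AFFECTED)
    ped = Pedigree(family_id=unit_id, individuals={ind.iid: ind})
    unit = CaseUnit(unit_id=unit_id, kind=UnitKind.SIMPLEX, pedigree=ped, proband_id=ind.iid)
    records = add_background(ped, config, rng, loci, annotations, panel)
    truth = None
    if negative:
        # off-panel causal: survives the cascade, never called
        gene = "OFFPANEL1"
        chrom, pos = loci.fresh(gene, rng)
        ref, alt = _snv_alleles(rng)
        ann = AnnotationRow(
            variant_key=(chrom, pos, ref, alt),
            gene=gene,
            exon=1,
            hgvs_c=f"c.{pos % 1_000_000}{ref}>{alt}",
            hgvs_p=f"p.Q{pos % 999}X",
            consequence=Consequence.NONSENSE,
            af_evs=None,
            af_1kg=None,
            af_inhouse=None,
            reference_status=ReferenceStatus("novel"),
        )
        annotations.add(ann, PredictorOutputs())
        records.append(
            VariantRecord(chrom, pos, ref, alt, _draw_qual(rng, config, False), {ind.iid: Genotype.HET})
        )
        return unit, records, truth

    gene_pool = sorted(g for g, pg in panel.items() if pg.supports(model))
    gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
    on_x = loci.base(gene)[0] == "X"
    keys, classes = [], []
    if model is InheritanceModel.AR:
        hom = rng.random() < 0.2
        alleles = [(causal_class, Genotype.HOM_ALT)] if hom else [
            (causal_class, Genotype.HET),
            (pair_class, Genotype.HET),
        ]
    elif model is InheritanceModel.XL:
        alleles = [(causal_class, Genotype.HEMI)]
    else:
        alleles = [(causal_class, Genotype.HET)]
    for cls_name, gt in alleles:
        ref, alt = _snv_alleles(rng)
        chrom, pos = loci.fresh(gene, rng)
        ann, pred, expected = _planted_annotation(
            gene, chrom, pos, ref, alt, cls_name, rng, config, known_db
        )
        annotations.add(ann, pred)
        records.append(
            VariantRecord(chrom, pos, ref, alt, _draw_qual(rng, config, False), {ind.iid: gt})
        )
        keys.append((chrom, pos, ref, alt))
        classes.append(expected)
    truth = PlantedTruth(
        unit_id=unit_id,
        gene=gene,
        model=model,
        keys=tuple(keys),
        expected_classes=tuple(classes),
        expected_phase=PhaseStatus.ASSUMED_TRANS if len(keys) == 2 else None,
    )
    return unit, records, truth


def generate_cohort(
    config: SimulationConfig, panel: Optional[dict[str, PanelGene]] = None
) -> SimulatedCohort:
    """Generate a full synthetic cohort in memory.

    A ``negative_fraction`` of units (rounded) are negatives whose causal
    allele is off-panel; all units carry background. Identical configs give
    identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    panel = panel if panel is not None else _default_panel()
    loci = LocusAllocator(panel)
    annotations = AnnotationTable()
    known_db: list[KnownPathogenicEntry] = []
    units: list[CaseUnit] = []
    records: dict[str, list[VariantRecord]] = {}
    truths: list[PlantedTruth] = []

    n_neg_fam = round(config.n_families * config.negative_fraction)
    n_neg_sim = round(config.n_simplex * config.negative_fraction)

    for i in range(config.n_families):
        unit_id = f"FAM{i + 1:03d}"
        negative = i < n_neg_fam
        model = InheritanceModel(_weighted_choice(rng, config.model_mix))
        sim = simulate_pedigree(model, config, rng, family_id=unit_id)
        ped = sim.pedigree
        unit_records = add_background(ped, config, rng, loci, annotations, panel)
        if negative:
            # intronic causal on-panel: removed at the functional stage
            genes = sorted(panel)
            gene = genes[int(rng.integers(0, len(genes)))]
            chrom, pos = loci.fresh(gene, rng)
            ref, alt = _snv_alleles(rng)
            ann = AnnotationRow(
                variant_key=(chrom, pos, ref, alt),
                gene=gene,
                exon=1,
                hgvs_c=f"c.{pos % 1_000_000}+8{ref}>{alt}",
                hgvs_p="",
                consequence=Consequence.OTHER,
                af_evs=None,
                af_1kg=None,
                af_inhouse=None,
                reference_status=ReferenceStatus("novel"),
            )
            annotations.add(ann, PredictorOutputs())
            genotypes = {
                iid: (Genotype.HET if sim.carriers[iid][0] else Genotype.HOM_REF)
                for iid in ped.individuals
            }
            unit_records.append(
                VariantRecord(chrom, pos, ref, alt, _draw_qual(rng, config, False), genotypes)
            )
        else:
            gene_pool = sorted(g for g, pg in panel.items() if pg.supports(model))
            gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
            causal = _weighted_choice(rng, config.causal_class_mix)
            pair = _weighted_choice(rng, config.causal_class_mix)
            planted, truth = plant_variants(
                sim, gene, causal, config, rng, loci, annotations, known_db, pair_class=pair
            )
            unit_records.extend(planted)
            truths.append(truth)
        affected = ped.affected()
        units.append(
            CaseUnit(
                unit_id=unit_id,
                kind=UnitKind.FAMILIAL,
                pedigree=ped,
                proband_id=affected[0].iid,
            )
        )
        records[unit_id] = unit_records

    for i in range(config.n_simplex):
        unit_id = f"SIM{i + 1:03d}"
        negative = i < n_neg_sim
        model = InheritanceModel(_weighted_choice(rng, config.model_mix))
        causal = _weighted_choice(rng, config.causal_class_mix)
        pair = _weighted_choice(rng, config.causal_class_mix)
        unit, unit_records, truth = _simplex_unit(
            unit_id, model, causal, pair, negative, config, rng, loci, annotations, known_db, panel
        )
        units.append(unit)
        records[unit_id] = unit_records
        if truth is not None:
            truths.append(truth)

    cohort = Cohort(units=units, records=records, annotations=annotations, known_db=known_db, panel=panel)
    return SimulatedCohort(cohort=cohort, truths=truths, config=config)


# ---------------------------------------------------------------------------
# Materialization
# ---------------------------------------------------------------------------


def materialize_cohort(
    sim: SimulatedCohort | Cohort, out_dir: str | Path, truths: Optional[list[PlantedTruth]] = None
) -> dict:
    """Write a cohort to disk in the formats the readers consume.

    Emits one VCF + PED per unit, a cohort annotation TSV, the known DB and
    panel TSVs, a pipeline config YAML, and (when available) the planted
    truth as JSON. Returns the manifest of written paths.
    """
    cohort = sim.cohort if isinstance(sim, SimulatedCohort) else sim
    if truths is None and isinstance(sim, SimulatedCohort):
        truths = sim.truths
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcfs, peds = [], []
    for unit in cohort.units:
        vcf_path = out / f"{unit.unit_id}.vcf"
        ped_path = out / f"{unit.unit_id}.ped"
        sample_ids = list(unit.pedigree.individuals)
        io_formats.write_vcf(vcf_path, sample_ids, cohort.records[unit.unit_id])
        io_formats.write_ped(unit.pedigree, ped_path)
        vcfs.append(str(vcf_path))
        peds.append(str(ped_path))
    ann_path = out / "annotations.tsv"
    io_formats.write_annotations(cohort.annotations, ann_path)
    known_path = out / "known_pathogenic.tsv"
    lines = ["gene\thgvs_c\thgvs_p\trsid\tcitation"]
    for e in cohort.known_db:
        lines.append(f"{e.gene}\t{e.hgvs_c}\t{e.hgvs_p}\t{e.rsid}\t{e.citation}")
    known_path.write_text("\n".join(lines) + "\n")
    panel_path = out / "panel.tsv"
    plines = ["gene\tinheritance\trefseq\tcytoband\texon_count\tdescription"]
    mode_repr = {
        frozenset({"AD"}): "AD",
        frozenset({"AR"}): "AR",
        frozenset({"AD", "AR"}): "AR/AD",
        frozenset({"XL"}): "X-linked",
        frozenset({"digenic"}): "digenic",
    }
    for pg in cohort.panel.values():
        plines.append(
            f"{pg.gene}\t{mode_repr[pg.modes]}\t{pg.refseq}\t{pg.cytoband}\t{pg.exon_count}\t"
        )
    panel_path.write_text("\n".join(plines) + "\n")
    if truths:
        truth_path = out / "truth.json"
        truth_path.write_text(
            json.dumps(
                [
                    {
                        "unit_id": t.unit_id,
                        "gene": t.gene,
                        "model": t.model.value if t.model else None,
                        "keys": [list(k) for k in t.keys],
                        "expected_classes": [c.roman for c in t.expected_classes],
                        "expected_phase": t.expected_phase.value if t.expected_phase else None,
                    }
                    for t in truths
                ],
                indent=2,
            )
            + "\n"
        )
    # paths relative to the config file keep the cohort relocatable and the
    # materialization byte-identical across runs
    config_path = out / "config.yaml"
    config_path.write_text(
        "inputs:\n"
        + "  vcf:\n"
        + "".join(f"    - {Path(p).name}\n" for p in vcfs)
        + "  ped:\n"
        + "".join(f"    - {Path(p).name}\n" for p in peds)
        + f"  annotations: {ann_path.name}\n"
        + f"  known_db: {known_path.name}\n"
        + f"  panel: {panel_path.name}\n"
        + "output:\n  dir: results\n"
    )
    return {
        "vcf": vcfs,
        "ped": peds,
        "annotations": str(ann_path),
        "known_db": str(known_path),
        "panel": str(panel_path),
        "config": str(config_path),
    }
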