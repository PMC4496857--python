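"""Pedigree-level inheritance inference, cosegregation testing, and
compound-heterozygote detection.

Model inference follows the classical pedigree-reading rules: autosomal
dominant when affected individuals appear in every generation; autosomal
recessive when affected offspring arise from unaffected parents; X-linked
when affected males occur without male-to-male transmission. A pedigree may
satisfy several rules (an X-linked family with affected heterozygous females
looks dominant), so inference returns every compatible model in a fixed
precedence order and lets the prioritizer iterate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

from .models import (
    Affection,
    AnnotationRow,
    Genotype,
    InheritanceModel,
    MODEL_PRECEDENCE,
    PanelGene,
    Pedigree,
    PhaseStatus,
    SegregationResult,
    SegregationViolation,
    Sex,
    VariantKey,
    VariantRecord,
)


class InferenceError(ValueError):
    pass


class FemalePenetrance:
    VARIABLE = "variable"  # het females may be affected or unaffected
    COMPLETE = "complete"  # het females must be affected


@dataclass(frozen=True)
class InheritancePolicy:
    female_penetrance: str = FemalePenetrance.VARIABLE
    penetrance_exceptions: int = 0  # tolerated autosomal violations


@dataclass(frozen=True)
class ModeInference:
    models: tuple[InheritanceModel, ...]
    unconstrained: bool = False  # simplex: no pedigree information


# ---------------------------------------------------------------------------
# Mode inference
# ---------------------------------------------------------------------------


def _male_to_male_transmission(ped: Pedigree) -> bool:
    for ind in ped.individuals.values():
        if ind.affection is Affection.AFFECTED and ind.father is not None:
            father = ped.individuals[ind.father]
            if (
                ind.sex is Sex.MALE
                and father.sex is Sex.MALE
                and father.affection is Affection.AFFECTED
            ):
                return True
    return False


def _affected_in_every_generation(ped: Pedigree) -> bool:
    levels = ped.generation_levels()
    return all(
        any(i.affection is Affection.AFFECTED for i in members)
        for members in levels.values()
    )


def _recessive_sibship(ped: Pedigree) -> bool:
    """Some affected individual has two pedigree parents, both unaffected."""
    for ind in ped.affected():
        if ind.father is None:
            continue
        father = ped.individuals[ind.father]
        mother = ped.individuals[ind.mother]
        if (
            father.affection is Affection.UNAFFECTED
            and mother.affection is Affection.UNAFFECTED
        ):
            return True
    return False


def infer_modes(ped: Pedigree, policy: InheritancePolicy = InheritancePolicy()) -> ModeInference:
    """Return every inheritance model compatible with the pedigree's affection
    pattern, ordered AD, XL, AR.

    A simplex pedigree (single affected, no affected relatives, < 2
    informative generations) constrains nothing: all three models are
    returned flagged unconstrained.
    """
    affected = ped.affected()
    if not affected:
        raise InferenceError(f"{ped.family_id}: no affected individual")
    if len(affected) == 1 and len(ped.individuals) == 1:
        return ModeInference(models=MODEL_PRECEDENCE, unconstrained=True)
    if ped.n_generations < 2:
        return ModeInference(models=MODEL_PRECEDENCE, unconstrained=True)

    fits: list[InheritanceModel] = []
    if _affected_in_every_generation(ped):
        fits.append(InheritanceModel.AD)
    affected_males = [i for i in affected if i.sex is Sex.MALE]
    if affected_males and not _male_to_male_transmission(ped):
        if policy.female_penetrance == FemalePenetrance.COMPLETE:
            ok = all(
                child.affection is Affection.AFFECTED
                for male in affected_males
                for child in ped.children_of(male.iid)
                if child.sex is Sex.FEMALE
            )
        else:
            ok = True
        if ok:
            fits.append(InheritanceModel.XL)
    if _recessive_sibship(ped):
        fits.append(InheritanceModel.AR)

    if not fits:
        return ModeInference(models=MODEL_PRECEDENCE, unconstrained=True)
    ordered = tuple(m for m in MODEL_PRECEDENCE if m in fits)
    return ModeInference(models=ordered, unconstrained=False)


# ---------------------------------------------------------------------------
# Per-individual genotype compatibility
# ---------------------------------------------------------------------------


def genotype_compatible(
    gt: Genotype,
    model: InheritanceModel,
    sex: Sex,
    affection: Affection,
    policy: InheritancePolicy = InheritancePolicy(),
    ar_pair: bool = False,
) -> tuple[bool, tuple[Genotype, ...]]:
    """Is an observed genotype consistent with the model, given sex and
    affection? Returns (compatible, expected genotype set).

    For AR the caller handles in-trans pairs; here a single variant's
    genotype under AR means hom_alt for affecteds (or het membership in a
    pair when ``ar_pair``).
    """
    if model in (InheritanceModel.AD, InheritanceModel.AR) and gt is Genotype.HEMI:
        raise ValueError("hemizygous genotype on an autosomal model")
    if affection is Affection.UNKNOWN or gt is Genotype.MISSING:
        return True, ()
    affected = affection is Affection.AFFECTED

    if model is InheritanceModel.AD:
        expected = (Genotype.HET, Genotype.HOM_ALT) if affected else (Genotype.HOM_REF,)
        return gt in expected, expected
    if model is InheritanceModel.AR:
        if affected:
            expected = (Genotype.HET,) if ar_pair else (Genotype.HOM_ALT,)
            return gt in expected, expected
        expected = (Genotype.HOM_REF, Genotype.HET)
        return gt in expected, expected
    # X-linked
    if sex is Sex.MALE:
        expected = (Genotype.HEMI,) if affected else (Genotype.HOM_REF,)
        return gt in expected, expected
    if affected:
        expected = (Genotype.HET, Genotype.HOM_ALT)
        return gt in expected, expected
    if policy.female_penetrance == FemalePenetrance.COMPLETE:
        expected = (Genotype.HOM_REF,)
    else:
        expected = (Genotype.HOM_REF, Genotype.HET)  # unaffected carrier allowed
    return gt in expected, expected


# ---------------------------------------------------------------------------
# Cosegregation
# ---------------------------------------------------------------------------


def _genotype_of(records: dict[VariantKey, VariantRecord], key: VariantKey, iid: str) -> Genotype:
    rec = records.get(key)
    if rec is None:
        return Genotype.MISSING
    return rec.genotypes.get(iid, Genotype.MISSING)


def cosegregates(
    variants: tuple[VariantKey, ...],
    records: dict[VariantKey, VariantRecord],
    ped: Pedigree,
    model: InheritanceModel,
    policy: InheritancePolicy = InheritancePolicy(),
) -> SegregationResult:
    """Test whether the candidate cosegregates with affection under a model.

    ``variants`` is a single key for AD/XL (or hom-alt AR), or an in-trans
    pair for compound-het AR. Members without genotypes are skipped and
    listed as untested; removing an individual can therefore never turn a
    consistent result inconsistent.
    """
    if model is InheritanceModel.AR and len(variants) not in (1, 2):
        raise ValueError("AR cosegregation takes one hom-alt variant or a pair")
    if model is not InheritanceModel.AR and len(variants) != 1:
        raise ValueError(f"{model.value} cosegregation takes exactly one variant")

    violations: list[SegregationViolation] = []
    untested: list[str] = []
    budget = policy.penetrance_exceptions if model is not InheritanceModel.XL else 0

    for ind in ped.individuals.values():
        gts = [_genotype_of(records, key, ind.iid) for key in variants]
        if any(g is Genotype.MISSING for g in gts):
            untested.append(ind.iid)
            continue
        if model is InheritanceModel.AR and len(variants) == 2:
            carries_both = all(g in (Genotype.HET, Genotype.HOM_ALT) for g in gts)
            if ind.affection is Affection.AFFECTED and not carries_both:
                violations.append(
                    SegregationViolation(ind.iid, (Genotype.HET,), next(g for g in gts if g not in (Genotype.HET, Genotype.HOM_ALT)))
                )
            elif ind.affection is Affection.UNAFFECTED and carries_both:
                violations.append(
                    SegregationViolation(ind.iid, (Genotype.HOM_REF,), gts[0])
                )
        else:
            ok, expected = genotype_compatible(
                gts[0], model, ind.sex, ind.affection, policy, ar_pair=False
            )
            if not ok:
                violations.append(SegregationViolation(ind.iid, expected, gts[0]))

    tolerated = violations[: max(0, budget)] if budget else []
    effective = tuple(violations[len(tolerated):]) if tolerated else tuple(violations)
    return SegregationResult(
        model=model,
        consistent=len(effective) == 0,
        violations=effective,
        untested=tuple(untested),
    )


# ---------------------------------------------------------------------------
# Compound heterozygotes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundHetPair:
    sample: str
    gene: str
    keys: tuple[VariantKey, VariantKey]
    phase_status: PhaseStatus


def _parent_carries(records, key: VariantKey, iid: Optional[str]) -> Optional[bool]:
    if iid is None:
        return None
    gt = _genotype_of(records, key, iid)
    if gt is Genotype.MISSING:
        return None
    return gt.carries_alt()


def resolve_phase(
    records: dict[VariantKey, VariantRecord],
    ped: Optional[Pedigree],
    sample: str,
    k1: VariantKey,
    k2: VariantKey,
) -> PhaseStatus:
    """Phase a het pair by transmission when parental genotypes exist.

    Enumerates all parental-origin assignments consistent with the parents'
    carrier status; if every consistent assignment puts the two variants on
    opposite parental haplotypes the pair is resolved trans, if all put them
    on the same side it is resolved cis, otherwise (or without parents) the
    pair is assumed trans.
    """
    ind = ped.individuals.get(sample) if ped is not None else None
    if ind is None or (ind.father is None and ind.mother is None):
        return PhaseStatus.ASSUMED_TRANS

    def origins(key: VariantKey) -> list[str]:
        f = _parent_carries(records, key, ind.father)
        m = _parent_carries(records, key, ind.mother)
        possible = []
        if f is not False:
            possible.append("father")
        if m is not False:
            possible.append("mother")
        return possible or ["father", "mother"]  # de novo / unknowable

    assignments = [
        (o1, o2) for o1, o2 in itertools.product(origins(k1), origins(k2))
    ]
    if all(o1 != o2 for o1, o2 in assignments):
        return PhaseStatus.RESOLVED_TRANS
    if all(o1 == o2 for o1, o2 in assignments):
        return PhaseStatus.RESOLVED_CIS
    return PhaseStatus.ASSUMED_TRANS


def find_compound_hets(
    survivors_by_gene: dict[str, list[VariantRecord]],
    sample: str,
    panel: dict[str, PanelGene],
    ped: Optional[Pedigree] = None,
) -> list[CompoundHetPair]:
    """Pairs of distinct heterozygous variants in one AR-capable panel gene
    for one sample, phased by transmission when a trio is available."""
    pairs: list[CompoundHetPair] = []
    for gene in sorted(survivors_by_gene):
        panel_gene = panel.get(gene)
        if panel_gene is None or not panel_gene.supports(InheritanceModel.AR):
            continue
        records = survivors_by_gene[gene]
        hets = sorted(
            (r for r in records if r.genotypes.get(sample) is Genotype.HET),
            key=lambda r: r.key,
        )
        rec_map = {r.key: r for r in records}
        for r1, r2 in itertools.combinations(hets, 2):
            phase = resolve_phase(rec_map, ped, sample, r1.key, r2.key)
            pairs.append(
                CompoundHetPair(
                    sample=sample, gene=gene, keys=(r1.key, r2.key), phase_status=phase
                )
            )
    return pairs
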