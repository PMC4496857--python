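"""Inheritance inference, cosegregation, and compound-het phasing."""

from __future__ import annotations

import itertools

import pytest

from panelprio.fixtures import load_fixture_cohort
from panelprio.inheritance_engine import (
    FemalePenetrance,
    InferenceError,
    InheritancePolicy,
    cosegregates,
    find_compound_hets,
    genotype_compatible,
    infer_modes,
    resolve_phase,
)
from panelprio.models import (
    Affection,
    Genotype,
    Individual,
    InheritanceModel,
    Pedigree,
    PhaseStatus,
    Sex,
    VariantRecord,
)

from conftest import make_record, make_trio

_M, _F = Sex.MALE, Sex.FEMALE
_A, _U = Affection.AFFECTED, Affection.UNAFFECTED


def _ped(fid, rows):
    return Pedigree(
        family_id=fid,
        individuals={
            iid: Individual(iid, fa, mo, sex, aff) for iid, fa, mo, sex, aff in rows
        },
    )


def _three_gen_ad():
    return _ped(
        "AD",
        [
            ("I-1", None, None, _M, _A),
            ("I-2", None, None, _F, _U),
            ("II-1", "I-1", "I-2", _M, _A),
            ("II-2", None, None, _F, _U),
            ("III-1", "II-1", "II-2", _F, _A),
        ],
    )


def _ar_sibship():
    return _ped(
        "AR",
        [
            ("dad", None, None, _M, _U),
            ("mum", None, None, _F, _U),
            ("boy", "dad", "mum", _M, _A),
            ("girl", "dad", "mum", _F, _A),
        ],
    )


# ---------------------------------------------------------------------------
# Mode inference
# ---------------------------------------------------------------------------


def test_ad_pattern_with_male_to_male():
    inference = infer_modes(_three_gen_ad())
    assert inference.models == (InheritanceModel.AD,)
    assert not inference.unconstrained


def test_ar_pattern_unaffected_parents():
    inference = infer_modes(_ar_sibship())
    assert InheritanceModel.AR in inference.models
    assert InheritanceModel.AD not in inference.models


def test_xl_pattern_dominant_looking_without_male_to_male(full_cohort):
    """An X-linked family with affected het females mimics dominance; both
    models must be offered, dominant first."""
    ped = next(u for u in full_cohort.cohort.units if u.unit_id == "F12").pedigree
    inference = infer_modes(ped)
    assert InheritanceModel.XL in inference.models
    assert inference.models[0] is InheritanceModel.AD


def test_skipped_generation_excludes_dominant(full_cohort):
    ped = next(u for u in full_cohort.cohort.units if u.unit_id == "F04").pedigree
    inference = infer_modes(ped)
    assert InheritanceModel.AD not in inference.models
    assert inference.models[0] is InheritanceModel.XL


def test_simplex_returns_all_models_unconstrained():
    ped = _ped("S", [("p", None, None, _M, _A)])
    inference = infer_modes(ped)
    assert set(inference.models) == set(InheritanceModel)
    assert inference.unconstrained


def test_no_affected_raises():
    ped = make_trio(child_affected=False)
    with pytest.raises(InferenceError):
        infer_modes(ped)


# ---------------------------------------------------------------------------
# Genotype compatibility
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "gt,model,sex,aff,expected",
    [
        (Genotype.HET, InheritanceModel.XL, _F, _A, True),  # manifesting carrier
        (Genotype.HET, InheritanceModel.AR, _F, _A, False),  # one allele is not enough
        (Genotype.HOM_REF, InheritanceModel.AD, _M, _A, False),
        (Genotype.HET, InheritanceModel.AD, _M, _A, True),
        (Genotype.HEMI, InheritanceModel.XL, _M, _U, False),  # unaffected hemi male
        (Genotype.HET, InheritanceModel.XL, _F, _U, True),  # carrier, variable penetrance
    ],
)
def test_genotype_compatibility(gt, model, sex, aff, expected):
    ok, _ = genotype_compatible(gt, model, sex, aff)
    assert ok is expected


def test_complete_penetrance_rejects_unaffected_het_female():
    policy = InheritancePolicy(female_penetrance=FemalePenetrance.COMPLETE)
    ok, _ = genotype_compatible(Genotype.HET, InheritanceModel.XL, _F, _U, policy)
    assert not ok


def test_hemi_on_autosomal_model_is_data_error():
    with pytest.raises(ValueError):
        genotype_compatible(Genotype.HEMI, InheritanceModel.AD, _M, _A)


# ---------------------------------------------------------------------------
# Cosegregation
# ---------------------------------------------------------------------------


def _records_for(ped, gts, key=("1", 100, "A", "T")):
    rec = VariantRecord(*key, 99.0, {iid: gts.get(iid, Genotype.HOM_REF) for iid in ped.individuals})
    return {key: rec}


def test_dominant_candidate_cosegregates():
    ped = _three_gen_ad()
    records = _records_for(
        ped, {"I-1": Genotype.HET, "II-1": Genotype.HET, "III-1": Genotype.HET}
    )
    result = cosegregates((("1", 100, "A", "T"),), records, ped, InheritanceModel.AD)
    assert result.consistent and result.violations == ()


def test_variant_in_unaffected_sib_breaks_cosegregation():
    ped = _three_gen_ad()
    records = _records_for(
        ped,
        {
            "I-1": Genotype.HET,
            "II-1": Genotype.HET,
            "III-1": Genotype.HET,
            "I-2": Genotype.HET,  # unaffected carrier under AD: violation
        },
    )
    result = cosegregates((("1", 100, "A", "T"),), records, ped, InheritanceModel.AD)
    assert not result.consistent
    assert [v.individual for v in result.violations] == ["I-2"]


def test_xl_variable_penetrance_allows_unaffected_carrier(full_cohort):
    unit = next(u for u in full_cohort.cohort.units if u.unit_id == "F12")
    recs = {
        r.key: r
        for r in full_cohort.cohort.records["F12"]
        if r.chrom == "X" and any(g is Genotype.HEMI for g in r.genotypes.values())
    }
    key = next(iter(recs))
    result = cosegregates((key,), recs, unit.pedigree, InheritanceModel.XL)
    assert result.consistent


def test_missing_genotypes_skipped_and_listed():
    ped = _three_gen_ad()
    key = ("1", 100, "A", "T")
    gts = {"I-1": Genotype.HET, "II-1": Genotype.HET, "III-1": Genotype.MISSING}
    records = {key: VariantRecord(*key, 99.0, {i: gts.get(i, Genotype.HOM_REF) for i in ped.individuals})}
    result = cosegregates((key,), records, ped, InheritanceModel.AD)
    assert result.consistent and "III-1" in result.untested


def test_removing_individuals_never_flips_consistent_to_inconsistent():
    """Monotonicity in missing data: masking any genotyped member of a
    consistent configuration keeps it consistent."""
    ped = _three_gen_ad()
    key = ("1", 100, "A", "T")
    carrier = {"I-1": Genotype.HET, "II-1": Genotype.HET, "III-1": Genotype.HET}
    for masked in ped.individuals:
        gts = {
            i: (Genotype.MISSING if i == masked else carrier.get(i, Genotype.HOM_REF))
            for i in ped.individuals
        }
        records = {key: VariantRecord(*key, 99.0, gts)}
        assert cosegregates((key,), records, ped, InheritanceModel.AD).consistent


def test_ar_single_variant_without_pair_is_contract_error():
    ped = _ar_sibship()
    with pytest.raises(ValueError):
        cosegregates(
            (("1", 1, "A", "T"), ("1", 2, "A", "T"), ("1", 3, "A", "T")),
            {},
            ped,
            InheritanceModel.AR,
        )


def test_affected_without_candidate_allele_never_consistent():
    ped = _ar_sibship()
    k1, k2 = ("1", 100, "A", "T"), ("1", 200, "G", "C")
    gts1 = {"boy": Genotype.HET, "girl": Genotype.HOM_REF, "dad": Genotype.HET}
    gts2 = {"boy": Genotype.HET, "girl": Genotype.HET, "mum": Genotype.HET}
    records = {
        k1: VariantRecord(*k1, 99.0, {i: gts1.get(i, Genotype.HOM_REF) for i in ped.individuals}),
        k2: VariantRecord(*k2, 99.0, {i: gts2.get(i, Genotype.HOM_REF) for i in ped.individuals}),
    }
    result = cosegregates((k1, k2), records, ped, InheritanceModel.AR)
    assert not result.consistent
    assert any(v.individual == "girl" for v in result.violations)


# ---------------------------------------------------------------------------
# Compound hets and phasing
# ---------------------------------------------------------------------------


def _trio_records(dad_gt1, mum_gt1, dad_gt2, mum_gt2):
    k1, k2 = ("4", 100, "A", "T"), ("4", 200, "G", "C")
    r1 = VariantRecord(*k1, 99.0, {"dad": dad_gt1, "mum": mum_gt1, "kid": Genotype.HET})
    r2 = VariantRecord(*k2, 99.0, {"dad": dad_gt2, "mum": mum_gt2, "kid": Genotype.HET})
    return {k1: r1, k2: r2}, k1, k2


def test_pair_without_parents_assumed_trans(panel):
    k1, k2 = ("4", 100, "A", "T"), ("4", 200, "G", "C")
    recs = [
        VariantRecord(*k1, 99.0, {"p": Genotype.HET}),
        VariantRecord(*k2, 99.0, {"p": Genotype.HET}),
    ]
    pairs = find_compound_hets({"PDE6B": recs}, "p", panel, ped=None)
    assert len(pairs) == 1
    assert pairs[0].phase_status is PhaseStatus.ASSUMED_TRANS


def test_single_het_yields_no_pair(panel):
    recs = [VariantRecord("6", 100, "A", "T", 99.0, {"p": Genotype.HET})]
    assert find_compound_hets({"EYS": recs}, "p", panel, ped=None) == []


def test_trio_same_parent_resolved_cis():
    records, k1, k2 = _trio_records(
        Genotype.HET, Genotype.HOM_REF, Genotype.HET, Genotype.HOM_REF
    )
    ped = make_trio()
    assert resolve_phase(records, ped, "kid", k1, k2) is PhaseStatus.RESOLVED_CIS


def test_trio_opposite_parents_resolved_trans():
    records, k1, k2 = _trio_records(
        Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF, Genotype.HET
    )
    ped = make_trio()
    assert resolve_phase(records, ped, "kid", k1, k2) is PhaseStatus.RESOLVED_TRANS


def test_phase_matches_brute_force_enumeration():
    """Exhaustive check over all parental carrier configurations of a trio."""
    ped = make_trio()
    gts = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
    for d1, m1, d2, m2 in itertools.product(gts, repeat=4):
        records, k1, k2 = _trio_records(d1, m1, d2, m2)

        def origins(dad_gt, mum_gt):
            possible = []
            if dad_gt in (Genotype.HET, Genotype.HOM_ALT):
                possible.append("father")
            if mum_gt in (Genotype.HET, Genotype.HOM_ALT):
                possible.append("mother")
            return possible or ["father", "mother"]

        combos = list(itertools.product(origins(d1, m1), origins(d2, m2)))
        if all(a != b for a, b in combos):
            expected = PhaseStatus.RESOLVED_TRANS
        elif all(a == b for a, b in combos):
            expected = PhaseStatus.RESOLVED_CIS
        else:
            expected = PhaseStatus.ASSUMED_TRANS
        assert resolve_phase(records, ped, "kid", k1, k2) is expected
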