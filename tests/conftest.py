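"""Shared fixtures: small hand-built objects plus the packaged cohort."""

from __future__ import annotations

import pytest

from panelprio.fixtures import load_default_known_db, load_default_panel, load_fixture_cohort
from panelprio.models import (
    Affection,
    AnnotationRow,
    Consequence,
    Genotype,
    Individual,
    Pedigree,
    PolyPhen2,
    PredictorOutputs,
    ReferenceStatus,
    Sex,
    Sift,
    VariantRecord,
)


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def known_db():
    return load_default_known_db()


@pytest.fixture(scope="session")
def full_cohort():
    return load_fixture_cohort("full_cohort")


def make_annotation(
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    gene="RHO",
    exon=1,
    hgvs_c="c.100A>T",
    hgvs_p="p.K34X",
    consequence=Consequence.NONSYNONYMOUS,
    af_evs=None,
    af_1kg=None,
    af_inhouse=None,
    reference="novel",
):
    return AnnotationRow(
        variant_key=(chrom, pos, ref, alt),
        gene=gene,
        exon=exon,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        consequence=consequence,
        af_evs=af_evs,
        af_1kg=af_1kg,
        af_inhouse=af_inhouse,
        reference_status=ReferenceStatus(reference),
    )


def make_record(chrom="1", pos=1000, ref="A", alt="T", qual=99.0, genotypes=None):
    return VariantRecord(chrom, pos, ref, alt, qual, genotypes or {})


def make_trio(family_id="TRIO", child_sex=Sex.MALE, child_affected=True):
    rows = {
        "dad": Individual("dad", None, None, Sex.MALE, Affection.UNAFFECTED),
        "mum": Individual("mum", None, None, Sex.FEMALE, Affection.UNAFFECTED),
        "kid": Individual(
            "kid",
            "dad",
            "mum",
            child_sex,
            Affection.AFFECTED if child_affected else Affection.UNAFFECTED,
        ),
    }
    return Pedigree(family_id=family_id, individuals=rows)
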