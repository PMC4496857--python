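"""Per-unit prioritization, carrier demotion, summaries, end-to-end runs."""

from __future__ import annotations

import pytest

from panelprio.io_formats import AnnotationTable
from panelprio.models import (
    Affection,
    Consequence,
    Genotype,
    Individual,
    InheritanceModel,
    PathogenicityClass,
    Pedigree,
    PhaseStatus,
    PolyPhen2,
    PredictorOutputs,
    Sift,
    Sex,
    UnitKind,
    VariantRecord,
    CaseUnit,
)
from panelprio.prioritizer import (
    Cohort,
    ContractError,
    prioritize_unit,
    run_cohort,
    summarize_cohort,
)

from conftest import make_annotation


def _simplex_unit(uid="450", sex=Sex.MALE):
    iid = f"P{uid}"
    ind = Individual(iid, None, None, sex, Affection.AFFECTED)
    ped = Pedigree(family_id=uid, individuals={iid: ind})
    return CaseUnit(unit_id=uid, kind=UnitKind.SIMPLEX, pedigree=ped, proband_id=iid)


def _table_with(*rows):
    table = AnnotationTable()
    for ann, pred in rows:
        table.add(ann, pred)
    return table


def test_xl_family_yields_hemizygous_call(full_cohort):
    """The skipped-generation X-linked family resolves to a single Class II
    hemizygous call in its X-linked gene."""
    res = run_cohort(full_cohort.cohort)
    call = next(c for c in res.calls if c.unit_id == "F04" and c.primary)
    assert call.model is InheritanceModel.XL
    assert call.gene == "RP2"
    assert call.genotype_label == "Hemi"
    assert [c.value for c in call.member_classes] == [PathogenicityClass.II]
    assert call.segregation is not None and call.segregation.consistent


def test_compound_het_simplex_call_with_known_and_novel_allele(full_cohort):
    res = run_cohort(full_cohort.cohort)
    call = next(c for c in res.calls if c.unit_id == "440" and c.primary)
    assert call.model is InheritanceModel.AR
    assert call.gene == "EYS"
    assert sorted(c.value.roman for c in call.member_classes) == ["I", "II"]
    assert call.phase_status is PhaseStatus.ASSUMED_TRANS
    assert call.call_class is PathogenicityClass.I


def test_single_known_allele_in_recessive_gene_demoted_to_carrier(panel, known_db):
    """One qualifying allele in a recessive-only gene without a qualifying
    counter-allele produces a carrier record, not a solving call."""
    unit = _simplex_unit()
    iid = unit.proband_id
    known = make_annotation(
        chrom="1", pos=100, gene="USH2A", hgvs_p="p.C3416G",
        consequence=Consequence.NONSYNONYMOUS, reference="known",
    )
    # counter-allele is ensemble-unsupported missense (class III)
    weak = make_annotation(chrom="1", pos=200, gene="USH2A", hgvs_p="p.V2228E")
    table = _table_with(
        (known, PredictorOutputs(PolyPhen2.PROBABLY_DAMAGING, Sift.DAMAGING, 0.8)),
        (weak, PredictorOutputs(PolyPhen2.BENIGN, Sift.TOLERATED, 0.2)),
    )
    survivors = [
        VariantRecord("1", 100, "A", "T", 99.0, {iid: Genotype.HET}),
        VariantRecord("1", 200, "A", "T", 99.0, {iid: Genotype.HET}),
    ]
    calls, carriers, discarded = prioritize_unit(unit, survivors, table, panel, known_db)
    assert calls == []
    assert len(carriers) == 1
    assert carriers[0].gene == "USH2A" and carriers[0].variant.hgvs_p == "p.C3416G"
    # conservation: the class III counter-allele lands in the discard trace
    assert [d.variant_key for d in discarded] == [("1", 200, "A", "T")]


def test_homozygous_recessive_single_variant_call(panel, known_db):
    unit = _simplex_unit("ARHOM")
    iid = unit.proband_id
    ann = make_annotation(chrom="4", pos=100, gene="PDE6B", consequence=Consequence.NONSENSE,
                          hgvs_c="c.900C>A", hgvs_p="p.C300X")
    table = _table_with((ann, PredictorOutputs()))
    survivors = [VariantRecord("4", 100, "A", "T", 99.0, {iid: Genotype.HOM_ALT})]
    calls, carriers, _ = prioritize_unit(unit, survivors, table, panel, known_db)
    assert len(calls) == 1
    assert calls[0].model is InheritanceModel.AR
    assert calls[0].genotype_label == "Homo"


def test_off_panel_gene_never_called(panel, known_db):
    unit = _simplex_unit("OFF")
    iid = unit.proband_id
    ann = make_annotation(chrom="12", pos=100, gene="NOTONPANEL", consequence=Consequence.NONSENSE)
    table = _table_with((ann, PredictorOutputs()))
    survivors = [VariantRecord("12", 100, "A", "T", 99.0, {iid: Genotype.HET})]
    calls, carriers, discarded = prioritize_unit(unit, survivors, table, panel, known_db)
    assert calls == [] and carriers == []
    assert len(discarded) == 1


def test_every_survivor_accounted_for(full_cohort):
    """Conservation: each cascade survivor is a call member, a carrier
    record, or a discard with a reason — never silently dropped."""
    from panelprio.filter_cascade import run_cascade

    res = run_cohort(full_cohort.cohort)
    for unit in full_cohort.cohort.units:
        survivors, _ = run_cascade(
            full_cohort.cohort.records[unit.unit_id], full_cohort.cohort.annotations
        )
        called = {
            a.variant_key for c in res.calls if c.unit_id == unit.unit_id for a in c.variants
        }
        carried = {
            c.variant.variant_key
            for c in res.carriers
            if c.unit_id == unit.unit_id
        }
        dropped = {d.variant_key for d in res.discarded if d.unit_id == unit.unit_id}
        assert {r.key for r in survivors} == called | carried | dropped


def test_summary_recomputes_from_call_list(full_cohort):
    res = run_cohort(full_cohort.cohort)
    s = res.summary
    # independent recount
    primaries = [c for c in res.calls if c.primary]
    solved_units = {c.unit_id for c in primaries}
    fam_units = {u.unit_id for u in full_cohort.cohort.units if u.kind is UnitKind.FAMILIAL}
    assert s.solved_familial == len(solved_units & fam_units)
    assert s.solved_simplex == len(solved_units - fam_units)
    distinct = {a.variant_key: a for c in res.calls for a in c.variants}
    novel = sum(1 for a in distinct.values() if a.reference_status.is_novel)
    assert s.n_candidate_variants == len(distinct)
    assert s.novel_fraction == pytest.approx(100.0 * novel / len(distinct), abs=0.1)
    assert s.compound_het_count == sum(1 for c in primaries if len(c.variants) == 2)


def test_zero_units_is_contract_error():
    with pytest.raises(ContractError):
        summarize_cohort([], [], [])


def test_unit_without_genotyped_affected_is_contract_error(panel, known_db):
    ind = Individual("p", None, None, Sex.MALE, Affection.UNAFFECTED)
    ped = Pedigree(family_id="U", individuals={"p": ind})
    unit = CaseUnit(unit_id="U", kind=UnitKind.SIMPLEX, pedigree=ped, proband_id="p")
    with pytest.raises(ContractError):
        prioritize_unit(unit, [], AnnotationTable(), panel, known_db)


def test_empty_cohort_unit_yields_zero_calls(panel, known_db):
    unit = _simplex_unit("EMPTY")
    cohort = Cohort(
        units=[unit], records={"EMPTY": []}, annotations=AnnotationTable(),
        known_db=known_db, panel=panel,
    )
    result = run_cohort(cohort)
    assert result.calls == []
    assert result.summary.overall_rate == 0.0


def test_pipeline_files_round_trip(tmp_path, full_cohort):
    """Materialized fixture -> file-driven pipeline reproduces the in-memory
    result, and a second run is byte-identical."""
    from panelprio.fixtures import materialize_fixture
    from panelprio.prioritizer import run_pipeline

    manifest = materialize_fixture("full_cohort", tmp_path / "cohort")
    report1, summary = run_pipeline(manifest["config"])
    in_memory = run_cohort(full_cohort.cohort).summary
    assert summary.solved_familial == in_memory.solved_familial
    assert summary.solved_simplex == in_memory.solved_simplex
    assert summary.novel_fraction == in_memory.novel_fraction
    bytes1 = report1.read_bytes()
    report2, _ = run_pipeline(manifest["config"])
    assert report2.read_bytes() == bytes1


def test_config_schema_violation_names_key(tmp_path):
    from panelprio.prioritizer import ConfigError, load_config

    cfg = tmp_path / "bad.yaml"
    cfg.write_text("inputs: {vcf: a, ped: b, annotations: c, known_db: d, panel: e}\nbogus: 1\n")
    with pytest.raises(ConfigError, match="bogus"):
        load_config(cfg)


def test_missing_input_file_fails_before_processing(tmp_path):
    from panelprio.prioritizer import ConfigError, run_pipeline

    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "inputs:\n  vcf: missing.vcf\n  ped: missing.ped\n"
        "  annotations: missing.tsv\n  known_db: missing.tsv\n  panel: missing.tsv\n"
    )
    with pytest.raises(ConfigError, match="missing"):
        run_pipeline(cfg)
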