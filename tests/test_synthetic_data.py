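"""Synthetic cohort generator: Mendelian consistency, structural properties
per inheritance model, frequency realism, and determinism."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from panelprio.inheritance_engine import infer_modes
from panelprio.models import (
    Affection,
    Genotype,
    InheritanceModel,
    Sex,
)
from panelprio.prioritizer import run_cohort
from panelprio.synthetic_data import (
    LocusAllocator,
    SimulationConfig,
    _drop_background_genotypes,
    generate_cohort,
    materialize_cohort,
    simulate_pedigree,
)

CFG = SimulationConfig(seed=0)


def _rng(seed=0):
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Pedigree structure per model
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(10))
def test_dominant_pedigree_has_affected_in_every_generation(seed):
    sim = simulate_pedigree(InheritanceModel.AD, CFG, _rng(seed))
    levels = sim.pedigree.generation_levels()
    for members in levels.values():
        assert any(i.affection is Affection.AFFECTED for i in members)


@pytest.mark.parametrize("seed", range(10))
def test_recessive_affecteds_only_from_carrier_parents(seed):
    sim = simulate_pedigree(InheritanceModel.AR, CFG, _rng(seed))
    for ind in sim.pedigree.affected():
        assert ind.father is not None, "recessive affecteds arise within the pedigree"
        assert sim.carriers[ind.father][0] + sim.carriers[ind.father][1] >= 1
        assert sim.carriers[ind.mother][0] + sim.carriers[ind.mother][1] >= 1
        father = sim.pedigree.individuals[ind.father]
        mother = sim.pedigree.individuals[ind.mother]
        assert father.affection is Affection.UNAFFECTED
        assert mother.affection is Affection.UNAFFECTED


@pytest.mark.parametrize("seed", range(10))
def test_xlinked_pedigree_never_transmits_male_to_male(seed):
    sim = simulate_pedigree(InheritanceModel.XL, CFG, _rng(seed), family_id="X")
    ped = sim.pedigree
    for ind in ped.individuals.values():
        if ind.sex is Sex.MALE and sim.carriers[ind.iid][0] >= 1 and ind.father:
            assert sim.carriers[ind.father][0] == 0, "son's X never comes from his father"


@pytest.mark.parametrize("seed", range(15))
def test_planted_model_always_inferable(seed):
    """With complete penetrance, the planted model is among the inferred
    models for every simulated familial pedigree."""
    cfg = SimulationConfig(seed=0, female_penetrance=1.0)
    for model in InheritanceModel:
        sim = simulate_pedigree(model, cfg, _rng(seed * 3 + hash(model.value) % 97))
        assert model in infer_modes(sim.pedigree).models


def test_planted_carrier_states_are_mendelian():
    """Every carrier configuration is reachable from parental states by
    brute-force transmission enumeration."""
    for seed in range(8):
        for model in InheritanceModel:
            sim = simulate_pedigree(model, CFG, _rng(seed))
            on_x = model is InheritanceModel.XL
            for ind in sim.pedigree.individuals.values():
                if ind.is_founder:
                    continue
                a_child = sim.carriers[ind.iid][0]
                fa = sim.carriers[ind.father][0]
                mo = sim.carriers[ind.mother][0]
                possible = set()
                if on_x:
                    from_m = {0} if mo == 0 else ({1} if mo == 2 else {0, 1})
                    if ind.sex is Sex.MALE:
                        possible = from_m
                    else:
                        possible = {fa + m for m in from_m}
                else:
                    from_f = {0} if fa == 0 else ({1} if fa == 2 else {0, 1})
                    from_m = {0} if mo == 0 else ({1} if mo == 2 else {0, 1})
                    possible = {f + m for f, m in itertools.product(from_f, from_m)}
                assert a_child in possible


# ---------------------------------------------------------------------------
# Background variation
# ---------------------------------------------------------------------------


def test_background_genotypes_are_mendelian():
    sim = simulate_pedigree(InheritanceModel.AD, CFG, _rng(3))
    ped = sim.pedigree
    rng = _rng(11)
    copies_of = {
        Genotype.HOM_REF: 0, Genotype.HET: 1, Genotype.HOM_ALT: 2, Genotype.HEMI: 1,
    }
    for af in (0.01, 0.2, 0.5):
        gts = _drop_background_genotypes(ped, af, False, rng)
        for ind in ped.individuals.values():
            if ind.is_founder:
                continue
            child = copies_of[gts[ind.iid]]
            fa, mo = copies_of[gts[ind.father]], copies_of[gts[ind.mother]]
            from_f = {0} if fa == 0 else ({1} if fa == 2 else {0, 1})
            from_m = {0} if mo == 0 else ({1} if mo == 2 else {0, 1})
            assert child in {f + m for f in from_f for m in from_m}


def test_founder_frequency_converges_to_nominal():
    """Law-of-large-numbers check: the empirical allele frequency across a
    large founder pool stays within 3 standard errors of nominal."""
    from panelprio.models import Individual, Pedigree

    n = 2000
    inds = {
        f"f{i}": Individual(f"f{i}", None, None, Sex.FEMALE, Affection.UNAFFECTED)
        for i in range(n)
    }
    ped = Pedigree(family_id="POOL", individuals=inds)
    rng = _rng(5)
    for af in (0.05, 0.2, 0.5):
        gts = _drop_background_genotypes(ped, af, False, rng)
        count = sum({Genotype.HOM_REF: 0, Genotype.HET: 1, Genotype.HOM_ALT: 2}[g] for g in gts.values())
        emp = count / (2 * n)
        se = (af * (1 - af) / (2 * n)) ** 0.5
        assert abs(emp - af) <= 3 * se


# ---------------------------------------------------------------------------
# Whole cohorts
# ---------------------------------------------------------------------------


def test_generation_is_deterministic(tmp_path):
    cfg = SimulationConfig(seed=42, n_families=2, n_simplex=2, background_rate=10)
    materialize_cohort(generate_cohort(cfg), tmp_path / "a")
    materialize_cohort(generate_cohort(cfg), tmp_path / "b")
    files_a = sorted((tmp_path / "a").glob("*"))
    files_b = sorted((tmp_path / "b").glob("*"))
    assert [f.name for f in files_a] == [f.name for f in files_b]
    for fa, fb in zip(files_a, files_b):
        if fa.is_file():
            assert fa.read_bytes() == fb.read_bytes(), fa.name


def test_all_positive_detection_rate_is_total():
    cfg = SimulationConfig(seed=7, n_families=3, n_simplex=3,
                           predictor_fidelity=1.0, female_penetrance=1.0,
                           background_rate=10)
    res = run_cohort(generate_cohort(cfg).cohort)
    assert res.summary.overall_rate == 100.0


def test_all_negative_detection_rate_is_zero():
    cfg = SimulationConfig(seed=8, n_families=2, n_simplex=2,
                           negative_fraction=1.0, background_rate=20)
    res = run_cohort(generate_cohort(cfg).cohort)
    assert res.summary.overall_rate == 0.0


def test_negatives_still_carry_background():
    cfg = SimulationConfig(seed=9, n_families=1, n_simplex=1,
                           negative_fraction=1.0, background_rate=20)
    sim = generate_cohort(cfg)
    assert all(len(recs) > 0 for recs in sim.cohort.records.values())


def test_planted_truth_classes_match_classifier():
    """The generator's intended class for each planted allele is what the
    classifier assigns."""
    from panelprio.pathogenicity_classifier import classify_members

    cfg = SimulationConfig(seed=13, n_families=4, n_simplex=4, predictor_fidelity=1.0)
    sim = generate_cohort(cfg)
    for truth in sim.truths:
        anns = tuple(sim.cohort.annotations.rows[k] for k in truth.keys)
        classes = classify_members(anns, sim.cohort.annotations, sim.cohort.known_db)
        assert tuple(c.value for c in classes) == truth.expected_classes
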