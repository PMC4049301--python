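"""Mendelian trio checks, phasing from parents and recessive co-segregation."""

import itertools

import pandas as pd
import pytest

from ciliaseek.segregation import (
    Individual,
    Pedigree,
    PedigreeError,
    cosegregation_test,
    mendelian_check,
    pedigrees_from_ped,
    trans_phase_from_parents,
)
from ciliaseek.variants import HET, HOM_ALT, HOM_REF, MISSING


def _trio_ped(affected_child=True):
    df = pd.DataFrame(
        [
            ("F1", "dad", "0", "0", 1, 1),
            ("F1", "mum", "0", "0", 2, 1),
            ("F1", "kid", "dad", "mum", 2, 2 if affected_child else 1),
        ],
        columns=["family", "individual", "father", "mother", "sex", "phenotype"],
    )
    return Pedigree.from_frame("F1", df)


# ---------------------------------------------------------------------------
# Mendelian check


def test_het_parents_hom_child_consistent():
    ok, detail = mendelian_check(HOM_ALT, HET, HET)
    assert ok and detail is None


def test_de_novo_flagged():
    ok, detail = mendelian_check(HET, HOM_REF, HOM_REF)
    assert not ok
    assert "de novo" in detail


def test_missing_parent_defaults_consistent():
    assert mendelian_check(HOM_ALT, None, HET)[0]  # missing father unconstrained
    assert mendelian_check(HOM_ALT, MISSING, HET)[0]
    # the genotyped parent still constrains: hom-ref mother cannot give alt
    assert not mendelian_check(HOM_ALT, None, HOM_REF)[0]


def test_malformed_genotype_raises():
    with pytest.raises(ValueError):
        mendelian_check(7, HET, HET)


def test_mendelian_matches_exhaustive_allele_assignment():
    """Agreement with an oracle that enumerates transmitted alleles."""

    def alleles(code):
        return {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}[code]

    codes = [HOM_REF, HET, HOM_ALT]
    for child, father, mother in itertools.product(codes, repeat=3):
        possible = {
            tuple(sorted((f, m)))
            for f in alleles(father)
            for m in alleles(mother)
        }
        expected = tuple(sorted(alleles(child))) in possible
        assert mendelian_check(child, father, mother)[0] == expected


# ---------------------------------------------------------------------------
# Phase from parental carriage


def test_phase_trans_and_cis_examples():
    assert trans_phase_from_parents(True, False, False, True) == "trans"
    assert trans_phase_from_parents(True, True, False, False) == "cis"


def test_phase_enumeration_matches_truth_table():
    for fa, fb, ma, mb in itertools.product([False, True], repeat=4):
        result = trans_phase_from_parents(fa, fb, ma, mb)
        if (fa, fb) in [(True, False), (False, True)] and (ma, mb) in [
            (True, False),
            (False, True),
        ] and (fa, fb) != (ma, mb):
            assert result == "trans"
        elif (fa and fb and not ma and not mb) or (ma and mb and not fa and not fb):
            assert result == "cis"
        else:
            assert result == "unknown"


# ---------------------------------------------------------------------------
# Co-segregation verdicts


KEYS = ["c1:10:A:G", "c1:20:C:T"]


def test_unaffected_homozygote_excludes():
    """A gene whose candidate variants are homozygous in unaffected relatives
    fails co-segregation (the exclusion that removed two candidate genes)."""
    df = pd.DataFrame(
        [
            ("F1", "dad", "0", "0", 1, 1),
            ("F1", "mum", "0", "0", 2, 1),
            ("F1", "kid", "dad", "mum", 2, 2),
            ("F1", "uncle", "0", "0", 1, 1),
        ],
        columns=["family", "individual", "father", "mother", "sex", "phenotype"],
    )
    ped = Pedigree.from_frame("F1", df)
    gts = {
        "kid": {KEYS[0]: HOM_ALT},
        "dad": {KEYS[0]: HET},
        "mum": {KEYS[0]: HET},
        "uncle": {KEYS[0]: HOM_ALT},
    }
    verdict = cosegregation_test(ped, gts, "WDR66", [KEYS[0]])
    assert verdict.status == "excludes"
    assert any("uncle" in r for r in verdict.reasons)


def test_compound_het_with_carrier_parents_supports():
    """Affected child het for two variants, each parent carrying one: the
    variants are in trans and the gene is supported."""
    ped = _trio_ped()
    gts = {
        "kid": {KEYS[0]: HET, KEYS[1]: HET},
        "dad": {KEYS[0]: HET, KEYS[1]: HOM_REF},
        "mum": {KEYS[0]: HOM_REF, KEYS[1]: HET},
    }
    verdict = cosegregation_test(ped, gts, "RSPH1", KEYS)
    assert verdict.status == "supports"
    assert verdict.phase_verified


def test_double_het_without_parents_supports_unverified():
    ped = _trio_ped()
    gts = {"kid": {KEYS[0]: HET, KEYS[1]: HET}}
    verdict = cosegregation_test(ped, gts, "RSPH1", KEYS)
    assert verdict.status == "supports"
    assert not verdict.phase_verified


def test_cis_configuration_excludes():
    """Both variants inherited from one parent: affected child is not
    biallelic, so the gene is excluded."""
    ped = _trio_ped()
    gts = {
        "kid": {KEYS[0]: HET, KEYS[1]: HET},
        "dad": {KEYS[0]: HET, KEYS[1]: HET},
        "mum": {KEYS[0]: HOM_REF, KEYS[1]: HOM_REF},
    }
    verdict = cosegregation_test(ped, gts, "RSPH1", KEYS)
    assert verdict.status == "excludes"


def test_all_missing_is_uninformative():
    ped = _trio_ped()
    gts = {
        "kid": {k: MISSING for k in KEYS},
        "dad": {k: MISSING for k in KEYS},
        "mum": {k: MISSING for k in KEYS},
    }
    verdict = cosegregation_test(ped, gts, "RSPH1", KEYS)
    assert verdict.status == "uninformative"


def test_no_candidate_variants_is_uninformative():
    verdict = cosegregation_test(_trio_ped(), {}, "RSPH1", [])
    assert verdict.status == "uninformative"
    assert verdict.reasons


def test_verdict_invariant_to_member_ordering():
    rows = [
        ("F1", "dad", "0", "0", 1, 1),
        ("F1", "mum", "0", "0", 2, 1),
        ("F1", "kid", "dad", "mum", 2, 2),
        ("F1", "sib", "dad", "mum", 1, 1),
    ]
    gts = {
        "kid": {KEYS[0]: HOM_ALT},
        "dad": {KEYS[0]: HET},
        "mum": {KEYS[0]: HET},
        "sib": {KEYS[0]: HOM_ALT},
    }
    verdicts = []
    for perm in itertools.permutations(rows):
        df = pd.DataFrame(
            list(perm),
            columns=["family", "individual", "father", "mother", "sex", "phenotype"],
        )
        ped = Pedigree.from_frame("F1", df)
        verdicts.append(cosegregation_test(ped, gts, "G", [KEYS[0]]))
    assert len({(v.status, tuple(v.reasons)) for v in verdicts}) == 1


# ---------------------------------------------------------------------------
# Pedigree validation


def test_unresolved_parent_rejected():
    df = pd.DataFrame(
        [("F1", "kid", "ghost", "0", 1, 2)],
        columns=["family", "individual", "father", "mother", "sex", "phenotype"],
    )
    with pytest.raises(PedigreeError):
        Pedigree.from_frame("F1", df)


def test_ancestry_cycle_rejected():
    with pytest.raises(PedigreeError):
        Pedigree(
            "F1",
            {
                "a": Individual("a", "b", None, 1, False),
                "b": Individual("b", "a", None, 1, False),
            },
        )


def test_cohort_pedigrees_parse(small_cohort):
    sim, _ = small_cohort
    peds = pedigrees_from_ped(sim.ped)
    assert len(peds) == len(sim.case_samples) + len(sim.control_samples)
    fam1 = peds["FAM001"]
    assert fam1.affected_ids == ["CASE001"]
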