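"""The deterministic synthetic cohort generator."""

import filecmp

import numpy as np
import pytest
from scipy.stats import binom

from ciliaseek.cascade import restrict_to_regions
from ciliaseek.synthetic import (
    CILIA_GENES,
    CohortSpec,
    FixtureSpec,
    FixtureSpecError,
    lof_site_pool,
    make_panel,
    make_rsph1_fixture,
    simulate_cohort,
    write_inputs,
)
from ciliaseek.variants import HET, HOM_ALT, read_vcf


SMALL = CohortSpec(n_cases=3, n_controls=8, n_background_variants=300, seed=11)


# ---------------------------------------------------------------------------
# Transcript fixture anatomy


def test_fixture_anatomy(fixture_plus):
    tx = fixture_plus.transcript
    assert tx.n_exons == 8
    assert tx.length == 1400
    assert tx.span[1] - tx.span[0] + 1 == 24000
    assert tx.protein.endswith("*")
    assert len(tx.protein) - 1 == 309
    assert tx.protein[28] == "E" and tx.protein[93] == "W"


def test_fixture_exon4_starts_at_c275(fixture_plus):
    tx = fixture_plus.transcript
    # first base of the fourth transcript-order exon is coding position 275
    t_start = tx._tx_order_exons[3][0]
    assert tx.transcript_to_coding(t_start).position == 275


def test_minus_strand_fixture_same_cdna(fixture_plus, fixture_minus):
    assert fixture_minus.transcript.sequence == fixture_plus.transcript.sequence
    assert fixture_minus.transcript.protein == fixture_plus.transcript.protein


def test_fixture_deterministic():
    a = make_rsph1_fixture(FixtureSpec(seed=5))
    b = make_rsph1_fixture(FixtureSpec(seed=5))
    assert a.transcript == b.transcript
    assert a.genome == b.genome


def test_fixture_exon_count_stable_across_seeds():
    for seed in range(5):
        fx = make_rsph1_fixture(FixtureSpec(seed=seed))
        assert fx.transcript.n_exons == 8


def test_contradictory_pin_rejected_by_name():
    with pytest.raises(FixtureSpecError, match="400"):
        make_rsph1_fixture(FixtureSpec(pinned_residues={400: "W"}))
    # exon 8 starting at c.1 would force seven exons into the 100 nt 5' UTR
    with pytest.raises(FixtureSpecError, match="8@1"):
        make_rsph1_fixture(FixtureSpec(pinned_exon_starts={8: 1}))


def test_lof_pool_nonempty_and_verified(fixture_plus):
    pool = lof_site_pool(fixture_plus.transcript, fixture_plus.genome)
    assert len(pool) >= 10
    assert len({v.key for v, _ in pool}) == len(pool)
    assert all(name.startswith("c.") for _, name in pool)


# ---------------------------------------------------------------------------
# Panel


def test_panel_composition():
    panel = make_panel(seed=0)
    assert len(panel.transcripts) == len(CILIA_GENES) + 16
    assert set(panel.cilia_genes) <= set(panel.genes)
    # every gene sits on its own contig
    contigs = [t.contig for t in panel.transcripts]
    assert len(set(contigs)) == len(contigs)
    strands = {t.strand for t in panel.transcripts}
    assert strands == {"+", "-"}


# ---------------------------------------------------------------------------
# Cohort structure


@pytest.fixture(scope="module")
def sim():
    return simulate_cohort(SMALL)


def test_all_variants_fall_in_bait_regions(sim):
    regions = sim.panel.bait_regions()
    kept = restrict_to_regions(sim.variants, regions, window=0)
    assert len(kept) == len(sim.variants)


def test_every_case_planted_biallelic(sim):
    for case in sim.case_samples:
        plants = sim.truth.plants_for_sample(case)
        assert sim.truth.case_is_biallelic(case)
        gts = sim.genotypes[case]
        for p in plants:
            expected = HOM_ALT if p.zygosity == "hom" else HET
            assert gts[p.variant_key] == expected
            assert p.gene == sim.truth.causal_gene


def test_controls_carry_no_planted_allele(sim):
    planted_keys = {p.variant_key for p in sim.truth.plants}
    for ctrl in sim.control_samples:
        assert (sim.genotypes.loc[sorted(planted_keys), ctrl] == 0).all()


def test_parents_are_obligate_carriers_in_trans(sim):
    for case in sim.case_samples:
        plants = sim.truth.plants_for_sample(case)
        assert len(plants) == 2  # compound_het default mode
        (a, b) = plants
        assert sim.genotypes[f"{case}F"][a.variant_key] == HET
        assert sim.genotypes[f"{case}F"][b.variant_key] == 0
        assert sim.genotypes[f"{case}M"][b.variant_key] == HET
        assert sim.genotypes[f"{case}M"][a.variant_key] == 0


def test_consanguineous_family_in_homozygous_mode():
    spec = CohortSpec(
        n_cases=2, n_controls=2, n_background_variants=100,
        causal_mode="homozygous", seed=3,
    )
    sim = simulate_cohort(spec)
    fam1 = sim.ped[sim.ped["family"] == "FAM001"]
    affected = set(fam1[fam1["phenotype"] == 2]["individual"])
    assert affected == {"CASE001", "CASE001S"}
    # parents are first cousins: each descends from the shared grandparents
    by_id = fam1.set_index("individual")
    father, mother = by_id.loc["CASE001F"], by_id.loc["CASE001M"]
    assert by_id.loc[father["father"], "father"] == "FAM001_GGF"
    assert by_id.loc[mother["father"], "father"] == "FAM001_GGF"
    # both affected sibs are homozygous, the unaffected sib is a carrier
    key = sim.truth.plants_for_sample("CASE001")[0].variant_key
    assert sim.genotypes["CASE001"][key] == HOM_ALT
    assert sim.genotypes["CASE001S"][key] == HOM_ALT
    assert sim.genotypes["CASE001U"][key] == HET


def test_unknown_causal_mode_rejected():
    with pytest.raises(ValueError):
        simulate_cohort(CohortSpec(causal_mode="dominant"))


# ---------------------------------------------------------------------------
# Allele-frequency spectrum calibration


def test_background_genotypes_match_hardy_weinberg_spectrum():
    """Observed allele counts lie within exact binomial(2n, q) 99.9% bands
    for at least 99% of background variants at n = 600 samples."""
    spec = CohortSpec(n_cases=1, n_controls=597, n_background_variants=500, seed=2)
    sim = simulate_cohort(spec)
    planted = {p.variant_key for p in sim.truth.plants}
    bg_keys = [v.key for v in sim.variants if v.key not in planted]
    n_alleles = 2 * sim.genotypes.shape[1]
    within = 0
    for key in bg_keys:
        q = sim.truth.true_frequencies[key]
        count = int(sim.genotypes.loc[key].clip(lower=0).sum())
        lo, hi = binom.ppf([0.0005, 0.9995], n_alleles, q)
        within += lo <= count <= hi
    assert within / len(bg_keys) >= 0.99


def test_true_frequencies_cover_every_variant(sim):
    assert set(sim.truth.true_frequencies) == {v.key for v in sim.variants}
    assert all(0 < q <= 0.5 for q in sim.truth.true_frequencies.values())


# ---------------------------------------------------------------------------
# File output determinism and round trip


def test_write_inputs_byte_identical(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    write_inputs(simulate_cohort(SMALL), a)
    paths = write_inputs(simulate_cohort(SMALL), b)
    for name, path_b in paths.items():
        assert filecmp.cmp(a / path_b.name, path_b, shallow=False), name


def test_different_seed_different_output(tmp_path):
    p1 = write_inputs(simulate_cohort(SMALL), tmp_path / "s11")
    other = CohortSpec(n_cases=3, n_controls=8, n_background_variants=300, seed=12)
    p2 = write_inputs(simulate_cohort(other), tmp_path / "s12")
    assert not filecmp.cmp(p1["vcf"], p2["vcf"], shallow=False)


def test_vcf_round_trip(sim, tmp_path):
    paths = write_inputs(sim, tmp_path)
    variants, genotypes = read_vcf(paths["vcf"])
    assert variants == sorted(sim.variants)
    assert list(genotypes.columns) == list(sim.genotypes.columns)
    reordered = sim.genotypes.loc[genotypes.index]
    assert (genotypes.values == reordered.values).all()


def test_output_files_are_small_text(tmp_path):
    """Everything the generator writes is plain text under 64 KiB per file."""
    paths = write_inputs(simulate_cohort(SMALL), tmp_path)
    for path in paths.values():
        raw = path.read_bytes()
        assert b"\x00" not in raw
        raw.decode("ascii")
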