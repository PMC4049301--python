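"""The rare-recessive filtering cascade and its report identities."""

import pytest
from hypothesis import given, strategies as st

from ciliaseek.cascade import (
    CascadeReport,
    ConfigurationError,
    candidate_list_intersection,
    final_candidate_genes,
    frequency_filter,
    recessive_gene_candidates,
    restrict_to_regions,
    run_cascade,
    zygosity_partition,
)
from ciliaseek.cascade import functional_class_filter
from ciliaseek.consequence import FUNCTIONAL_CLASSES
from ciliaseek.variants import HET, HOM_ALT, HOM_REF, MISSING, FrequencyTable, Variant


def _v(pos, chrom="c1", ref="A", alt="G"):
    return Variant(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Region restriction


def test_window_boundary_inclusive():
    regions = [("c1", 1000, 2000, "r1")]
    inside = _v(2100)   # exactly window bases past the end
    outside = _v(2101)  # one base further
    kept = restrict_to_regions([inside, outside], regions, window=100)
    assert kept == [inside]


def test_window_zero_keeps_in_region_variant():
    regions = [("c1", 1000, 2000, "r1")]
    assert restrict_to_regions([_v(1000), _v(2000), _v(999)], regions, window=0) == [
        _v(1000),
        _v(2000),
    ]


def test_unknown_contig_dropped():
    assert restrict_to_regions([_v(5, chrom="other")], [("c1", 1, 10, "r")], 0) == []


@given(
    regions=st.lists(
        st.tuples(st.integers(1, 500), st.integers(0, 50)), min_size=1, max_size=10
    ),
    positions=st.lists(st.integers(1, 600), min_size=1, max_size=30),
    window=st.integers(0, 20),
)
def test_region_restriction_matches_naive_oracle(regions, positions, window):
    region_tuples = [("c1", s, s + ln, f"r{i}") for i, (s, ln) in enumerate(regions)]
    variants = [_v(p) for p in sorted(set(positions))]
    kept = restrict_to_regions(variants, region_tuples, window)
    naive = [
        v
        for v in variants
        if any(s - window <= v.pos <= e + window for _c, s, e, _n in region_tuples)
    ]
    assert kept == naive


# ---------------------------------------------------------------------------
# Frequency filter


def test_frequency_filter_rule():
    table = FrequencyTable()
    table.add("c1:1:A:G", "EVS", 0.005)
    table.add("c1:2:A:G", "EVS", 0.005)
    table.add("c1:2:A:G", "KG1000", 0.02)
    kept = frequency_filter([_v(1), _v(2), _v(3)], table)
    # maf 0.005 kept; max(0.005, 0.02) dropped; novel kept
    assert kept == [_v(1), _v(3)]


def test_carrier_derived_rare_allele_is_kept():
    """An allele carried het by 5 of 6500 control individuals has MAF
    5/13000 < 0.01 and survives the frequency filter."""
    table = FrequencyTable()
    table.add("c1:1:A:G", "EVS", 5 / 13000)
    assert frequency_filter([_v(1)], table) == [_v(1)]


def test_frequency_folding_above_half():
    table = FrequencyTable()
    table.add("c1:1:A:G", "EVS", 0.999)  # folded to 0.001
    assert table.max_maf("c1:1:A:G") == pytest.approx(0.001)
    assert frequency_filter([_v(1)], table) == [_v(1)]


@given(
    mafs=st.lists(
        st.one_of(st.none(), st.floats(min_value=0.0, max_value=0.5)),
        min_size=1,
        max_size=40,
    ),
    threshold=st.floats(min_value=0.001, max_value=0.5),
)
def test_frequency_filter_matches_rowwise_oracle(mafs, threshold):
    table = FrequencyTable()
    variants = []
    for i, maf in enumerate(mafs):
        v = _v(i + 1)
        variants.append(v)
        if maf is not None:
            table.add(v.key, "EVS", maf)
    kept = frequency_filter(variants, table, threshold)
    oracle = [
        v
        for v, maf in zip(variants, mafs)
        if maf is None or maf < threshold
    ]
    assert kept == oracle


# ---------------------------------------------------------------------------
# Zygosity partition


def test_zygosity_partition_codes():
    variants = [_v(1), _v(2), _v(3), _v(4)]
    gts = {"c1:1:A:G": HET, "c1:2:A:G": HOM_ALT, "c1:3:A:G": HOM_REF, "c1:4:A:G": MISSING}
    het, hom = zygosity_partition(variants, gts)
    assert het == [_v(1)] and hom == [_v(2)]


@given(codes=st.lists(st.sampled_from([HOM_REF, HET, HOM_ALT, MISSING]), max_size=50))
def test_partition_sizes_sum_to_carried_count(codes):
    variants = [_v(i + 1) for i in range(len(codes))]
    gts = {v.key: c for v, c in zip(variants, codes)}
    het, hom = zygosity_partition(variants, gts)
    carried = sum(1 for c in codes if c in (HET, HOM_ALT))
    assert len(het) + len(hom) == carried
    assert not set(het) & set(hom)


# ---------------------------------------------------------------------------
# Report identities


def test_report_identities_hold_for_published_branch_counts():
    """het + hom = MAF-filtered total for the printed per-individual counts
    of the two index families (462+125=587 and 514+155=669)."""
    for total, maf, het, het_fn, genes_ch, genes_ch_cilia, hom, hom_fn, hom_cilia in [
        (5064, 587, 462, 130, 8, 2, 125, 9, 0),
        (5612, 669, 514, 92, 9, 2, 155, 7, 3),
    ]:
        report = CascadeReport(
            sample="fixture",
            counts={
                "total": total,
                "maf_filtered": maf,
                "het": het,
                "het_functional": het_fn,
                "genes_compound_het": genes_ch,
                "genes_compound_het_cilia": genes_ch_cilia,
                "hom": hom,
                "hom_functional": hom_fn,
                "genes_hom_cilia": hom_cilia,
            },
        )
        report.validate()
        assert report.counts["het"] + report.counts["hom"] == report.counts["maf_filtered"]


def test_report_validation_rejects_broken_partition():
    report = CascadeReport(
        sample="bad",
        counts={
            "total": 10,
            "maf_filtered": 5,
            "het": 3,
            "het_functional": 1,
            "genes_compound_het": 0,
            "genes_compound_het_cilia": 0,
            "hom": 3,
            "hom_functional": 1,
            "genes_hom_cilia": 0,
        },
    )
    with pytest.raises(ValueError, match="partition"):
        report.validate()


# ---------------------------------------------------------------------------
# Gene-level recessive model and panel intersection


def test_compound_het_gene_is_candidate(small_cohort):
    sim, annotations = small_cohort
    case = sim.case_samples[0]
    keys = [p.variant_key for p in sim.truth.plants_for_sample(case)]
    variants = [v for v in sim.variants if v.key in keys]
    compound, hom = recessive_gene_candidates(variants, [], annotations)
    assert sim.truth.causal_gene in compound


def test_single_het_not_a_candidate(small_cohort):
    sim, annotations = small_cohort
    case = sim.case_samples[0]
    keys = [p.variant_key for p in sim.truth.plants_for_sample(case)][:1]
    variants = [v for v in sim.variants if v.key in keys]
    compound, hom = recessive_gene_candidates(variants, [], annotations)
    assert compound == {}


@given(
    data=st.lists(
        st.tuples(st.integers(0, 5), st.sampled_from([HET, HOM_ALT])),
        min_size=0,
        max_size=20,
    )
)
def test_recessive_candidates_match_bruteforce(data):
    """Random (gene, zygosity) assignments agree with direct enumeration."""

    class FakeRec:
        def __init__(self, gene):
            self.gene = gene

    annotations = {}
    het, hom = [], []
    for i, (gene_idx, code) in enumerate(data):
        v = _v(i + 1)
        annotations[v.key] = [FakeRec(f"G{gene_idx}")]
        (het if code == HET else hom).append(v)
    compound, hom_by_gene = recessive_gene_candidates(het, hom, annotations)
    genes = {f"G{i}" for i in range(6)}
    for gene in genes:
        n_het = len({v for v in het if annotations[v.key][0].gene == gene})
        n_hom = len([v for v in hom if annotations[v.key][0].gene == gene])
        assert (gene in compound) == (n_het >= 2)
        assert (gene in hom_by_gene) == (n_hom >= 1)


def test_panel_intersection_case_insensitive():
    result = candidate_list_intersection(
        ["DNAH12", "rsph1", "ABC1"], ["RSPH1", "RSPH4A", "DNAH12"]
    )
    assert set(result) == {"DNAH12", "rsph1"}


def test_panel_intersection_empty_inputs():
    assert candidate_list_intersection([], ["RSPH1"]) == {}
    with pytest.raises(ConfigurationError):
        candidate_list_intersection(["RSPH1"], [])


@given(
    genes=st.sets(st.sampled_from([f"G{i}" for i in range(20)]), max_size=15),
    panel=st.sets(st.sampled_from([f"G{i}" for i in range(20)]), min_size=1, max_size=15),
)
def test_intersection_matches_set_operation(genes, panel):
    result = candidate_list_intersection(sorted(genes), sorted(panel))
    assert set(result) == genes & panel


# ---------------------------------------------------------------------------
# Full cascade on the simulated cohort


def test_cascade_filters_commute(small_cohort):
    """Frequency and functional-class filters give the same final set in
    either order."""
    sim, annotations = small_cohort
    for sample in sim.case_samples[:2] + sim.control_samples[:2]:
        gts = sim.genotypes[sample].to_dict()
        carried = [v for v in sim.variants if gts.get(v.key, MISSING) in (HET, HOM_ALT)]
        a = functional_class_filter(
            frequency_filter(carried, sim.frequencies), annotations
        )
        b = frequency_filter(
            functional_class_filter(carried, annotations), sim.frequencies
        )
        assert a == b


def test_cascade_final_set_matches_bruteforce(small_cohort):
    """The cascade's final candidate genes equal a direct application of all
    filter rules at once."""
    sim, annotations = small_cohort
    regions = sim.panel.bait_regions()
    cilia = set(sim.panel.cilia_genes)
    for sample in sim.case_samples:
        gts = sim.genotypes[sample].to_dict()
        report = run_cascade(
            sample, sim.variants, gts, annotations, sim.frequencies, regions, sim.panel.cilia_genes
        )
        # brute force
        per_gene_het, per_gene_hom = {}, {}
        for v in sim.variants:
            code = gts.get(v.key, MISSING)
            if code not in (HET, HOM_ALT):
                continue
            maf = sim.frequencies.max_maf(v.key)
            if maf is not None and maf >= 0.01:
                continue
            recs = [r for r in annotations[v.key] if r.csq_class in FUNCTIONAL_CLASSES]
            for rec in recs:
                target = per_gene_het if code == HET else per_gene_hom
                target.setdefault(rec.gene, set()).add(v.key)
        expected = {
            g for g, vs in per_gene_het.items() if len(vs) >= 2 and g in cilia
        } | {g for g in per_gene_hom if g in cilia}
        assert final_candidate_genes(report) == expected
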