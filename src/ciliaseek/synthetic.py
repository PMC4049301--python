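"""Deterministic synthetic inputs for end-to-end validation.

This module generates everything the pipeline consumes — genome segments,
transcript models, a multi-sample cohort VCF, a population allele-frequency
table, panel BED regions, pedigrees and a candidate gene list — with the
statistical structure the recessive analysis assumes, plus a truth table of
planted causal genotypes for recovery testing.

The flagship fixture emulates the anatomy of the human RSPH1 transcript: a
1.4 kb, 8-exon cDNA spanning 24 kb of genomic sequence encoding a
309-residue protein, with Glu pinned at residue 29 (codon GAG), Trp at
residue 94 (codon TGG) and the exon-4 splice acceptor immediately 5' of
coding position 275 — so that the G>A change at c.281 creates p.Trp94*, the
G>T change at c.85 creates p.Glu29*, and an A>C at c.275-2 destroys the
canonical acceptor.

The simulated cohort emulates a targeted-panel study of 70 unrelated
probands with a recessive ciliopathy: a background spectrum of mostly-rare
variants drawn from a truncated beta distribution under Hardy-Weinberg
genotype sampling, plus one planted biallelic loss-of-function
configuration in the causal gene per case (homozygous, or compound
heterozygous in trans through the parents).  Controls carry no planted
alleles.  All randomness flows from a single integer seed; identical specs
yield byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ciliaseek.consequence import (
    LOF_CLASSES,
    ConsequenceClass,
    classify_consequence,
)
from ciliaseek.domains import DomainAnnotation, DomainInterval, RSPH1_PROTEIN_LENGTH
from ciliaseek.transcripts import TranscriptModel, write_transcripts_json
from ciliaseek.variants import (
    HET,
    HOM_ALT,
    MISSING,
    FrequencyTable,
    Variant,
    write_bed,
    write_fasta,
    write_gene_list,
    write_ped,
    write_vcf,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
# preferred codon per amino acid for pinned residues; Glu->GAG and Trp->TGG
# make single-base G>A / G>T substitutions create stop codons
_PREFERRED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAG", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "AGT", "T": "ACA", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default MORN-repeat and low-complexity intervals of the RSPH1-like protein.
RSPH1_DOMAIN_INTERVALS: tuple[tuple[int, int, str, str], ...] = (
    (26, 43, "MORN", "Pfam"),
    (44, 66, "MORN", "Pfam"),
    (67, 89, "MORN", "Pfam"),
    (90, 112, "MORN", "Pfam"),
    (113, 133, "MORN", "Pfam"),
    (137, 152, "MORN", "Pfam"),
    (159, 181, "MORN", "Pfam"),
    (238, 251, "low_complexity", "SMART"),
)


class FixtureSpecError(ValueError):
    """Contradictory or impossible fixture pins."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_composition(
    rng: np.random.Generator, total: int, parts: int, minimum: int
) -> list[int]:
    """Random composition of ``total`` into ``parts`` integers >= minimum."""
    if total < parts * minimum:
        raise FixtureSpecError(
            f"cannot split {total} into {parts} parts of at least {minimum}"
        )
    extra = rng.multinomial(total - parts * minimum, [1.0 / parts] * parts)
    return [minimum + int(e) for e in extra]


# ---------------------------------------------------------------------------
# Transcript fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Anatomy pins for the RSPH1-like transcript fixture."""

    exon_count: int = 8
    cdna_length: int = 1400
    genomic_span: int = 24000
    cds_codons: int = 309  # coding residues, excluding the stop codon
    pinned_residues: Mapping[int, str] = field(
        default_factory=lambda: {29: "E", 94: "W"}
    )
    pinned_exon_starts: Mapping[int, int] = field(default_factory=lambda: {4: 275})
    domain_intervals: tuple[tuple[int, int, str, str], ...] = RSPH1_DOMAIN_INTERVALS
    utr5_length: int = 100
    seed: int = 0

    @property
    def cds_length(self) -> int:
        return 3 * (self.cds_codons + 1)

    def validate(self) -> None:
        if self.genomic_span < self.cdna_length:
            raise FixtureSpecError("genomic_span smaller than cdna_length")
        if self.utr5_length + self.cds_length > self.cdna_length:
            raise FixtureSpecError("CDS plus 5' UTR exceeds cdna_length")
        for residue, aa in self.pinned_residues.items():
            if not 2 <= residue <= self.cds_codons:
                raise FixtureSpecError(
                    f"pinned residue {residue}:{aa} outside coding residues "
                    f"2..{self.cds_codons}"
                )
            if aa not in _PREFERRED_CODON:
                raise FixtureSpecError(f"pinned residue {residue}: unknown amino acid {aa!r}")
        for exon, c_pos in self.pinned_exon_starts.items():
            if not 2 <= exon <= self.exon_count:
                raise FixtureSpecError(
                    f"pinned exon start {exon}@{c_pos}: exon outside 2..{self.exon_count}"
                )
            if not 1 <= c_pos <= self.cds_length:
                raise FixtureSpecError(
                    f"pinned exon start {exon}@{c_pos}: coding position beyond CDS "
                    f"of length {self.cds_length}"
                )


@dataclass(frozen=True)
class TranscriptFixture:
    """A generated transcript with its genome segment and domain annotation."""

    transcript: TranscriptModel
    genome: dict[str, str]
    domains: DomainAnnotation
    spec: FixtureSpec | None = None

    @property
    def contig(self) -> str:
        return self.transcript.contig


def _build_transcript(
    rng: np.random.Generator,
    transcript_id: str,
    gene: str,
    contig: str,
    strand: str,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    utr5: int,
    cds_codons: int,
    pinned_residues: Mapping[int, str],
    flank: int = 1000,
) -> tuple[TranscriptModel, str]:
    """Assemble one transcript and its contig sequence.

    Works in transcript space first (cDNA with pinned codons), then lays the
    exons onto a random genomic background with GT..AG introns, reverse
    complementing the whole contig for minus-strand transcripts.
    """
    cdna_len = sum(exon_lengths)
    cds_len = 3 * (cds_codons + 1)
    utr3 = cdna_len - utr5 - cds_len
    assert utr3 >= 0
    codons = ["ATG"]
    for residue in range(2, cds_codons + 1):
        aa = pinned_residues.get(residue)
        if aa is not None:
            codons.append(_PREFERRED_CODON[aa])
        else:
            codons.append(_CODONS[rng.integers(0, len(_CODONS))])
    codons.append("TAA")
    cdna = _random_bases(rng, utr5) + "".join(codons) + _random_bases(rng, utr3)
    assert len(cdna) == cdna_len

    # plus-strand template layout
    genomic_parts = [_random_bases(rng, flank)]
    exon_coords: list[tuple[int, int]] = []
    cursor = flank + 1
    offset = 0
    for i, exon_len in enumerate(exon_lengths):
        exon_seq = cdna[offset : offset + exon_len]
        genomic_parts.append(exon_seq)
        exon_coords.append((cursor, cursor + exon_len - 1))
        cursor += exon_len
        offset += exon_len
        if i < len(intron_lengths):
            ilen = intron_lengths[i]
            intron = "GT" + _random_bases(rng, ilen - 4) + "AG"
            genomic_parts.append(intron)
            cursor += ilen
    genomic_parts.append(_random_bases(rng, flank))
    contig_seq = "".join(genomic_parts)

    if strand == "-":
        length = len(contig_seq)
        contig_seq = _revcomp(contig_seq)
        exon_coords = [
            (length - e + 1, length - s + 1) for s, e in reversed(exon_coords)
        ]

    tx = TranscriptModel(
        transcript_id=transcript_id,
        gene=gene,
        contig=contig,
        strand=strand,
        exons=tuple(exon_coords),
        cds_start=utr5 + 1,
        cds_end=utr5 + cds_len,
        sequence=cdna,
    )
    # cross-check: re-splice from the genome
    spliced = "".join(contig_seq[s - 1 : e] for s, e in tx.exons)
    if strand == "-":
        spliced = _revcomp(spliced)
    assert spliced == cdna, "genome/transcript sequence disagreement"
    return tx, contig_seq


def make_rsph1_fixture(
    spec: FixtureSpec | None = None, strand: str = "+"
) -> TranscriptFixture:
    """Generate the RSPH1-like transcript fixture.

    The returned transcript translates to ``spec.cds_codons`` residues with
    every pinned residue in place, and each pinned exon's acceptor lies
    immediately 5' of its pinned coding position.  Deterministic for a given
    seed; ``strand='-'`` builds the minus-strand twin with identical cDNA
    anatomy.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # exon lengths in transcript order, honouring pinned exon starts:
    # the first (k-1) exons must total utr5 + c_pos - 1
    pins = sorted(spec.pinned_exon_starts.items())
    min_exon = 30
    boundaries: list[tuple[int, int]] = []  # (exon index after segment, cumulative target)
    prev_exons, prev_total = 0, 0
    exon_lengths: list[int] = []
    for exon_ordinal, c_pos in pins:
        target = spec.utr5_length + c_pos - 1
        seg_exons = exon_ordinal - 1 - prev_exons
        seg_total = target - prev_total
        if seg_exons <= 0 or seg_total < seg_exons * min_exon:
            raise FixtureSpecError(
                f"pinned exon start {exon_ordinal}@{c_pos} incompatible with "
                "preceding pins or minimum exon length"
            )
        exon_lengths.extend(_random_composition(rng, seg_total, seg_exons, min_exon))
        prev_exons, prev_total = exon_ordinal - 1, target
    remaining_exons = spec.exon_count - prev_exons
    remaining_total = spec.cdna_length - prev_total
    exon_lengths.extend(
        _random_composition(rng, remaining_total, remaining_exons, min_exon)
    )
    intron_lengths = _random_composition(
        rng, spec.genomic_span - spec.cdna_length, spec.exon_count - 1, 200
    )

    contig = "synth21" if strand == "+" else "synth21_rev"
    tx, contig_seq = _build_transcript(
        rng,
        transcript_id="TX_RSPH1_SYN" + ("_REV" if strand == "-" else ""),
        gene="RSPH1",
        contig=contig,
        strand=strand,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        utr5=spec.utr5_length,
        cds_codons=spec.cds_codons,
        pinned_residues=spec.pinned_residues,
    )
    protein = tx.protein
    for residue, aa in spec.pinned_residues.items():
        if protein[residue - 1] != aa:
            raise FixtureSpecError(
                f"pinned residue {residue}:{aa} not realized (got "
                f"{protein[residue - 1]})"
            )
    domains = DomainAnnotation(
        protein_id="RSPH1",
        protein_length=spec.cds_codons,
        intervals=[DomainInterval(*iv) for iv in spec.domain_intervals],
    )
    return TranscriptFixture(
        transcript=tx, genome={contig: contig_seq}, domains=domains, spec=spec
    )


def make_background_gene(
    gene: str, seed: int, strand: str = "+", n_exons: int = 4, cds_codons: int = 200
) -> TranscriptFixture:
    """A compact generic gene fixture for panel background."""
    rng = np.random.default_rng(seed)
    utr5, utr3 = 40, 80
    cdna_len = utr5 + 3 * (cds_codons + 1) + utr3
    exon_lengths = _random_composition(rng, cdna_len, n_exons, 30)
    intron_lengths = _random_composition(rng, 350 * (n_exons - 1), n_exons - 1, 200)
    tx, contig_seq = _build_transcript(
        rng,
        transcript_id=f"TX_{gene}_SYN",
        gene=gene,
        contig=f"ctg_{gene}",
        strand=strand,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        utr5=utr5,
        cds_codons=cds_codons,
        pinned_residues={},
        flank=300,
    )
    domains = DomainAnnotation(
        protein_id=gene, protein_length=cds_codons, intervals=[]
    )
    return TranscriptFixture(transcript=tx, genome={tx.contig: contig_seq}, domains=domains)


# ---------------------------------------------------------------------------
# Panel


#: Genes with putative motile-cilia function included in the synthetic panel.
CILIA_GENES = (
    "RSPH1",
    "RSPH4A",
    "RSPH9",
    "DNAH1",
    "DNAH3",
    "DNAH12",
    "WDR66",
    "CCDC40",
)


@dataclass
class Panel:
    """The synthetic targeted gene panel: transcripts, genome and regions."""

    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    cilia_genes: list[str]

    @property
    def genes(self) -> list[str]:
        return [t.gene for t in self.transcripts]

    def transcript_for(self, gene: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.gene == gene:
                return t
        raise KeyError(gene)

    def bait_regions(self) -> list[tuple[str, int, int, str]]:
        """One bait region per gene covering the full transcript span."""
        return sorted(
            (t.contig, t.span[0], t.span[1], t.gene) for t in self.transcripts
        )


def make_panel(seed: int = 0, n_background_genes: int = 16) -> Panel:
    """Build the synthetic panel: the RSPH1-like fixture, the other
    motile-cilia genes, and ``n_background_genes`` non-cilia genes."""
    transcripts: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    fixture = make_rsph1_fixture(FixtureSpec(seed=seed))
    transcripts.append(fixture.transcript)
    genome.update(fixture.genome)
    others = [g for g in CILIA_GENES if g != "RSPH1"] + [
        f"GENE{i:02d}" for i in range(1, n_background_genes + 1)
    ]
    for i, gene in enumerate(others):
        strand = "+" if i % 2 == 0 else "-"
        fx = make_background_gene(gene, seed=seed * 1000 + i + 1, strand=strand)
        transcripts.append(fx.transcript)
        genome.update(fx.genome)
    return Panel(
        transcripts=transcripts, genome=genome, cilia_genes=list(CILIA_GENES)
    )


# ---------------------------------------------------------------------------
# Loss-of-function site pool


def lof_site_pool(
    tx: TranscriptModel, genome: Mapping[str, str], max_sites: int = 40
) -> list[tuple[Variant, str]]:
    """Candidate single-base loss-of-function changes in one transcript.

    Returns (variant, c. name) pairs whose consequence class is stop_gained
    or canonical_splice, in deterministic transcript order.
    """
    pool: list[tuple[Variant, str]] = []
    cds = tx.cds_sequence
    # nonsense candidates: single-base changes turning a codon into a stop
    for ordinal in range(2, tx.cds_length // 3):
        codon = cds[(ordinal - 1) * 3 : ordinal * 3]
        for offset in range(3):
            for base in "ACGT":
                if base == codon[offset]:
                    continue
                alt_codon = codon[:offset] + base + codon[offset + 1 :]
                if alt_codon in _STOPS:
                    c_pos = (ordinal - 1) * 3 + offset + 1
                    t_pos = tx.cds_start + c_pos - 1
                    g = tx.transcript_to_genomic(t_pos)
                    ref = genome[tx.contig][g - 1]
                    alt = base if tx.strand == "+" else base.translate(_COMPLEMENT)
                    v = Variant(tx.contig, g, ref, alt)
                    rec = classify_consequence(tx, v, genome)
                    if rec.csq_class is ConsequenceClass.STOP_GAINED:
                        pool.append((v, rec.c_hgvs))
        if len(pool) >= max_sites:
            break
    # canonical splice candidates: +/-1 and +/-2 of each internal boundary
    for t_start, t_end, _gs, _ge in tx._tx_order_exons:
        for anchor_t, offs in ((t_end, (1, 2)), (t_start, (-1, -2))):
            for off in offs:
                anchor_g = tx.transcript_to_genomic(anchor_t)
                g = anchor_g + off if tx.strand == "+" else anchor_g - off
                lo, hi = tx.span
                if not lo <= g <= hi:
                    continue
                ref = genome[tx.contig][g - 1]
                alt = next(b for b in "ACGT" if b != ref)
                v = Variant(tx.contig, g, ref, alt)
                try:
                    rec = classify_consequence(tx, v, genome)
                except Exception:
                    continue
                if rec.csq_class is ConsequenceClass.CANONICAL_SPLICE:
                    pool.append((v, rec.c_hgvs))
    # drop duplicates, keep order
    seen: set[str] = set()
    unique = []
    for v, name in pool:
        if v.key not in seen:
            seen.add(v.key)
            unique.append((v, name))
    return unique[: max_sites + 28]


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of the simulated targeted-panel cohort."""

    n_cases: int = 70
    n_controls: int = 50
    n_background_variants: int = 2000
    maf_beta_a: float = 0.15
    maf_beta_b: float = 1.5
    causal_gene: str = "RSPH1"
    causal_mode: str = "compound_het"  # or "homozygous"
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.causal_mode not in ("homozygous", "compound_het"):
            raise ValueError(f"unknown causal_mode {self.causal_mode!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        if self.n_cases < 1:
            raise ValueError("need at least one case")


@dataclass(frozen=True)
class PlantRecord:
    family: str
    sample: str
    gene: str
    variant_key: str
    c_hgvs: str
    zygosity: str  # "hom" | "het"


@dataclass
class CohortTruth:
    """The simulator's planted causal configuration, for recovery testing."""

    causal_gene: str
    causal_mode: str
    plants: list[PlantRecord]
    true_frequencies: dict[str, float]  # variant key -> population frequency

    def plants_for_sample(self, sample: str) -> list[PlantRecord]:
        return [p for p in self.plants if p.sample == sample]

    def case_is_biallelic(self, sample: str) -> bool:
        plants = self.plants_for_sample(sample)
        n_hom = sum(1 for p in plants if p.zygosity == "hom")
        n_het = sum(1 for p in plants if p.zygosity == "het")
        return n_hom >= 1 or n_het >= 2


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    panel: Panel
    variants: list[Variant]
    genotypes: pd.DataFrame  # int8, index variant key, columns samples
    frequencies: FrequencyTable
    ped: pd.DataFrame
    truth: CohortTruth
    case_samples: list[str]
    control_samples: list[str]

    @property
    def families(self) -> list[str]:
        return sorted(self.ped["family"].unique())


def _maf_spectrum(rng: np.random.Generator, spec: CohortSpec, n: int) -> np.ndarray:
    """Truncated beta allele frequencies on (0, 0.5]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(spec.maf_beta_a, spec.maf_beta_b, size=n)
        ok = draw[(draw > 0) & (draw <= 0.5)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def simulate_cohort(
    spec: CohortSpec | None = None, panel: Panel | None = None
) -> SimulatedCohort:
    """Simulate the cohort: background spectrum plus planted causal genotypes.

    Every case carries a biallelic loss-of-function configuration in the
    causal gene (per ``spec.causal_mode``); parents are obligate carriers
    arranged in trans; controls carry no planted allele.  Background
    genotypes follow Hardy-Weinberg sampling at each variant's true
    frequency, independently per sample.
    """
    spec = spec or CohortSpec()
    spec.validate()
    panel = panel or make_panel(seed=spec.seed)
    if spec.causal_gene not in panel.genes:
        raise ValueError(f"causal gene {spec.causal_gene!r} not in panel")
    rng = np.random.default_rng(spec.seed)
    if spec.n_background_variants < len(panel.genes):
        warnings.warn(
            "fewer background variants than panel genes; some genes will be empty",
            stacklevel=2,
        )

    # ---- sample and pedigree layout
    ped_rows: list[tuple[str, str, str, str, int, int]] = []
    case_samples: list[str] = []
    genotyped: list[str] = []
    consang_extra_affected: dict[str, str] = {}
    for i in range(1, spec.n_cases + 1):
        fam = f"FAM{i:03d}"
        case, father, mother = f"CASE{i:03d}", f"CASE{i:03d}F", f"CASE{i:03d}M"
        if i == 1 and spec.causal_mode == "homozygous":
            # consanguineous topology: parents are first cousins via shared
            # grandparents; two affected sibs and one unaffected carrier sib
            ggf, ggm = f"{fam}_GGF", f"{fam}_GGM"
            gfa, gfb = f"{fam}_GFA", f"{fam}_GFB"
            gma, gmb = f"{fam}_GMA", f"{fam}_GMB"
            sib_aff, sib_un = f"CASE{i:03d}S", f"CASE{i:03d}U"
            ped_rows += [
                (fam, ggf, "0", "0", 1, 1),
                (fam, ggm, "0", "0", 2, 1),
                (fam, gfa, ggf, ggm, 1, 1),
                (fam, gfb, ggf, ggm, 1, 1),
                (fam, gma, "0", "0", 2, 1),
                (fam, gmb, "0", "0", 2, 1),
                (fam, father, gfa, gma, 1, 1),
                (fam, mother, gfb, gmb, 2, 1),
                (fam, case, father, mother, 2, 2),
                (fam, sib_aff, father, mother, 2, 2),
                (fam, sib_un, father, mother, 1, 1),
            ]
            genotyped += [case, sib_aff, sib_un, father, mother]
            consang_extra_affected[case] = sib_aff
        else:
            ped_rows += [
                (fam, father, "0", "0", 1, 1),
                (fam, mother, "0", "0", 2, 1),
                (fam, case, father, mother, 2, 2),
            ]
            genotyped += [case, father, mother]
        case_samples.append(case)
    control_samples = [f"CTRL{i:03d}" for i in range(1, spec.n_controls + 1)]
    for ctrl in control_samples:
        ped_rows.append((f"CTL{ctrl[-3:]}", ctrl, "0", "0", 1, 1))
    samples = genotyped + control_samples
    ped = pd.DataFrame(
        ped_rows, columns=["family", "individual", "father", "mother", "sex", "phenotype"]
    )

    # ---- background variants
    spans = {t.gene: (t.contig, t.span[0], t.span[1]) for t in panel.transcripts}
    genes = panel.genes
    keys_seen: set[str] = set()
    bg_variants: list[Variant] = []
    while len(bg_variants) < spec.n_background_variants:
        gene = genes[int(rng.integers(0, len(genes)))]
        contig, lo, hi = spans[gene]
        pos = int(rng.integers(lo, hi + 1))
        ref = panel.genome[contig][pos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        v = Variant(contig, pos, ref, alt)
        if v.key in keys_seen:
            continue
        keys_seen.add(v.key)
        bg_variants.append(v)

    true_q = _maf_spectrum(rng, spec, len(bg_variants))
    gt = rng.binomial(2, true_q[:, None], size=(len(bg_variants), len(samples))).astype(
        "int8"
    )

    # ---- planted causal variants
    causal_tx = panel.transcript_for(spec.causal_gene)
    pool = [
        (v, name)
        for v, name in lof_site_pool(causal_tx, panel.genome)
        if v.key not in keys_seen
    ]
    if len(pool) < 2:
        raise RuntimeError("loss-of-function site pool unexpectedly small")
    plants: list[PlantRecord] = []
    planted_gt: dict[str, dict[str, int]] = {}
    planted_names: dict[str, str] = {}
    sample_index = {s: j for j, s in enumerate(samples)}
    for i, case in enumerate(case_samples):
        fam = f"FAM{i + 1:03d}"
        father, mother = f"{case}F", f"{case}M"
        if spec.causal_mode == "homozygous":
            v, name = pool[int(rng.integers(0, len(pool)))]
            row = planted_gt.setdefault(v.key, {})
            planted_names[v.key] = name
            row[case] = HOM_ALT
            row[father] = HET
            row[mother] = HET
            plants.append(PlantRecord(fam, case, spec.causal_gene, v.key, name, "hom"))
            sib = consang_extra_affected.get(case)
            if sib:
                row[sib] = HOM_ALT
                row[f"{case}U"] = HET
                plants.append(
                    PlantRecord(fam, sib, spec.causal_gene, v.key, name, "hom")
                )
        else:
            ia, ib = rng.choice(len(pool), size=2, replace=False)
            (va, name_a), (vb, name_b) = pool[int(ia)], pool[int(ib)]
            row_a = planted_gt.setdefault(va.key, {})
            row_b = planted_gt.setdefault(vb.key, {})
            planted_names[va.key] = name_a
            planted_names[vb.key] = name_b
            row_a[case] = HET
            row_a[father] = HET  # father transmits allele A
            row_b[case] = HET
            row_b[mother] = HET  # mother transmits allele B
            plants.append(PlantRecord(fam, case, spec.causal_gene, va.key, name_a, "het"))
            plants.append(PlantRecord(fam, case, spec.causal_gene, vb.key, name_b, "het"))

    planted_variants = sorted(
        {key for key in planted_gt}
    )
    key_to_variant = {v.key: v for v, _ in pool}
    planted_rows = np.zeros((len(planted_variants), len(samples)), dtype="int8")
    for r, key in enumerate(planted_variants):
        for sample_id, code in planted_gt[key].items():
            planted_rows[r, sample_index[sample_id]] = code

    variants = bg_variants + [key_to_variant[k] for k in planted_variants]
    gt = np.vstack([gt, planted_rows])

    # ---- missingness (never applied to planted rows, which model
    # Sanger-confirmed genotypes)
    if spec.missing_rate > 0:
        mask = rng.random((len(bg_variants), len(samples))) < spec.missing_rate
        gt[: len(bg_variants)][mask] = MISSING

    genotypes = pd.DataFrame(
        gt, index=[v.key for v in variants], columns=samples, dtype="int8"
    )

    # ---- population frequency table
    freqs = FrequencyTable()
    resources = ("KG1000", "EVS", "DBSNP")
    planted_true_freq = 5.0 / 13000.0  # rare carrier-derived frequency
    for v, q in zip(bg_variants, true_q):
        if rng.random() < 0.10:
            continue  # novel: absent from every resource
        reported_any = False
        for resource in resources:
            if rng.random() < 0.7:
                noise = 1.0 + rng.normal(0.0, 0.1)
                maf = float(np.clip(q * max(noise, 0.05), 1.0 / 13000.0, 0.5))
                freqs.add(v.key, resource, maf)
                reported_any = True
        if not reported_any:
            freqs.add(v.key, "EVS", float(np.clip(q, 1.0 / 13000.0, 0.5)))
    true_frequencies = {v.key: float(q) for v, q in zip(bg_variants, true_q)}
    for j, key in enumerate(planted_variants):
        true_frequencies[key] = planted_true_freq
        if j % 2 == 1:  # odd-indexed plants are known rare alleles; even are novel
            freqs.add(key, "EVS", planted_true_freq)

    truth = CohortTruth(
        causal_gene=spec.causal_gene,
        causal_mode=spec.causal_mode,
        plants=plants,
        true_frequencies=true_frequencies,
    )
    for case in case_samples:
        assert truth.case_is_biallelic(case), f"plant invariant broken for {case}"

    return SimulatedCohort(
        spec=spec,
        panel=panel,
        variants=variants,
        genotypes=genotypes,
        frequencies=freqs,
        ped=ped,
        truth=truth,
        case_samples=case_samples,
        control_samples=control_samples,
    )


# ---------------------------------------------------------------------------
# File round trip


def write_inputs(sim: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write all pipeline input files for a simulated cohort.

    Produces: cohort.vcf, panel.bed, cohort.ped, frequencies.tsv,
    cilia_genes.txt, transcripts.json and genome.fa.  Deterministic: the
    same cohort yields byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "cohort.vcf",
        "bed": directory / "panel.bed",
        "ped": directory / "cohort.ped",
        "freq": directory / "frequencies.tsv",
        "genes": directory / "cilia_genes.txt",
        "transcripts": directory / "transcripts.json",
        "genome": directory / "genome.fa",
    }
    contigs = {name: len(seq) for name, seq in sim.panel.genome.items()}
    gene_by_contig = {t.contig: t.gene for t in sim.panel.transcripts}
    info = {v.key: f"GENE={gene_by_contig.get(v.chrom, '.')}" for v in sim.variants}
    write_vcf(paths["vcf"], sim.variants, sim.genotypes, contigs, info)
    write_bed(paths["bed"], sim.panel.bait_regions())
    write_ped(paths["ped"], sim.ped)
    sim.frequencies.write(paths["freq"])
    write_gene_list(paths["genes"], sim.panel.cilia_genes)
    write_transcripts_json(paths["transcripts"], sim.panel.transcripts)
    write_fasta(paths["genome"], sim.panel.genome)
    return paths
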