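"""Variant consequence classification against a transcript model.

The classifier maps one normalized variant through a
:class:`~ciliaseek.transcripts.TranscriptModel` to a consequence class and
HGVS c./p. names, the computation that turns a raw VCF record into a call
like ``c.281G>A; p.Trp94*`` (a nonsense change in codon 94) or
``c.275-2A>C`` (a canonical splice-acceptor substitution).

Class vocabulary and filter semantics follow standard panel-analysis usage:
"non-synonymous" means {missense, stop_gained, stop_lost, start_lost};
canonical splice sites are the two intronic bases flanking each exon; the
splice region (intronic offsets 3-8, or the first/last three exonic bases)
is reported but by default does not pass the functional filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from Bio.Seq import Seq

from ciliaseek.hgvs import aa3, format_p_substitution
from ciliaseek.transcripts import (
    CodingCoordinate,
    ReferenceMismatchError,
    TranscriptModel,
    codon_index,
)
from ciliaseek.variants import Variant, normalize


class ConsequenceClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    INTRONIC = "intronic"
    UTR = "utr"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"


#: Classes kept by the default functional ("non-synonymous, splice-site or
#: indel") filter of the recessive cascade.
FUNCTIONAL_CLASSES = frozenset(
    {
        ConsequenceClass.MISSENSE,
        ConsequenceClass.STOP_GAINED,
        ConsequenceClass.STOP_LOST,
        ConsequenceClass.START_LOST,
        ConsequenceClass.CANONICAL_SPLICE,
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.INFRAME_INDEL,
    }
)

#: Loss-of-function subset used when planting causal genotypes.
LOF_CLASSES = frozenset(
    {
        ConsequenceClass.STOP_GAINED,
        ConsequenceClass.CANONICAL_SPLICE,
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.START_LOST,
    }
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsequenceRecord:
    """Consequence of one variant on one transcript."""

    variant: Variant
    transcript_id: str
    gene: str
    csq_class: ConsequenceClass
    c_hgvs: str
    p_hgvs: str | None = None
    codon_ordinal: int | None = None
    codon_offset: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    coding: CodingCoordinate | None = None
    in_splice_region: bool = False

    def __post_init__(self) -> None:
        if self.csq_class is ConsequenceClass.STOP_GAINED and self.alt_aa != "*":
            raise ValueError("stop_gained requires alt_aa '*'")
        if self.csq_class is ConsequenceClass.CANONICAL_SPLICE:
            if self.p_hgvs is not None:
                raise ValueError("canonical_splice has no protein consequence")
            assert self.coding is not None
            if abs(self.coding.intron_offset) not in (1, 2):
                raise ValueError("canonical_splice requires |intron_offset| in {1,2}")


def _tx_alleles(tx: TranscriptModel, ref: str, alt: str) -> tuple[str, str]:
    if tx.strand == "-":
        return _revcomp(ref), _revcomp(alt)
    return ref, alt


def _exonic_splice_region(tx: TranscriptModel, t_pos: int) -> bool:
    """True if the exonic transcript position is within 3 bases of an
    internal exon boundary (the exonic part of the splice region)."""
    for i, (t_start, t_end, _gs, _ge) in enumerate(tx._tx_order_exons):
        if t_start <= t_pos <= t_end:
            near_donor = i < tx.n_exons - 1 and t_end - t_pos < 3
            near_acceptor = i > 0 and t_pos - t_start < 3
            return near_donor or near_acceptor
    return False


def classify_consequence(
    tx: TranscriptModel,
    variant: Variant,
    genome: Mapping[str, str] | None = None,
) -> ConsequenceRecord:
    """Classify a normalized variant against one transcript.

    Exonic reference alleles are checked against the spliced transcript
    sequence; intronic ones against ``genome`` when provided.  Minus-strand
    transcripts have the VCF alleles reverse complemented before codon
    lookup.
    """
    variant = normalize(variant)
    if variant.chrom != tx.contig:
        raise ValueError(
            f"variant {variant.key} on {variant.chrom}, transcript on {tx.contig}"
        )
    if variant.is_snv:
        return _classify_snv(tx, variant, genome)
    return _classify_indel(tx, variant, genome)


def _check_genomic_ref(
    genome: Mapping[str, str] | None, variant: Variant
) -> None:
    if genome is None or variant.chrom not in genome:
        return
    seq = genome[variant.chrom]
    observed = seq[variant.pos - 1 : variant.pos - 1 + len(variant.ref)].upper()
    if observed != variant.ref.upper():
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"variant says {variant.ref}, genome has {observed}"
        )


def _intronic_record(
    tx: TranscriptModel, variant: Variant, coord: CodingCoordinate
) -> ConsequenceRecord:
    tref, talt = _tx_alleles(tx, variant.ref, variant.alt)
    off = abs(coord.intron_offset)
    if off <= 2:
        csq = ConsequenceClass.CANONICAL_SPLICE
    elif off <= 8:
        csq = ConsequenceClass.SPLICE_REGION
    else:
        csq = ConsequenceClass.INTRONIC
    return ConsequenceRecord(
        variant=variant,
        transcript_id=tx.transcript_id,
        gene=tx.gene,
        csq_class=csq,
        c_hgvs=f"c.{coord}{tref}>{talt}",
        coding=coord,
        in_splice_region=csq is ConsequenceClass.SPLICE_REGION,
    )


def _classify_snv(
    tx: TranscriptModel, variant: Variant, genome: Mapping[str, str] | None
) -> ConsequenceRecord:
    coord = tx.genomic_to_coding(variant.pos)
    tref, talt = _tx_alleles(tx, variant.ref, variant.alt)
    if not coord.is_exonic:
        _check_genomic_ref(genome, variant)
        return _intronic_record(tx, variant, coord)

    t_pos = tx.coding_to_transcript(coord)
    observed = tx.base_at_transcript(t_pos).upper()
    if observed != tref.upper():
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.pos} "
            f"({tx.transcript_id} c.{coord}): variant says {tref}, "
            f"transcript has {observed}"
        )
    splice_flag = _exonic_splice_region(tx, t_pos)
    if coord.region != "cds":
        return ConsequenceRecord(
            variant=variant,
            transcript_id=tx.transcript_id,
            gene=tx.gene,
            csq_class=ConsequenceClass.UTR,
            c_hgvs=f"c.{coord}{tref}>{talt}",
            coding=coord,
            in_splice_region=splice_flag,
        )

    ordinal, offset = codon_index(coord.position, tx.cds_length)
    cds = tx.cds_sequence
    codon = cds[(ordinal - 1) * 3 : ordinal * 3]
    alt_codon = codon[: offset - 1] + talt + codon[offset:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ordinal == 1 and alt_aa != "M":
        csq = ConsequenceClass.START_LOST
    elif ref_aa == "*":
        csq = (
            ConsequenceClass.SYNONYMOUS if alt_aa == "*" else ConsequenceClass.STOP_LOST
        )
    elif alt_aa == "*":
        csq = ConsequenceClass.STOP_GAINED
    elif ref_aa == alt_aa:
        csq = ConsequenceClass.SYNONYMOUS
    else:
        csq = ConsequenceClass.MISSENSE
    return ConsequenceRecord(
        variant=variant,
        transcript_id=tx.transcript_id,
        gene=tx.gene,
        csq_class=csq,
        c_hgvs=f"c.{coord}{tref}>{talt}",
        p_hgvs=format_p_substitution(ref_aa, ordinal, alt_aa),
        codon_ordinal=ordinal,
        codon_offset=offset,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        coding=coord,
        in_splice_region=splice_flag,
    )


def _shift3_deletion(seq: str, start0: int, length: int) -> int:
    """3'-shift a deletion of ``length`` bases starting at 0-based ``start0``
    within ``seq``; returns the shifted 0-based start."""
    while start0 + length < len(seq) and seq[start0] == seq[start0 + length]:
        start0 += 1
    return start0


def _classify_indel(
    tx: TranscriptModel, variant: Variant, genome: Mapping[str, str] | None
) -> ConsequenceRecord:
    """Classify a simple VCF-anchored insertion or deletion.

    Supported: pure insertions (ref is one anchor base, alt extends it) and
    pure deletions (alt is one anchor base) lying fully inside one exon or
    fully intronic.  Indels straddling an exon/intron boundary are classed
    by their most severe touched feature (canonical splice wins).
    """
    _check_genomic_ref(genome, variant)
    ref, alt = variant.ref, variant.alt
    if not (ref[0] == alt[0] and (len(ref) == 1 or len(alt) == 1)):
        raise ValueError(f"unsupported complex allele change {variant.key}")
    is_del = len(ref) > 1
    # genomic footprint of the changed bases (excludes the shared anchor)
    if is_del:
        g_lo, g_hi = variant.pos + 1, variant.pos + len(ref) - 1
    else:
        g_lo, g_hi = variant.pos, variant.pos  # insertion after the anchor
    coords = [tx.genomic_to_coding(g) for g in range(g_lo, g_hi + 1)]
    exonic = [c for c in coords if c.is_exonic]
    intron_offsets = [abs(c.intron_offset) for c in coords if not c.is_exonic]
    touches_canonical = any(off <= 2 for off in intron_offsets)
    coding_change = any(c.region == "cds" for c in exonic)
    delta = len(alt) - len(ref)

    c_name = _indel_c_hgvs(tx, variant, is_del)
    anchor = min(coords, key=lambda c: (not c.is_exonic, abs(c.intron_offset)))

    if touches_canonical and not exonic:
        csq = ConsequenceClass.CANONICAL_SPLICE
        anchor = min(
            (c for c in coords if not c.is_exonic), key=lambda c: abs(c.intron_offset)
        )
    elif coding_change:
        csq = (
            ConsequenceClass.FRAMESHIFT if delta % 3 else ConsequenceClass.INFRAME_INDEL
        )
    elif exonic:
        csq = ConsequenceClass.UTR
    elif intron_offsets and min(intron_offsets) <= 8:
        csq = ConsequenceClass.SPLICE_REGION
    else:
        csq = ConsequenceClass.INTRONIC

    p_name = None
    if csq in (ConsequenceClass.FRAMESHIFT, ConsequenceClass.INFRAME_INDEL):
        first_cds = min(
            (c for c in exonic if c.region == "cds"), key=lambda c: c.position
        )
        ordinal, _ = codon_index(first_cds.position, tx.cds_length)
        ref_aa = str(
            Seq(tx.cds_sequence[(ordinal - 1) * 3 : ordinal * 3]).translate()
        )
        suffix = "fs" if csq is ConsequenceClass.FRAMESHIFT else "del" if is_del else "ins"
        p_name = f"p.{aa3(ref_aa)}{ordinal}{suffix}"
    return ConsequenceRecord(
        variant=variant,
        transcript_id=tx.transcript_id,
        gene=tx.gene,
        csq_class=csq,
        c_hgvs=c_name,
        p_hgvs=p_name,
        coding=anchor,
    )


def _indel_c_hgvs(tx: TranscriptModel, variant: Variant, is_del: bool) -> str:
    """Name a simple indel in c. notation, 3'-shifted within the transcript
    when it lies fully inside one exon; otherwise named at its genomic
    anchor without shifting."""
    ref, alt = variant.ref, variant.alt
    changed = ref[1:] if is_del else alt[1:]
    t_changed = _revcomp(changed) if tx.strand == "-" else changed

    if is_del:
        g_positions = list(range(variant.pos + 1, variant.pos + len(ref)))
        t_positions = []
        for g in g_positions:
            t = None
            try:
                t = tx.genomic_to_transcript(g)
            except Exception:
                t = None
            if t is None:
                t_positions = None
                break
            t_positions.append(t)
        if t_positions:
            t_lo = min(t_positions)
            length = len(t_changed)
            start0 = _shift3_deletion(tx.sequence, t_lo - 1, length)
            seq = tx.sequence[start0 : start0 + length]
            c_lo = tx.transcript_to_coding(start0 + 1)
            c_hi = tx.transcript_to_coding(start0 + length)
            if length == 1:
                return f"c.{c_lo}del{seq}"
            return f"c.{c_lo}_{c_hi}del{seq}"
        # boundary-straddling: name at genomic anchor without shifting
        c_lo = tx.genomic_to_coding(g_positions[0])
        c_hi = tx.genomic_to_coding(g_positions[-1])
        if tx.strand == "-":
            c_lo, c_hi = c_hi, c_lo
        if len(t_changed) == 1:
            return f"c.{c_lo}del{t_changed}"
        return f"c.{c_lo}_{c_hi}del{t_changed}"

    # insertion after the anchor base
    try:
        t_anchor = tx.genomic_to_transcript(variant.pos)
    except Exception:
        t_anchor = None
    if t_anchor is not None:
        ins = t_changed
        if tx.strand == "-":
            # insertion falls 5' of the anchor in transcript orientation
            t_anchor -= 1
        pos0 = t_anchor  # insert between t_anchor and t_anchor+1
        # 3'-shift: rotate while the next base equals the first inserted base
        while pos0 < len(tx.sequence) and tx.sequence[pos0] == ins[0]:
            ins = ins[1:] + ins[0]
            pos0 += 1
        # duplication detection
        k = len(ins)
        if pos0 >= k and tx.sequence[pos0 - k : pos0] == ins:
            c_lo = tx.transcript_to_coding(pos0 - k + 1)
            c_hi = tx.transcript_to_coding(pos0)
            if k == 1:
                return f"c.{c_lo}dup{ins}"
            return f"c.{c_lo}_{c_hi}dup{ins}"
        if pos0 < 1 or pos0 >= len(tx.sequence):
            raise ValueError(f"insertion at transcript edge unsupported: {variant.key}")
        c_lo = tx.transcript_to_coding(pos0)
        c_hi = tx.transcript_to_coding(pos0 + 1)
        return f"c.{c_lo}_{c_hi}ins{ins}"
    # intronic insertion: name between flanking intronic coordinates
    c_lo = tx.genomic_to_coding(variant.pos)
    c_hi = tx.genomic_to_coding(variant.pos + 1)
    if tx.strand == "-":
        c_lo, c_hi = c_hi, c_lo
        t_changed = t_changed
    return f"c.{c_lo}_{c_hi}ins{t_changed}"


def annotate_variants(
    transcripts: Sequence[TranscriptModel],
    variants: Sequence[Variant],
    genome: Mapping[str, str] | None = None,
) -> dict[str, list[ConsequenceRecord]]:
    """Annotate each variant against every transcript whose span contains it.

    A variant belongs to every gene whose transcript it hits; variants
    outside all transcripts get an empty record list.
    """
    by_contig: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_contig.setdefault(tx.contig, []).append(tx)
    out: dict[str, list[ConsequenceRecord]] = {}
    for v in variants:
        records = []
        for tx in by_contig.get(v.chrom, []):
            lo, hi = tx.span
            if lo <= v.pos <= hi:
                records.append(classify_consequence(tx, v, genome))
        out[v.key] = records
    return out
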