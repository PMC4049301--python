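"""Strand-aware transcript models and coordinate arithmetic.

A :class:`TranscriptModel` holds the exon structure of one transcript on a
genomic contig together with its spliced cDNA sequence and the CDS span in
transcript coordinates.  It converts between three coordinate systems:

* genomic (1-based position on the contig),
* transcript (1-based position in the spliced cDNA, 5'->3'),
* coding / HGVS c. (1-based from the A of the initiator ATG, with signed
  intronic offsets such as ``c.275-2`` for the second acceptor base).

All conversions are strand-aware: on a minus-strand transcript the spliced
sequence is the reverse complement of the concatenated genomic exons.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq


class OutOfTranscriptError(ValueError):
    """Genomic position falls outside the transcript span."""


class ReferenceMismatchError(ValueError):
    """Supplied reference allele disagrees with the transcript/genome sequence."""


@dataclass(frozen=True)
class CodingCoordinate:
    """One position in HGVS coding-DNA coordinates.

    ``position`` is the coding nucleotide index of the anchor base: positive
    within the CDS, negative in the 5' UTR (``c.-k``) and positive with
    ``region='utr3'`` in the 3' UTR (``c.*k``).  ``intron_offset`` is 0 for
    exonic bases; for intronic bases it is the signed distance from the
    nearest exon boundary (positive past a donor, ``c.X+k``; negative before
    an acceptor, ``c.Y-k``).
    """

    position: int
    intron_offset: int = 0
    region: str = "cds"  # "cds" | "utr5" | "utr3"

    def __post_init__(self) -> None:
        if self.region not in ("cds", "utr5", "utr3"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.region == "cds" and self.position < 1:
            raise ValueError("CDS coding position must be >= 1")
        if self.region == "utr5" and self.position >= 0:
            raise ValueError("5' UTR coding position must be negative")
        if self.region == "utr3" and self.position < 1:
            raise ValueError("3' UTR coding position must be >= 1")

    @property
    def is_exonic(self) -> bool:
        return self.intron_offset == 0

    def __str__(self) -> str:
        base = f"*{self.position}" if self.region == "utr3" else str(self.position)
        if self.intron_offset:
            return f"{base}{self.intron_offset:+d}"
        return base


def codon_index(c_pos: int, cds_length: int | None = None) -> tuple[int, int]:
    """Return ``(codon_ordinal, codon_offset)`` for a coding position.

    The ordinal is 1-based (codon 1 is the initiator ATG) and the offset is
    the 1-3 position within the codon, so c.281 -> (94, 2).
    """
    if c_pos < 1:
        raise ValueError(f"coding position must be >= 1, got {c_pos}")
    if cds_length is not None and c_pos > cds_length:
        raise ValueError(f"coding position {c_pos} beyond CDS length {cds_length}")
    return (c_pos - 1) // 3 + 1, (c_pos - 1) % 3 + 1


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript plus its spliced sequence.

    Parameters
    ----------
    exons:
        Genomic exon intervals, 1-based inclusive, sorted by genomic start,
        non-overlapping.  For minus-strand transcripts the *first* exon in
        transcript order is the genomically last interval.
    cds_start, cds_end:
        CDS span in transcript (spliced cDNA) coordinates, 1-based inclusive.
        The CDS includes the stop codon.
    sequence:
        Spliced cDNA in transcript orientation (reverse complement of the
        genome for minus-strand transcripts).
    """

    transcript_id: str
    gene: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("transcript needs at least one exon")
        prev_end = 0
        for s, e in exons:
            if s > e:
                raise ValueError(f"exon interval {s}-{e} reversed")
            if s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        total = sum(e - s + 1 for s, e in exons)
        if total != len(self.sequence):
            raise ValueError(
                f"spliced sequence length {len(self.sequence)} != exon total {total}"
            )
        if not (1 <= self.cds_start <= self.cds_end <= total):
            raise ValueError("CDS span outside transcript")
        if self.cds_length % 3:
            raise ValueError("CDS length must be a multiple of 3")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_end]

    @property
    def protein(self) -> str:
        """Translation of the CDS including the terminal stop as '*'."""
        return str(Seq(self.cds_sequence).translate())

    @property
    def _tx_order_exons(self) -> tuple[tuple[int, int, int, int], ...]:
        """Exons in transcript order as (t_start, t_end, g_start, g_end)."""
        order = self.exons if self.strand == "+" else self.exons[::-1]
        out = []
        t = 1
        for g_start, g_end in order:
            ln = g_end - g_start + 1
            out.append((t, t + ln - 1, g_start, g_end))
            t += ln
        return tuple(out)

    # -- conversions -------------------------------------------------------

    def genomic_to_transcript(self, g_pos: int) -> int | None:
        """Transcript position of an exonic genomic base, or None if intronic."""
        lo, hi = self.span
        if not lo <= g_pos <= hi:
            raise OutOfTranscriptError(
                f"{self.contig}:{g_pos} outside transcript span {lo}-{hi}"
            )
        for t_start, _t_end, g_start, g_end in self._tx_order_exons:
            if g_start <= g_pos <= g_end:
                if self.strand == "+":
                    return t_start + (g_pos - g_start)
                return t_start + (g_end - g_pos)
        return None

    def transcript_to_genomic(self, t_pos: int) -> int:
        if not 1 <= t_pos <= self.length:
            raise OutOfTranscriptError(f"transcript position {t_pos} out of range")
        for t_start, t_end, g_start, g_end in self._tx_order_exons:
            if t_start <= t_pos <= t_end:
                if self.strand == "+":
                    return g_start + (t_pos - t_start)
                return g_end - (t_pos - t_start)
        raise AssertionError("unreachable")

    def transcript_to_coding(self, t_pos: int) -> CodingCoordinate:
        if t_pos < self.cds_start:
            return CodingCoordinate(t_pos - self.cds_start, region="utr5")
        if t_pos > self.cds_end:
            return CodingCoordinate(t_pos - self.cds_end, region="utr3")
        return CodingCoordinate(t_pos - self.cds_start + 1)

    def coding_to_transcript(self, coord: CodingCoordinate) -> int:
        """Transcript position of the (exonic) anchor base of *coord*."""
        if coord.region == "utr5":
            t = self.cds_start + coord.position
        elif coord.region == "utr3":
            t = self.cds_end + coord.position
        else:
            t = self.cds_start + coord.position - 1
        if not 1 <= t <= self.length:
            raise OutOfTranscriptError(f"coordinate {coord} outside transcript")
        return t

    def genomic_to_coding(self, g_pos: int) -> CodingCoordinate:
        """Map a genomic position to HGVS coding coordinates.

        Exonic positions get ``intron_offset`` 0.  Intronic positions are
        anchored to the nearest exon boundary; when a position is equidistant
        from both flanking exons the tie is broken toward the 5' (donor-side)
        exon, giving a ``+k`` offset.
        """
        t = self.genomic_to_transcript(g_pos)
        if t is not None:
            return self.transcript_to_coding(t)
        # intronic: locate flanking exons in genomic order
        starts = [s for s, _ in self.exons]
        i = bisect.bisect_right(starts, g_pos) - 1
        left_end = self.exons[i][1]
        right_start = self.exons[i + 1][0]
        d_left = g_pos - left_end
        d_right = right_start - g_pos
        if self.strand == "+":
            donor_dist, donor_anchor_g = d_left, left_end
            acceptor_dist, acceptor_anchor_g = d_right, right_start
        else:
            donor_dist, donor_anchor_g = d_right, right_start
            acceptor_dist, acceptor_anchor_g = d_left, left_end
        if donor_dist <= acceptor_dist:
            offset, anchor_g = donor_dist, donor_anchor_g
        else:
            offset, anchor_g = -acceptor_dist, acceptor_anchor_g
        anchor_t = self.genomic_to_transcript(anchor_g)
        assert anchor_t is not None
        anchor = self.transcript_to_coding(anchor_t)
        return CodingCoordinate(anchor.position, offset, region=anchor.region)

    def coding_to_genomic(self, coord: CodingCoordinate) -> int:
        anchor_g = self.transcript_to_genomic(self.coding_to_transcript(coord))
        if coord.intron_offset == 0:
            return anchor_g
        if self.strand == "+":
            return anchor_g + coord.intron_offset
        return anchor_g - coord.intron_offset

    def base_at_transcript(self, t_pos: int) -> str:
        return self.sequence[t_pos - 1]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "gene": self.gene,
            "contig": self.contig,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
            "sequence": self.sequence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(
            transcript_id=d["transcript_id"],
            gene=d["gene"],
            contig=d["contig"],
            strand=d["strand"],
            exons=tuple(tuple(e) for e in d["exons"]),
            cds_start=int(d["cds_start"]),
            cds_end=int(d["cds_end"]),
            sequence=d["sequence"],
        )


def write_transcripts_json(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    payload = {"transcripts": [t.to_dict() for t in transcripts]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_transcripts_json(path: str | Path) -> list[TranscriptModel]:
    payload = json.loads(Path(path).read_text())
    return [TranscriptModel.from_dict(d) for d in payload["transcripts"]]
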