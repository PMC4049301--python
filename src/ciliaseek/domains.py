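"""Protein-domain interval mapping and truncation-extent arithmetic.

RSPH1, the radial-spoke-head protein mutated in the central-pair-deficient
subtype of primary ciliary dyskinesia, is a 309-residue protein carrying
seven MORN (membrane occupation and recognition nexus) repeats under the
Pfam consensus plus a short low-complexity region.  This module maps
candidate-variant protein positions onto such annotated intervals and
computes how much of the protein a premature stop removes.

Splice-site variants have no protein position of their own; they are mapped
via the codon of the first coding base of the downstream exon and flagged
as inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

#: Consensus MORN repeat length in residues.
MORN_CONSENSUS_LENGTH = 23

RSPH1_PROTEIN_LENGTH = 309


class DomainValidationError(ValueError):
    """Domain interval inconsistent with the protein it annotates."""


@dataclass(frozen=True)
class DomainInterval:
    start: int
    end: int
    label: str
    source: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass(frozen=True)
class DomainHit:
    interval: DomainInterval
    ordinal: int  # 1-based index among same-label intervals
    inferred: bool = False


@dataclass
class DomainAnnotation:
    """Labelled residue intervals on one protein."""

    protein_id: str
    protein_length: int
    intervals: list[DomainInterval]

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if not 1 <= iv.start <= iv.end <= self.protein_length:
                raise DomainValidationError(
                    f"{self.protein_id}: interval {iv.label} {iv.start}-{iv.end} "
                    f"outside protein of length {self.protein_length}"
                )
        by_source: dict[str, list[DomainInterval]] = {}
        for iv in self.intervals:
            by_source.setdefault(iv.source, []).append(iv)
        for source, ivs in by_source.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise DomainValidationError(
                        f"{self.protein_id}: overlapping {source} intervals "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    def by_label(self, label: str) -> list[DomainInterval]:
        return sorted(
            (iv for iv in self.intervals if iv.label == label), key=lambda i: i.start
        )

    def length_deviations(
        self, label: str = "MORN", consensus: int = MORN_CONSENSUS_LENGTH
    ) -> list[int]:
        """Signed deviation of each repeat's length from the consensus."""
        return [iv.length - consensus for iv in self.by_label(label)]


def load_domains(path: str | Path, protein_length: int, protein_id: str | None = None) -> DomainAnnotation:
    """Load a domain annotation TSV (protein_id, start, end, label, source)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return DomainAnnotation(
            protein_id=protein_id or "unknown",
            protein_length=protein_length,
            intervals=[],
        )
    if protein_id is None:
        protein_id = str(df["protein_id"].iloc[0])
    sub = df[df["protein_id"] == protein_id]
    intervals = [
        DomainInterval(int(r.start), int(r.end), str(r.label), str(r.source))
        for r in sub.itertuples(index=False)
    ]
    return DomainAnnotation(
        protein_id=protein_id, protein_length=protein_length, intervals=intervals
    )


def rsph1_domains() -> DomainAnnotation:
    """Bundled RSPH1 annotation: seven Pfam MORN repeats at residues 26-43,
    44-66, 67-89, 90-112, 113-133, 137-152 and 159-181, plus a
    low-complexity region at 238-251."""
    with resources.as_file(
        resources.files("ciliaseek.data").joinpath("rsph1_domains.tsv")
    ) as path:
        return load_domains(path, RSPH1_PROTEIN_LENGTH, "RSPH1")


def locate_residue(
    annotation: DomainAnnotation, residue: int, inferred: bool = False
) -> list[DomainHit]:
    """All annotated intervals containing ``residue``, each with the ordinal
    index of the interval among same-label intervals (MORN repeat number)."""
    if not 1 <= residue <= annotation.protein_length:
        raise ValueError(
            f"residue {residue} outside protein of length {annotation.protein_length}"
        )
    hits = []
    for iv in annotation.intervals:
        if iv.contains(residue):
            ordinal = annotation.by_label(iv.label).index(iv) + 1
            hits.append(DomainHit(interval=iv, ordinal=ordinal, inferred=inferred))
    return hits


@dataclass(frozen=True)
class TruncationSummary:
    stop_ordinal: int
    protein_length: int
    fraction_retained: float
    domains_lost: tuple[DomainInterval, ...]


def truncation_extent(
    annotation: DomainAnnotation, stop_ordinal: int
) -> TruncationSummary:
    """Extent of a premature-stop truncation.

    The stop codon replaces residue ``stop_ordinal``; residues 1 to
    ``stop_ordinal - 1`` are retained.  A domain is lost or truncated when
    its end lies at or beyond the stop ordinal.
    """
    length = annotation.protein_length
    if not 1 <= stop_ordinal <= length:
        raise ValueError(f"stop ordinal {stop_ordinal} outside 1..{length}")
    retained = (stop_ordinal - 1) / length
    lost = tuple(
        iv
        for iv in sorted(annotation.intervals, key=lambda i: (i.start, i.end))
        if iv.end >= stop_ordinal
    )
    return TruncationSummary(
        stop_ordinal=stop_ordinal,
        protein_length=length,
        fraction_retained=retained,
        domains_lost=lost,
    )
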