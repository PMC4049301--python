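"""Parsing and formatting of a pragmatic HGVS subset.

Supported coding-DNA (c.) constructs:

* substitutions: ``c.281G>A``, ``c.275-2A>C``, ``c.-5A>G``, ``c.*12T>C``
* deletions of an explicit sequence: ``c.10delA``, ``c.10_12delACG``
* insertions of an explicit sequence: ``c.10_11insACGT``
* duplications of an explicit sequence: ``c.10dupA``, ``c.10_12dupACG``

Protein (p.) names use 3-letter amino-acid codes with ``*`` for a gained
stop (``p.Trp94*``).  Anything outside this grammar raises
:class:`UnsupportedHgvsError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.SeqUtils import seq3

from ciliaseek.transcripts import CodingCoordinate


class UnsupportedHgvsError(ValueError):
    """HGVS string is outside the supported grammar subset."""


_COORD_RE = re.compile(r"^(?P<utr3>\*)?(?P<pos>-?\d+)(?P<off>[+-]\d+)?$")
_SUB_RE = re.compile(r"^(?P<coord>[\d*+-]+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_INDEL_RE = re.compile(
    r"^(?P<start>[\d*+-]+)(?:_(?P<end>[\d*+-]+))?(?P<op>del|ins|dup)(?P<seq>[ACGT]+)$"
)


def parse_coordinate(text: str) -> CodingCoordinate:
    m = _COORD_RE.match(text)
    if not m:
        raise UnsupportedHgvsError(f"cannot parse coordinate {text!r}")
    pos = int(m.group("pos"))
    off = int(m.group("off")) if m.group("off") else 0
    if m.group("utr3"):
        if pos < 1:
            raise UnsupportedHgvsError(f"bad 3' UTR coordinate {text!r}")
        return CodingCoordinate(pos, off, region="utr3")
    if pos < 0:
        return CodingCoordinate(pos, off, region="utr5")
    if pos == 0:
        raise UnsupportedHgvsError("c.0 does not exist")
    return CodingCoordinate(pos, off, region="cds")


def format_coordinate(coord: CodingCoordinate) -> str:
    return str(coord)


@dataclass(frozen=True)
class HgvsC:
    """A parsed c. description.

    ``kind`` is one of ``sub``, ``del``, ``ins``, ``dup``.  For ``sub`` the
    ``ref``/``alt`` single bases are set; for the others ``seq`` holds the
    explicit deleted/inserted/duplicated sequence and ``end`` the optional
    second coordinate.
    """

    kind: str
    start: CodingCoordinate
    end: CodingCoordinate | None = None
    ref: str | None = None
    alt: str | None = None
    seq: str | None = None


def parse_hgvs_c(text: str) -> HgvsC:
    if not text.startswith("c."):
        raise UnsupportedHgvsError(f"expected 'c.' prefix in {text!r}")
    body = text[2:]
    m = _SUB_RE.match(body)
    if m:
        return HgvsC(
            kind="sub",
            start=parse_coordinate(m.group("coord")),
            ref=m.group("ref"),
            alt=m.group("alt"),
        )
    m = _INDEL_RE.match(body)
    if m:
        start = parse_coordinate(m.group("start"))
        end = parse_coordinate(m.group("end")) if m.group("end") else None
        op, seq = m.group("op"), m.group("seq")
        if op == "ins" and end is None:
            raise UnsupportedHgvsError(f"insertion needs a flanking pair: {text!r}")
        n_span = None
        if end is not None and start.region == end.region == "cds":
            n_span = end.position - start.position + 1
        if op in ("del", "dup"):
            if end is None and len(seq) != 1:
                raise UnsupportedHgvsError(
                    f"multi-base {op} needs a range: {text!r}"
                )
            if n_span is not None and n_span != len(seq):
                raise UnsupportedHgvsError(
                    f"range and sequence length disagree in {text!r}"
                )
        return HgvsC(kind=op, start=start, end=end, seq=seq)
    raise UnsupportedHgvsError(f"unsupported HGVS construct {text!r}")


def format_hgvs_c(desc: HgvsC) -> str:
    s = format_coordinate(desc.start)
    if desc.kind == "sub":
        return f"c.{s}{desc.ref}>{desc.alt}"
    if desc.kind in ("del", "dup"):
        if desc.end is not None:
            return f"c.{s}_{format_coordinate(desc.end)}{desc.kind}{desc.seq}"
        return f"c.{s}{desc.kind}{desc.seq}"
    if desc.kind == "ins":
        assert desc.end is not None
        return f"c.{s}_{format_coordinate(desc.end)}ins{desc.seq}"
    raise UnsupportedHgvsError(f"unknown kind {desc.kind!r}")


def aa3(aa: str) -> str:
    """3-letter code for one amino acid, with '*' mapped to 'Ter'."""
    if aa == "*":
        return "Ter"
    return seq3(aa)


def format_p_substitution(ref_aa: str, ordinal: int, alt_aa: str) -> str:
    """Protein-level name for a single-codon substitution.

    Gained stops are written with ``*`` (e.g. ``p.Trp94*``), synonymous
    changes with ``=``, everything else with 3-letter codes.
    """
    if alt_aa == "*":
        return f"p.{aa3(ref_aa)}{ordinal}*"
    if ref_aa == alt_aa:
        return f"p.{aa3(ref_aa)}{ordinal}="
    if ordinal == 1:
        return "p.Met1?"
    return f"p.{aa3(ref_aa)}{ordinal}{aa3(alt_aa)}"
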