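"""Variants, genotype matrices and the plain-file interfaces.

Genotypes are stored as a compact per-variant x per-sample integer matrix
(pandas DataFrame of int8): 0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate, -1 = missing.  Half-calls are treated as missing.

File formats handled here: multi-sample VCF v4.2 (GT only; written as
deterministic plain text, read through pysam), BED (0-based half-open),
6-column PED, a long-format population allele-frequency TSV and plain-text
gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass(frozen=True, order=True)
class Variant:
    """One normalized biallelic allele change (1-based VCF-style position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    def __str__(self) -> str:
        return self.key


def normalize(variant: Variant) -> Variant:
    """Trim shared suffix then prefix bases (left-parsimonious form)."""
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(variant.chrom, pos, ref, alt)


def gt_code(alleles: Sequence[int | None]) -> int:
    """Diploid genotype tuple -> matrix code; any missing allele -> MISSING."""
    if len(alleles) != 2 or any(a is None for a in alleles):
        return MISSING
    n_alt = sum(1 for a in alleles if a != 0)
    return (HOM_REF, HET, HOM_ALT)[n_alt]


def gt_string(code: int) -> str:
    return {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}[code]


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    path: str | Path,
    variants: Sequence[Variant],
    genotypes: pd.DataFrame,
    contigs: Mapping[str, int],
    info: Mapping[str, str] | None = None,
) -> None:
    """Write a deterministic multi-sample VCF v4.2.

    ``genotypes`` is indexed by variant key with one column per sample.
    ``info`` optionally maps variant key -> pre-formatted INFO string.
    """
    samples = list(genotypes.columns)
    lines = ["##fileformat=VCFv4.2"]
    for name in sorted(contigs):
        lines.append(f"##contig=<ID={name},length={contigs[name]}>")
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for v in sorted(variants):
        row = genotypes.loc[v.key]
        info_field = info.get(v.key, ".") if info else "."
        gts = "\t".join(gt_string(int(row[s])) for s in samples)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info_field}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[list[Variant], pd.DataFrame]:
    """Read a multi-sample VCF into (variants, genotype matrix).

    Multi-allelic records are split per alternate allele; genotypes are
    recoded against each split allele.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    variants: list[Variant] = []
    rows: list[list[int]] = []
    for rec in vf:
        alts = rec.alts or ()
        for alt_idx, alt in enumerate(alts, start=1):
            v = normalize(Variant(rec.chrom, rec.pos, rec.ref, alt))
            codes = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    codes.append(MISSING)
                    continue
                n = sum(1 for a in gt if a == alt_idx)
                codes.append((HOM_REF, HET, HOM_ALT)[n])
            variants.append(v)
            rows.append(codes)
    vf.close()
    gt = pd.DataFrame(rows, index=[v.key for v in variants], columns=samples, dtype="int8")
    return variants, gt


# ---------------------------------------------------------------------------
# BED


def write_bed(path: str | Path, regions: Iterable[tuple[str, int, int, str]]) -> None:
    """Write 1-based inclusive (chrom, start, end, name) regions as BED."""
    lines = [f"{c}\t{s - 1}\t{e}\t{name}" for c, s, e, name in regions]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED into 1-based inclusive (chrom, start, end, name) tuples."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        name = parts[3] if len(parts) > 3 else "."
        regions.append((parts[0], int(parts[1]) + 1, int(parts[2]), name))
    return regions


# ---------------------------------------------------------------------------
# PED

PED_COLUMNS = ["family", "individual", "father", "mother", "sex", "phenotype"]


def write_ped(path: str | Path, table: pd.DataFrame) -> None:
    table[PED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_ped(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=PED_COLUMNS, dtype=str)
    df["sex"] = df["sex"].astype(int)
    df["phenotype"] = df["phenotype"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Population frequency table


class FrequencyTable:
    """Per-resource population minor-allele frequencies keyed by variant.

    A variant absent from every resource is *novel*.  Frequencies above 0.5
    are folded to the minor allele on entry.
    """

    def __init__(self, records: Mapping[str, Mapping[str, float]] | None = None):
        self._records: dict[str, dict[str, float]] = {
            k: dict(v) for k, v in (records or {}).items()
        }

    def __len__(self) -> int:
        return len(self._records)

    def add(self, key: str, resource: str, maf: float) -> None:
        maf = float(maf)
        if not 0.0 <= maf <= 1.0:
            raise ValueError(f"MAF {maf} for {key} outside [0, 1]")
        if maf > 0.5:
            maf = 1.0 - maf
        self._records.setdefault(key, {})[resource] = maf

    def resources_for(self, key: str) -> dict[str, float]:
        return dict(self._records.get(key, {}))

    def is_novel(self, key: str) -> bool:
        return key not in self._records

    def max_maf(self, key: str) -> float | None:
        rec = self._records.get(key)
        return max(rec.values()) if rec else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self._records):
            chrom, pos, ref, alt = key.split(":")
            for resource in sorted(self._records[key]):
                rows.append(
                    (chrom, int(pos), ref, alt, resource, self._records[key][resource])
                )
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "resource", "maf"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        table = cls()
        for row in df.itertuples(index=False):
            try:
                key = f"{row.chrom}:{int(row.pos)}:{row.ref}:{row.alt}"
                table.add(key, str(row.resource), float(row.maf))
            except (ValueError, TypeError) as exc:  # malformed row: treat as absent
                logger.warning("skipping malformed frequency row %r: %s", row, exc)
        return table


# ---------------------------------------------------------------------------
# Gene lists


def write_gene_list(path: str | Path, genes: Iterable[str]) -> None:
    Path(path).write_text("\n".join(sorted(set(genes))) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


# ---------------------------------------------------------------------------
# FASTA (genome segments)


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                sequences[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences
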