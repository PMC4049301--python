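"""The rare-recessive filtering cascade with stepwise count reporting.

Per sample, the cascade runs in a fixed order: bait-region restriction
(regions +/- a 100 bp window) -> population-frequency filter (novel or
MAF < 0.01 in every reporting resource) -> zygosity partition into
heterozygous and homozygous-alternate branches -> functional-class filter
(non-synonymous, canonical splice, indel) -> gene-level recessive candidate
model (>= 1 homozygous or >= 2 heterozygous changes in one gene of one
sample) -> intersection with a motile-cilia candidate gene list.

Every step records its per-sample count, producing a report in the shape of
a targeted-panel filtering summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ciliaseek.consequence import FUNCTIONAL_CLASSES, ConsequenceClass, ConsequenceRecord
from ciliaseek.variants import HET, HOM_ALT, MISSING, FrequencyTable, Variant

logger = logging.getLogger(__name__)

STEP_ORDER = [
    "total",
    "maf_filtered",
    "het",
    "het_functional",
    "genes_compound_het",
    "genes_compound_het_cilia",
    "hom",
    "hom_functional",
    "genes_hom_cilia",
]

#: (parent step, child step) pairs along which counts must not increase.
_MONOTONE_EDGES = [
    ("total", "maf_filtered"),
    ("maf_filtered", "het"),
    ("het", "het_functional"),
    ("genes_compound_het", "genes_compound_het_cilia"),
    ("maf_filtered", "hom"),
    ("hom", "hom_functional"),
    ("hom_functional", "genes_hom_cilia"),
]


class CascadeError(RuntimeError):
    """A cascade stage failed; the stage name is included in the message."""


class ConfigurationError(ValueError):
    """Invalid cascade configuration (e.g. an empty candidate gene list)."""


@dataclass
class CascadeReport:
    """Ordered per-sample step counts plus surviving items per step."""

    sample: str
    counts: dict[str, int]
    survivors: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        """Check the internal identities of the report.

        Raises ``ValueError`` if the heterozygous and homozygous branch
        counts do not sum to the frequency-filtered total, or if any count
        increases along its branch.
        """
        missing = [s for s in STEP_ORDER if s not in self.counts]
        if missing:
            raise ValueError(f"report for {self.sample} missing steps {missing}")
        c = self.counts
        if c["het"] + c["hom"] != c["maf_filtered"]:
            raise ValueError(
                f"zygosity partition broken for {self.sample}: "
                f"{c['het']} + {c['hom']} != {c['maf_filtered']}"
            )
        for parent, child in _MONOTONE_EDGES:
            if c[child] > c[parent]:
                raise ValueError(
                    f"count increased {parent} -> {child} for {self.sample}: "
                    f"{c[parent]} -> {c[child]}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(step, self.sample, self.counts[step]) for step in STEP_ORDER],
            columns=["step", "sample", "count"],
        )


def reports_to_frame(reports: Sequence[CascadeReport]) -> pd.DataFrame:
    frames = [r.to_frame() for r in reports]
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot(index="step", columns="sample", values="count")
    return wide.reindex(STEP_ORDER)


# ---------------------------------------------------------------------------
# Individual filter stages


def restrict_to_regions(
    variants: Sequence[Variant],
    regions: Sequence[tuple[str, int, int, str]],
    window: int = 100,
) -> list[Variant]:
    """Keep variants within any region (1-based inclusive) expanded by
    ``window`` bases on both sides.

    Variants on contigs absent from the region set are dropped with a logged
    notice.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _name in regions:
        # IntervalTree is half-open on integers; store [start-window, end+window]
        trees.setdefault(chrom, IntervalTree()).addi(
            max(1, start - window), end + window + 1
        )
    kept = []
    missing_contigs = set()
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            missing_contigs.add(v.chrom)
            continue
        if tree.overlaps_point(v.pos):
            kept.append(v)
    for chrom in sorted(missing_contigs):
        logger.info("dropping variants on contig %s absent from region set", chrom)
    return kept


def frequency_filter(
    variants: Sequence[Variant],
    freqs: FrequencyTable,
    threshold: float = 0.01,
) -> list[Variant]:
    """Keep variants that are novel or whose maximum MAF across reporting
    resources is strictly below ``threshold``."""
    if not 0 < threshold <= 0.5:
        raise ConfigurationError(f"MAF threshold {threshold} outside (0, 0.5]")
    kept = []
    for v in variants:
        max_maf = freqs.max_maf(v.key)
        if max_maf is None or max_maf < threshold:
            kept.append(v)
    return kept


def zygosity_partition(
    variants: Sequence[Variant], genotypes: Mapping[str, int]
) -> tuple[list[Variant], list[Variant]]:
    """Split carried variants of one sample into (het, hom-alt) lists.

    Homozygous-reference and missing genotypes fall in neither list;
    half-calls arrive here already coded as missing.
    """
    het, hom = [], []
    n_missing = 0
    for v in variants:
        code = genotypes.get(v.key, MISSING)
        if code == HET:
            het.append(v)
        elif code == HOM_ALT:
            hom.append(v)
        elif code == MISSING:
            n_missing += 1
    if n_missing:
        logger.debug("%d variants with missing genotype treated as non-carried", n_missing)
    return het, hom


def functional_class_filter(
    variants: Sequence[Variant],
    annotations: Mapping[str, Sequence[ConsequenceRecord]],
    include_splice_region: bool = False,
) -> list[Variant]:
    """Keep variants with at least one functional transcript consequence.

    Functional classes are the non-synonymous substitutions, canonical
    splice changes and indels; ``include_splice_region`` additionally
    admits the extended splice region.
    """
    keep_classes = set(FUNCTIONAL_CLASSES)
    if include_splice_region:
        keep_classes.add(ConsequenceClass.SPLICE_REGION)
    kept = []
    for v in variants:
        if v.key not in annotations:
            raise CascadeError(
                f"functional filter: variant {v.key} has no annotation "
                "(cascade ordering violation)"
            )
        if any(rec.csq_class in keep_classes for rec in annotations[v.key]):
            kept.append(v)
    return kept


def genes_of(
    variant: Variant, annotations: Mapping[str, Sequence[ConsequenceRecord]]
) -> set[str]:
    return {rec.gene for rec in annotations.get(variant.key, ())}


def recessive_gene_candidates(
    het_variants: Sequence[Variant],
    hom_variants: Sequence[Variant],
    annotations: Mapping[str, Sequence[ConsequenceRecord]],
) -> tuple[dict[str, list[Variant]], dict[str, list[Variant]]]:
    """Gene-level recessive model for one sample.

    Returns ``(compound_het_genes, hom_genes)``: genes with >= 2 distinct
    heterozygous variants (putative compound heterozygotes, phase unknown at
    this stage) and genes with >= 1 homozygous-alternate variant, each with
    their supporting variants.  A variant counts toward every gene whose
    transcript annotation it hits.
    """
    het_by_gene: dict[str, list[Variant]] = {}
    for v in het_variants:
        for gene in genes_of(v, annotations):
            het_by_gene.setdefault(gene, []).append(v)
    hom_by_gene: dict[str, list[Variant]] = {}
    for v in hom_variants:
        for gene in genes_of(v, annotations):
            hom_by_gene.setdefault(gene, []).append(v)
    compound = {g: vs for g, vs in het_by_gene.items() if len(set(vs)) >= 2}
    return compound, hom_by_gene


def candidate_list_intersection(
    genes: Iterable[str], panel_list: Sequence[str]
) -> dict[str, str]:
    """Case-insensitive intersection of candidate genes with the panel list.

    Returns surviving genes mapped to the panel symbol they matched.
    Raises :class:`ConfigurationError` on an empty panel list.
    """
    if not panel_list:
        raise ConfigurationError("candidate gene panel list is empty")
    lookup = {symbol.upper(): symbol for symbol in panel_list}
    return {
        g: lookup[g.upper()]
        for g in genes
        if g.upper() in lookup
    }


# ---------------------------------------------------------------------------
# Full per-sample cascade


def run_cascade(
    sample: str,
    variants: Sequence[Variant],
    genotypes: Mapping[str, int],
    annotations: Mapping[str, Sequence[ConsequenceRecord]],
    freqs: FrequencyTable,
    regions: Sequence[tuple[str, int, int, str]],
    cilia_genes: Sequence[str],
    maf_threshold: float = 0.01,
    window: int = 100,
    include_splice_region: bool = False,
) -> CascadeReport:
    """Run the full filtering cascade for one sample and report step counts.

    ``genotypes`` maps variant key -> genotype code for this sample; the
    'total' step counts the variants the sample carries (het or hom-alt)
    inside the expanded bait regions.
    """
    try:
        in_region = restrict_to_regions(variants, regions, window)
    except Exception as exc:  # pragma: no cover - defensive
        raise CascadeError(f"region restriction failed: {exc}") from exc
    carried = [
        v for v in in_region if genotypes.get(v.key, MISSING) in (HET, HOM_ALT)
    ]
    rare = frequency_filter(carried, freqs, maf_threshold)
    het, hom = zygosity_partition(rare, genotypes)
    het_fn = functional_class_filter(het, annotations, include_splice_region)
    hom_fn = functional_class_filter(hom, annotations, include_splice_region)
    compound, hom_by_gene = recessive_gene_candidates(het_fn, hom_fn, annotations)
    compound_cilia = candidate_list_intersection(compound, cilia_genes)
    hom_cilia = candidate_list_intersection(hom_by_gene, cilia_genes)

    counts = {
        "total": len(carried),
        "maf_filtered": len(rare),
        "het": len(het),
        "het_functional": len(het_fn),
        "genes_compound_het": len(compound),
        "genes_compound_het_cilia": len(compound_cilia),
        "hom": len(hom),
        "hom_functional": len(hom_fn),
        "genes_hom_cilia": len(hom_cilia),
    }
    survivors = {
        "het_functional": sorted(v.key for v in het_fn),
        "hom_functional": sorted(v.key for v in hom_fn),
        "genes_compound_het": sorted(compound),
        "genes_compound_het_cilia": sorted(compound_cilia),
        "genes_hom_cilia": sorted(hom_cilia),
    }
    report = CascadeReport(sample=sample, counts=counts, survivors=survivors)
    report.validate()
    logger.info(
        "cascade %s: %s", sample, " ".join(f"{s}={counts[s]}" for s in STEP_ORDER)
    )
    return report


def final_candidate_genes(report: CascadeReport) -> set[str]:
    """Candidate genes surviving the whole cascade (both branches)."""
    return set(report.survivors.get("genes_compound_het_cilia", [])) | set(
        report.survivors.get("genes_hom_cilia", [])
    )
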