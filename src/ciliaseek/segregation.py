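"""Pedigree handling, Mendelian checks and recessive co-segregation.

Under a fully penetrant autosomal-recessive model a candidate gene is
*supported* by a family when every genotyped affected member is biallelic
(homozygous for a candidate variant, or carrying two heterozygous variants
established in trans from parental genotypes) and no genotyped unaffected
member is definitely biallelic.  A gene is *excluded* when an unaffected
member is biallelic or an affected member is not; anything else is
*uninformative*.  Affected double heterozygotes whose phase cannot be
established still support the gene but are flagged as phase-unverified,
mirroring the candidate status such genes have before confirmatory
sequencing of the parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ciliaseek.variants import HET, HOM_ALT, HOM_REF, MISSING, PED_COLUMNS

AFFECTED, UNAFFECTED = 2, 1


class PedigreeError(ValueError):
    """Malformed pedigree (unresolved parent or ancestry cycle)."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    father: str | None
    mother: str | None
    sex: int
    affected: bool


@dataclass
class Pedigree:
    family_id: str
    members: dict[str, Individual]

    def __post_init__(self) -> None:
        for ind in self.members.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.members:
                    raise PedigreeError(
                        f"{self.family_id}: parent {parent} of "
                        f"{ind.individual_id} not in pedigree"
                    )
        # reject ancestry cycles
        for start in self.members:
            seen = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                ind = self.members[cur]
                for parent in (ind.father, ind.mother):
                    if parent is None:
                        continue
                    if parent == start:
                        raise PedigreeError(
                            f"{self.family_id}: {start} is its own ancestor"
                        )
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)

    @property
    def affected_ids(self) -> list[str]:
        return sorted(i for i, m in self.members.items() if m.affected)

    @property
    def unaffected_ids(self) -> list[str]:
        return sorted(i for i, m in self.members.items() if not m.affected)

    @classmethod
    def from_frame(cls, family_id: str, df: pd.DataFrame) -> "Pedigree":
        members = {}
        ids = set(df["individual"])
        for row in df.itertuples(index=False):
            father = row.father if row.father not in ("0", 0, None) else None
            mother = row.mother if row.mother not in ("0", 0, None) else None
            if father is not None and father not in ids:
                raise PedigreeError(f"{family_id}: father {father} not listed")
            if mother is not None and mother not in ids:
                raise PedigreeError(f"{family_id}: mother {mother} not listed")
            members[row.individual] = Individual(
                individual_id=row.individual,
                father=father,
                mother=mother,
                sex=int(row.sex),
                affected=int(row.phenotype) == AFFECTED,
            )
        return cls(family_id=family_id, members=members)


def pedigrees_from_ped(df: pd.DataFrame) -> dict[str, Pedigree]:
    return {
        fam: Pedigree.from_frame(fam, sub)
        for fam, sub in df.groupby("family", sort=True)
    }


# ---------------------------------------------------------------------------
# Mendelian trio check


def mendelian_check(
    child: int, father: int | None, mother: int | None
) -> tuple[bool, str | None]:
    """Check that a biallelic child genotype is attainable from the parents.

    Genotype codes follow the package convention (0/1/2, missing None or
    -1).  A missing parental genotype makes the trio consistent by default.
    Returns ``(consistent, violation_detail)``.
    """

    def alleles(code: int | None) -> set[tuple[int, int]] | None:
        if code is None or code == MISSING:
            return None
        if code == HOM_REF:
            return {(0, 0)}
        if code == HET:
            return {(0, 1)}
        if code == HOM_ALT:
            return {(1, 1)}
        raise ValueError(f"malformed genotype code {code!r}")

    child_set = alleles(child)
    if child_set is None:
        return True, None
    (c1, c2) = next(iter(child_set))
    f_set = alleles(father)
    m_set = alleles(mother)
    f_alleles = {a for pair in (f_set or {(0, 0), (0, 1), (1, 1)}) for a in pair}
    m_alleles = {a for pair in (m_set or {(0, 0), (0, 1), (1, 1)}) for a in pair}
    for from_f, from_m in ((c1, c2), (c2, c1)):
        if from_f in f_alleles and from_m in m_alleles:
            return True, None
    detail = (
        f"child genotype {child} not attainable from parents "
        f"(father={father}, mother={mother})"
    )
    if child == HET and father == HOM_REF and mother == HOM_REF:
        detail += " [possible de novo]"
    return False, detail


# ---------------------------------------------------------------------------
# Phase from parents


def trans_phase_from_parents(
    father_carries_a: bool,
    father_carries_b: bool,
    mother_carries_a: bool,
    mother_carries_b: bool,
) -> str:
    """Phase two proband heterozygous variants from parental carriage.

    Returns ``trans`` when each parent carries exactly one of the two
    variants (and different ones), ``cis`` when one parent carries both and
    the other neither, ``unknown`` otherwise.
    """
    f = (father_carries_a, father_carries_b)
    m = (mother_carries_a, mother_carries_b)
    if sum(f) == 1 and sum(m) == 1 and f != m:
        return "trans"
    if (all(f) and not any(m)) or (all(m) and not any(f)):
        return "cis"
    return "unknown"


# ---------------------------------------------------------------------------
# Co-segregation under the recessive model


@dataclass
class SegregationVerdict:
    """Family-level verdict for one candidate gene."""

    family: str
    gene: str
    model: str
    status: str  # supports | excludes | uninformative
    phase_verified: bool = True
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == "excludes" and not self.reasons:
            raise ValueError("an excluding verdict needs at least one reason")


def _biallelic_state(
    individual: Individual,
    genotypes: Mapping[str, Mapping[str, int]],
    variant_keys: Sequence[str],
    pedigree: Pedigree,
) -> tuple[str, str | None]:
    """Classify one member's gene genotype configuration.

    Returns one of ``("biallelic", detail)``, ``("biallelic_unphased", detail)``,
    ``("carrier_or_clear", None)``, ``("ungenotyped", None)``.
    """
    gts = genotypes.get(individual.individual_id)
    if gts is None:
        return "ungenotyped", None
    carried = {
        k: gts.get(k, MISSING) for k in variant_keys if gts.get(k, MISSING) in (HET, HOM_ALT)
    }
    if not carried and all(gts.get(k, MISSING) == MISSING for k in variant_keys):
        return "ungenotyped", None
    homs = [k for k, c in carried.items() if c == HOM_ALT]
    hets = [k for k, c in carried.items() if c == HET]
    if homs:
        return "biallelic", f"homozygous for {homs[0]}"
    if len(hets) >= 2:
        phase = _phase_pair(individual, hets, genotypes, pedigree)
        if phase == "trans":
            return "biallelic", f"heterozygous in trans for {hets[0]} and {hets[1]}"
        if phase == "cis":
            return "carrier_or_clear", None
        return "biallelic_unphased", f"double heterozygous (phase unknown): {hets[:2]}"
    return "carrier_or_clear", None


def _phase_pair(
    individual: Individual,
    het_keys: Sequence[str],
    genotypes: Mapping[str, Mapping[str, int]],
    pedigree: Pedigree,
) -> str:
    """Phase the first two heterozygous variants from parental genotypes."""
    if individual.father is None or individual.mother is None:
        return "unknown"
    f_gts = genotypes.get(individual.father)
    m_gts = genotypes.get(individual.mother)
    if f_gts is None or m_gts is None:
        return "unknown"
    a, b = het_keys[0], het_keys[1]

    def carries(gts: Mapping[str, int], key: str) -> bool | None:
        code = gts.get(key, MISSING)
        if code == MISSING:
            return None
        return code in (HET, HOM_ALT)

    fa, fb = carries(f_gts, a), carries(f_gts, b)
    ma, mb = carries(m_gts, a), carries(m_gts, b)
    if None in (fa, fb, ma, mb):
        return "unknown"
    return trans_phase_from_parents(fa, fb, ma, mb)


def cosegregation_test(
    pedigree: Pedigree,
    genotypes: Mapping[str, Mapping[str, int]],
    gene: str,
    variant_keys: Sequence[str],
    model: str = "autosomal_recessive",
) -> SegregationVerdict:
    """Test co-segregation of candidate variants in one gene with disease.

    ``genotypes`` maps individual id -> {variant key -> genotype code} for
    the candidate variants of ``gene``.  Requires at least one genotyped
    affected member to be informative.
    """
    if model != "autosomal_recessive":
        raise ValueError(f"unsupported inheritance model {model!r}")
    if not variant_keys:
        return SegregationVerdict(
            family=pedigree.family_id,
            gene=gene,
            model=model,
            status="uninformative",
            reasons=[f"no candidate variants for gene {gene}"],
        )
    reasons: list[str] = []
    phase_verified = True
    n_affected_genotyped = 0
    # deterministic order regardless of input file ordering
    for ind_id in sorted(pedigree.members):
        individual = pedigree.members[ind_id]
        state, detail = _biallelic_state(individual, genotypes, variant_keys, pedigree)
        if state == "ungenotyped":
            continue
        if individual.affected:
            n_affected_genotyped += 1
            if state == "biallelic_unphased":
                phase_verified = False
            elif state != "biallelic":
                reasons.append(
                    f"affected {ind_id} is not biallelic for {gene} candidates"
                )
        else:
            if state == "biallelic":
                reasons.append(f"unaffected {ind_id} is biallelic: {detail}")
            elif state == "biallelic_unphased":
                # not a definite violation; noted but not excluding
                phase_verified = phase_verified and True

    if n_affected_genotyped == 0:
        return SegregationVerdict(
            family=pedigree.family_id,
            gene=gene,
            model=model,
            status="uninformative",
            reasons=["no genotyped affected individuals"],
        )
    if reasons:
        return SegregationVerdict(
            family=pedigree.family_id,
            gene=gene,
            model=model,
            status="excludes",
            reasons=reasons,
        )
    return SegregationVerdict(
        family=pedigree.family_id,
        gene=gene,
        model=model,
        status="supports",
        phase_verified=phase_verified,
    )


def verdicts_to_frame(verdicts: Sequence[SegregationVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                v.family,
                v.gene,
                v.status,
                "yes" if v.phase_verified else "no",
                "; ".join(v.reasons),
            )
            for v in verdicts
        ],
        columns=["family", "gene", "status", "phase_verified", "reasons"],
    )
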