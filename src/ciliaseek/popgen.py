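"""Hardy-Weinberg carrier-frequency consistency checks.

For a fully penetrant autosomal-recessive disease with birth prevalence P,
the pathogenic allele frequency attributable to one locus is
q = sqrt(P * locus_share) and the expected heterozygous carrier frequency
is 2q(1-q).  Observing a handful of heterozygous carriers of a candidate
allele in a control exome database (e.g. 9 carriers among 6500 unaffected
individuals) is therefore compatible with pathogenicity whenever the
observed carrier rate does not significantly exceed that expectation; only
a gross excess of carriers argues the allele is too common to cause the
disease.  The test is an exact two-sided binomial test of the observed
carrier count against the expected carrier frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binomtest


@dataclass(frozen=True)
class PrevalenceModel:
    """Disease birth prevalence range and the share attributable to one locus.

    ``prevalence_low``/``prevalence_high`` bracket the birth incidence
    (e.g. 1/30000 to 1/15000 for primary ciliary dyskinesia).
    ``locus_share`` is the fraction of disease attributable to the specific
    gene or allele; it defaults to 0.04 as an order-of-magnitude placeholder
    for one gene among many and should be set explicitly when known.
    """

    prevalence_low: float
    prevalence_high: float
    locus_share: float = 0.04

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_low <= self.prevalence_high < 1:
            raise ValueError(
                f"prevalence range [{self.prevalence_low}, {self.prevalence_high}] invalid"
            )
        if not 0 < self.locus_share <= 1:
            raise ValueError(f"locus_share {self.locus_share} outside (0, 1]")


@dataclass(frozen=True)
class CarrierObservation:
    """Carrier counts of one allele in a control cohort."""

    het_carriers: int
    individuals: int
    hom_carriers: int = 0

    def __post_init__(self) -> None:
        if self.individuals <= 0:
            raise ValueError("need a positive number of sampled individuals")
        if self.het_carriers < 0 or self.hom_carriers < 0:
            raise ValueError("carrier counts must be non-negative")
        if self.het_carriers + self.hom_carriers > self.individuals:
            raise ValueError("carriers exceed sampled individuals")


def allele_freq_from_carriers(obs: CarrierObservation) -> float:
    """Allele frequency estimate q = (het + 2*hom) / (2*individuals)."""
    return (obs.het_carriers + 2 * obs.hom_carriers) / (2 * obs.individuals)


def expected_carrier_freq(model: PrevalenceModel) -> tuple[float, float]:
    """Expected heterozygous carrier-frequency range under Hardy-Weinberg.

    For each prevalence bound P: q = sqrt(P * locus_share) and carrier
    frequency 2q(1-q).  Returns (low, high).
    """

    def carrier(p: float) -> float:
        q = math.sqrt(p * model.locus_share)
        return 2.0 * q * (1.0 - q)

    return carrier(model.prevalence_low), carrier(model.prevalence_high)


@dataclass(frozen=True)
class CarrierVerdict:
    verdict: str  # "consistent" | "inconsistent"
    p_value: float
    observed_rate: float
    expected_low: float
    expected_high: float
    hom_in_controls: bool
    alpha: float
    locus_share: float

    @property
    def consistent(self) -> bool:
        return self.verdict == "consistent"


def carrier_consistency_test(
    obs: CarrierObservation, model: PrevalenceModel, alpha: float = 0.05
) -> CarrierVerdict:
    """Test whether observed control carriers fit a pathogenic allele.

    The observed heterozygous carrier count is compared against
    Binomial(individuals, expected carrier frequency) at the upper
    prevalence bound.  The allele is *consistent* when the observed rate is
    at or below that expectation, or when the two-sided exact binomial
    p-value exceeds ``alpha``; only the upper tail (too many carriers)
    drives an inconsistent verdict.  Homozygous carriers in a control set
    are flagged separately, since unaffected homozygotes contradict a fully
    penetrant recessive allele directly.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    low, high = expected_carrier_freq(model)
    observed_rate = obs.het_carriers / obs.individuals
    test = binomtest(obs.het_carriers, obs.individuals, high, alternative="two-sided")
    if observed_rate <= high or test.pvalue > alpha:
        verdict = "consistent"
    else:
        verdict = "inconsistent"
    return CarrierVerdict(
        verdict=verdict,
        p_value=float(test.pvalue),
        observed_rate=observed_rate,
        expected_low=low,
        expected_high=high,
        hom_in_controls=obs.hom_carriers > 0,
        alpha=alpha,
        locus_share=model.locus_share,
    )
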