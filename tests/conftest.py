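import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from ciliaseek.consequence import annotate_variants
from ciliaseek.synthetic import (
    CohortSpec,
    FixtureSpec,
    make_rsph1_fixture,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def fixture_plus():
    """Default RSPH1-like fixture on the plus strand."""
    return make_rsph1_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def fixture_minus():
    """Minus-strand twin of the default fixture."""
    return make_rsph1_fixture(FixtureSpec(), strand="-")


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort for fast unit tests."""
    sim = simulate_cohort(
        CohortSpec(n_cases=4, n_controls=10, n_background_variants=400, seed=7)
    )
    annotations = annotate_variants(sim.panel.transcripts, sim.variants, sim.panel.genome)
    return sim, annotations


@pytest.fixture(scope="session")
def cohort_batch():
    """Twenty full-size simulated cohorts (seeds 0-19), pre-annotated."""
    batch = []
    for seed in range(20):
        sim = simulate_cohort(CohortSpec(seed=seed))
        annotations = annotate_variants(
            sim.panel.transcripts, sim.variants, sim.panel.genome
        )
        batch.append((sim, annotations))
    return batch
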