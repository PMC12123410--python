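import pytest

from tfact.activity_scores import vst
from tfact.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, seed 7, shared read-only across tests."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def nat_vst(cohort):
    return vst(cohort.expression.counts_nat)


@pytest.fixture(scope="session")
def tumor_vst(cohort):
    return vst(cohort.expression.counts_tumor)


@pytest.fixture(scope="session")
def regulons(cohort, nat_vst):
    """Inferred regulons on the default cohort (1000 bootstraps, seed 7)."""
    from tfact.regulon_inference import infer_regulons

    return infer_regulons(nat_vst, sorted(cohort.truth.targets), seed=7)
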