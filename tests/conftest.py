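import numpy as np
import pytest

from drpeptidome import CohortConfig, SampleInfo, generate_cohort
from drpeptidome.models import Group


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort with the default 14-sample typing structure."""
    cfg = CohortConfig(
        peptides_per_sample=60,
        n_lysate_proteins=200,
        n_induced=12,
        n_induced_peptides=30,
        n_self_proteins=120,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_sample_cohort():
    """Minimal heterozygous pair cohort with a planted dominance of 4."""
    samples = [
        SampleInfo("S1", Group.CONTROL, "DRB1*03:01", "DRB1*13:01"),
        SampleInfo("S2", Group.PULSED, "DRB1*01:01", "DRB1*07:01"),
    ]
    cfg = CohortConfig(
        samples=samples,
        peptides_per_sample=120,
        dual_overlap=0.3,
        dominance=4.0,
        n_lysate_proteins=80,
        n_induced=6,
        n_induced_peptides=10,
        n_self_proteins=60,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
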