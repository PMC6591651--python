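import numpy as np
import pytest

from biallelic import SimScenario, simulate_cohort, simulate_pileup


@pytest.fixture
def het_scenario() -> SimScenario:
    """Balanced biallelic expression at three divergent sites, fixed depth."""
    return SimScenario(
        gene="PAR2GENE",
        transcript_length=40,
        divergent_sites=(5, 17, 30),
        y_fraction=0.5,
        error_rate=0.01,
        depth=80,
        n_samples=6,
        seed=11,
    )


@pytest.fixture
def silenced_scenario() -> SimScenario:
    """Monoallelic (second allele silenced) expression, noise-free."""
    return SimScenario(
        gene="PAR2GENE",
        transcript_length=40,
        divergent_sites=(5, 17, 30),
        y_fraction=0.0,
        error_rate=0.0,
        depth=60,
        n_samples=4,
        seed=3,
    )


@pytest.fixture
def small_cohort():
    """Two monoallelic male cohorts plus one female control sample."""
    case = SimScenario(
        gene="PAR2GENE",
        transcript_length=40,
        divergent_sites=(5, 17, 30),
        y_fraction=0.0,
        error_rate=0.005,
        depth=80,
        n_samples=5,
        cohort="case",
        seed=21,
    )
    control = SimScenario(
        gene="PAR2GENE",
        transcript_length=40,
        divergent_sites=(5, 17, 30),
        y_fraction=0.0,
        error_rate=0.005,
        depth=80,
        n_samples=6,
        sexes=("male",) * 5 + ("female",),
        cohort="control",
        seed=22,
    )
    return simulate_cohort(case, control)
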