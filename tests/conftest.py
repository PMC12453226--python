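import numpy as np
import pytest

from digestmark import CohortConfig, MarkerKind, SpectraConfig, simulate_cohort
from digestmark.synthetic import simulate_spectra


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic trial: 12 animals x 3 phases x 5 days."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def unit_recovery_cohort():
    """Cohort with every marker fully recovered (faecal mass = intake mass)."""
    cfg = CohortConfig(seed=7)
    cfg.recovery_mean = {m: 1.0 for m in MarkerKind}
    cfg.recovery_sd = {m: 0.0 for m in MarkerKind}
    cfg.recovery_truncation = (0.5, 1.5)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_spectra(default_cohort):
    cfg = SpectraConfig(seed=3)
    return simulate_spectra(default_cohort, cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
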