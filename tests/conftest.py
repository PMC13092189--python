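import warnings

import pytest

import physpref as pp

# statsmodels emits benign overflow warnings when exponentiating huge robust
# CIs on near-separated fits; keep test output readable.
warnings.filterwarnings("ignore", category=RuntimeWarning, message="overflow")


@pytest.fixture(scope="session")
def codebook():
    return pp.default_codebook()


@pytest.fixture(scope="session")
def exact_cohort():
    """Deterministic cohort carrying the published per-scenario counts."""
    return pp.cohort_from_scenario_counts()


@pytest.fixture(scope="session")
def small_cohort():
    """One default synthetic cohort (n=324, seeded, with missingness)."""
    return pp.generate(pp.default_config(seed=123))


@pytest.fixture(scope="session")
def cohort_50k():
    """Large null cohort for law-of-large-numbers checks (no masking)."""
    cfg = pp.default_config(seed=5)
    cfg.n = 50_000
    cfg.missingness_rates = {}
    return pp.generate(cfg)
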