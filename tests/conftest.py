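"""Shared fixtures: a calibrated standard library and a default cohort.

Both are session-scoped; they are deterministic, so sharing them across
tests changes nothing but runtime.
"""

import pytest

from pde8a_editing import quant, synth


@pytest.fixture(scope="session")
def tspec() -> synth.TraceSpec:
    return synth.TraceSpec()


@pytest.fixture(scope="session")
def library(tspec) -> quant.StandardLibrary:
    """Standard library calibrated from noise-free simulated standards."""
    return quant.calibrate_standards(synth.simulate_standards(tspec), tspec.ladder_times)


@pytest.fixture(scope="session")
def cohort():
    """Default paired cohort: 8 control / 8 suicide subjects, two regions."""
    return synth.simulate_cohort(synth.CohortSpec(seed=42))
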