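import pytest

from cryptkinetics import (
    baseline_config,
    calibrate_targets,
    fast_config,
    fit_scenario,
)
from cryptkinetics import presets


@pytest.fixture(scope="session")
def targets():
    """Calibrated murine-ileum steady-state targets (N = 4000 cells/CVU)."""
    return calibrate_targets()


@pytest.fixture(scope="session")
def baseline_fit(targets):
    """Converged default-mode baseline fit (shared across tests)."""
    return fit_scenario(baseline_config(), targets)


@pytest.fixture(scope="session")
def reproduction_fit(targets):
    """Baseline fit with k2 pinned at its published value (unique solution)."""
    return fit_scenario(baseline_config(reproduction=True), targets)


@pytest.fixture(scope="session")
def fast_fit(targets):
    """Converged fast-scenario fit (5-day enterocyte renewal constraint)."""
    return fit_scenario(fast_config(), targets)


@pytest.fixture(scope="session")
def published_params():
    return presets.BASELINE_PARAMS


@pytest.fixture(scope="session")
def init():
    return presets.DEFAULT_INIT
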