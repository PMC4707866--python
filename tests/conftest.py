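"""Shared fixtures.

The expensive simulations (1-D reference run, dose sweep, 2-D pressure
sweep) are session-scoped so the module tests and the acceptance suite
measure the same runs.
"""

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from clotlysis import KineticParameters, MicrostructureParams
from clotlysis.coupled2d import CoupledScenario, compare_pressure_drops
from clotlysis.transport1d import Scenario1D, dose_sweep_1d, simulate_1d


@pytest.fixture(scope="session")
def ref_kp():
    return KineticParameters()


@pytest.fixture(scope="session")
def ref_mp():
    return MicrostructureParams()


@pytest.fixture(scope="session")
def reference_1d():
    """50 nM reference 1-D lysis run (4.5 mm clot, 95 min)."""
    sc = Scenario1D.reference()
    return sc, simulate_1d(sc)


@pytest.fixture(scope="session")
def dose_sweep_1d_results():
    """Front velocities for 1, 10, 100 and 1000 nM inlet tPA."""
    sc = Scenario1D.dose_sweep()
    return dose_sweep_1d([0.001, 0.01, 0.1, 1.0], sc)


@pytest.fixture(scope="session")
def pressure_sweep():
    """Coupled occlusion-lysis runs at 1, 5, 10 and 20 Pa."""
    base = CoupledScenario.reference()
    reports = compare_pressure_drops([1.0, 5.0, 10.0, 20.0], base)
    for r in reports:
        assert "error" not in r, f"sweep failed at {r['dp']} Pa: {r.get('error')}"
    return base, reports
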