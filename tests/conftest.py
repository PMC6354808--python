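import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neuropk.models import (
    DoseEvent,
    PKParams,
    build_rate_matrix,
    get_structure,
)
from neuropk.reference import REFERENCE_MEDIANS


@pytest.fixture(scope="session")
def medians() -> PKParams:
    return REFERENCE_MEDIANS


@pytest.fixture(scope="session")
def four_comp():
    return get_structure("four_compartment_lag")


@pytest.fixture(scope="session")
def single_dose():
    # 45.9 mg (306 g animal at 150 mg/kg) over 2 minutes
    return [DoseEvent(0.0, 45.9, 1.0 / 30.0)]


def reference_ode_amounts(params, structure, doses, times):
    """Test-local numerical oracle: adaptive RK integration of the same
    rate matrix, each dose segment integrated separately."""
    structure = get_structure(structure)
    A = build_rate_matrix(params, structure)
    n = structure.n_state
    c = structure.state_index("central")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    breaks = {0.0}
    breaks.update(float(t) for t in times)
    for d in doses:
        breaks.add(float(d.start_time))
        if d.infusion_duration > 0:
            breaks.add(float(d.end_time))
    breaks = sorted(breaks)
    x = np.zeros(n)
    out = np.zeros((len(times), n))
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        for d in doses:
            if d.infusion_duration == 0 and d.start_time == t0:
                x[c] += d.amount
        rate = sum(
            d.amount / d.infusion_duration
            for d in doses
            if d.infusion_duration > 0 and d.start_time <= t0 and d.end_time >= t1
        )
        u = np.zeros(n)
        u[c] = rate
        sol = solve_ivp(
            lambda t, s: A @ s + u,
            (t0, t1),
            x,
            method="DOP853",
            rtol=1e-12,
            atol=1e-14,
            dense_output=True,
        )
        for i, t in enumerate(times):
            if t0 < t <= t1:
                out[i] = sol.sol(t)
        x = sol.y[:, -1]
    return out
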