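import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clotfilm import (
    ChannelGeometry,
    TransportParams,
    default_parameters,
    equilibrate_clot,
    from_ode,
    run_elution,
    run_loading,
    simulate,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def baseline_traj():
    """One baseline 800-s cascade integration shared across the suite."""
    return simulate()


@pytest.fixture(scope="session")
def ode_series(baseline_traj):
    """ODE-coupled bottom-wall flux J(t) and fibrin(t) for the channel runs."""
    return from_ode(baseline_traj)


@pytest.fixture(scope="session")
def channel():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def tparams():
    return TransportParams()


@pytest.fixture(scope="session")
def loading_run(channel, tparams, ode_series):
    """800-s thrombin loading on the default 50×30 grid (timed)."""
    J, fib = ode_series
    t0 = time.perf_counter()
    hist = run_loading(channel, tparams, J, fib, t_end=800.0)
    return hist, time.perf_counter() - t0


@pytest.fixture(scope="session")
def elution_after_loading(loading_run, tparams, ode_series):
    """200-s elution continuing the 800-s loading state (timed)."""
    hist, _ = loading_run
    _, fib = ode_series
    t0 = time.perf_counter()
    res = run_elution(hist, tparams, t_end=200.0, fibrin=float(fib(800.0)))
    return res, time.perf_counter() - t0


@pytest.fixture(scope="session")
def grid_pair(channel, tparams, ode_series):
    """Clot-average total thrombin at 500 s on 100×60 and 200×120 grids."""
    J, fib = ode_series
    totals = {}
    for factor in (2, 4):
        hist = run_loading(channel.refined(factor), tparams, J, fib, t_end=500.0)
        totals[factor] = (hist.clot_total[-1], hist.budget_closure())
    return totals


@pytest.fixture(scope="session")
def washout_halflives(tparams):
    """Elution half-lives of a dilutely pre-loaded clot vs fibrin level.

    Uses a coarse 25×15 grid and a 0.01 μM total load so the linear
    (dilute) retardation factor applies.
    """
    geom = ChannelGeometry(nx=25, ny=15)
    out = {}
    for fib in (0.0, 9.0, 30.0, 90.0):
        state = equilibrate_clot(geom, tparams, fibrin=fib, total_clot_avg=0.01)
        res = run_elution(state, tparams, t_end=6000.0, geometry=geom,
                          fibrin=fib, record_dt=(0.25 if fib == 0 else 1.0),
                          stop_when_halved=True)
        assert res.half_life.reached
        out[fib] = res.half_life.halflife
    return out


@pytest.fixture(scope="session")
def escape_sweep():
    """Baseline endpoints for escape half-lives of 1, 2 and 4 s."""
    from clotfilm import Scenario

    return {tau: simulate(scenario=Scenario(escape_halflife=tau))
            for tau in (1.0, 2.0, 4.0)}
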