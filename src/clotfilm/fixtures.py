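"""Stand-in input series for the transport simulation.

The channel-flow study needs a bottom-wall thrombin flux J(t) and an
intraclot fibrin(t) series.  Experimentally these come from effluent
immunoassays; here they are generated either by coupling the thin-film ODE
model's own output (``from_ode``) or as parametric saturating ramps.
All fixtures are deterministic given their parameters; optional
multiplicative log-normal noise takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observables import flux_f12
from .reduced_ode import Trajectory

__all__ = ["TimeSeriesFixture", "from_ode", "parametric_ramp"]


@dataclass(frozen=True)
class TimeSeriesFixture:
    """A non-negative time series with provenance metadata."""

    times: np.ndarray
    values: np.ndarray
    units: str
    provenance: str   # "ode-coupled" | "parametric" | "constant"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("fixture times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("fixture values must be non-negative")

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.times, self.values)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.times, f"value_{self.units}": self.values})
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            df.to_csv(fh, index=False)

    def with_noise(self, sigma: float, seed: int) -> "TimeSeriesFixture":
        """Multiplicative log-normal noise for robustness tests."""
        rng = np.random.default_rng(seed)
        noisy = self.values * rng.lognormal(0.0, sigma, self.values.shape)
        return TimeSeriesFixture(self.times, noisy, self.units,
                                 f"{self.provenance}+lognormal(sigma={sigma},seed={seed})")


def from_ode(traj: Trajectory, n_points: int = 801
             ) -> tuple[TimeSeriesFixture, TimeSeriesFixture]:
    """Couple the thin-film model's own thrombin flux and fibrin to the PDE.

    J(t) is the F1.2-form production flux η4·α4·Xa(t)·δ (thrombin generated
    per unit patch area), resampled with fibrin(t) to a uniform grid.
    """
    grid = np.linspace(traj.times[0], traj.times[-1], n_points)
    jf = flux_f12(traj)
    j = TimeSeriesFixture(grid, np.interp(grid, jf.times, jf.values),
                          "uM_um_per_s", "ode-coupled")
    f = TimeSeriesFixture(grid, np.interp(grid, traj.times, traj.fibrin),
                          "uM", "ode-coupled")
    return j, f


def parametric_ramp(t_end: float, plateau: float, rise_time: float,
                    n_points: int = 801, shape: str = "exponential"
                    ) -> TimeSeriesFixture:
    """Smooth saturating ramp plateau·(1 − exp(−t/rise_time)).

    ``shape`` is kept for forward compatibility; only the exponential
    saturation is implemented.
    """
    if plateau < 0:
        raise ValueError("plateau must be non-negative")
    if rise_time <= 0:
        raise ValueError("rise_time must be positive")
    if shape != "exponential":
        raise ValueError(f"unknown ramp shape {shape!r}")
    t = np.linspace(0.0, t_end, n_points)
    return TimeSeriesFixture(t, plateau * (1.0 - np.exp(-t / rise_time)),
                             "arbitrary", "parametric")
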