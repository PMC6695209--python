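"""Derived observables: elution fluxes, effluent amounts, thrombin partitioning.

Two eluted species are assayable in the effluent of a flow assay: the
prothrombin activation fragment F1.2 (a 1:1 marker of thrombin generation
that escapes freely) and thrombin–antithrombin complex TAT (70% of eluted
thrombin; the rest is captured by other inhibitors).  Their surface fluxes
follow directly from the thin-film states:

    J_F1.2(t) = η4·α4·[Xa](t)·δ
    J_TAT(t)  = 0.7·k_elute·[IIa_free](t)·δ

with δ the core thickness.  The printed fluxes use (V_pore/area) = δ, i.e.
they omit the porosity factor; ``porosity_corrected=True`` opts into
δ·porosity instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParameters
from .reduced_ode import Trajectory, equilibrium_free_fraction

__all__ = [
    "FluxSeries",
    "MOL_PER_M2_S_PER_UM_UM_S",
    "flux_f12",
    "flux_tat",
    "cumulative_eluted",
    "thrombin_partition",
    "PartitionSeries",
    "fibrin_mg_per_ml",
    "UM_PER_MG_ML",
    "elution_halflife",
    "HalfLife",
]

#: 1 μM·μm/s = 1e-9 mol·m⁻²·s⁻¹
MOL_PER_M2_S_PER_UM_UM_S = 1e-9

#: fibrin monomer concentration per mass density: 3 mg/mL ↔ 9 μM
UM_PER_MG_ML = 3.0


@dataclass(frozen=True)
class FluxSeries:
    """A surface elution flux over time, in μM·μm·s⁻¹."""

    times: np.ndarray
    values: np.ndarray
    species: str
    units: str = "uM*um/s"

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")

    @property
    def in_mol_per_m2_s(self) -> np.ndarray:
        return self.values * MOL_PER_M2_S_PER_UM_UM_S

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            f"flux_{self.species}_uM_um_per_s": self.values,
        })


def _thickness(params: ModelParameters, porosity_corrected: bool) -> float:
    d = params.geometry.delta
    return d * params.geometry.porosity if porosity_corrected else d


def flux_f12(traj: Trajectory, params: ModelParameters | None = None,
             porosity_corrected: bool = False) -> FluxSeries:
    """F1.2 elution flux η4·α4·Xa(t)·δ — production-rate-limited escape."""
    p = params if params is not None else traj.params
    r4 = p.reaction(4)
    values = r4.rate * traj.xa * _thickness(p, porosity_corrected)
    return FluxSeries(traj.times, values, species="F1.2")


def flux_tat(traj: Trajectory, params: ModelParameters | None = None,
             porosity_corrected: bool = False) -> FluxSeries:
    """TAT elution flux tat_fraction·k_elute·IIa_free(t)·δ."""
    p = params if params is not None else traj.params
    values = (p.tat_fraction * p.k_elute * traj.iia_free
              * _thickness(p, porosity_corrected))
    return FluxSeries(traj.times, values, species="TAT")


def cumulative_eluted(flux: FluxSeries, area: float) -> np.ndarray:
    """Cumulative effluent amount ∫J·area dt in femtomol.

    ``area`` is the patch area in μm².  Trapezoidal quadrature on the flux
    grid; the result is monotone non-decreasing for non-negative fluxes.
    """
    if np.any(np.diff(flux.times) <= 0):
        raise ValueError("flux time grid must be strictly increasing")
    mol_per_s = flux.in_mol_per_m2_s * (area * 1e-12)  # μm² → m²
    cum = np.concatenate([
        [0.0],
        np.cumsum(np.diff(flux.times) * 0.5 * (mol_per_s[1:] + mol_per_s[:-1])),
    ])
    return cum * 1e15  # mol → fmol


@dataclass(frozen=True)
class PartitionSeries:
    """Thrombin partition between free, E-bound and γ′-bound pools."""

    times: np.ndarray
    free: np.ndarray
    e_bound: np.ndarray
    gamma_bound: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.free + self.e_bound + self.gamma_bound

    @property
    def fractions(self) -> pd.DataFrame:
        """Fractions of total per pool; free fraction is 1 where total is 0."""
        total = self.total
        safe = np.where(total > 0, total, 1.0)
        f_free = np.where(total > 0, self.free / safe, 1.0)
        f_e = np.where(total > 0, self.e_bound / safe, 0.0)
        f_g = np.where(total > 0, self.gamma_bound / safe, 0.0)
        return pd.DataFrame({"time_s": self.times, "free": f_free,
                             "e_bound": f_e, "gamma_bound": f_g})


def thrombin_partition(traj: Trajectory) -> PartitionSeries:
    return PartitionSeries(traj.times, traj.iia_free, traj.es, traj.gs)


def fibrin_mg_per_ml(fibrin_uM: float | np.ndarray) -> float | np.ndarray:
    """Convert fibrin monomer concentration (μM) to mass density (mg/mL).

    Anchored to the plasma fibrinogen equivalence 3 mg/mL = 9 μM (an
    effective monomer mass of ~333 kDa), so 90 μM ↔ 30 mg/mL exactly.
    """
    arr = np.asarray(fibrin_uM, dtype=float)
    if np.any(arr < 0):
        raise ValueError("fibrin concentration must be non-negative")
    out = arr / UM_PER_MG_ML
    return float(out) if np.isscalar(fibrin_uM) else out


@dataclass(frozen=True)
class HalfLife:
    """Outcome of a half-life measurement on a decaying amount series."""

    halflife: float | None   # s, None when the series never halves
    reached: bool
    final_fraction: float    # amount(t_end)/amount(0)

    def __str__(self) -> str:
        if self.reached:
            return f"half-life {self.halflife:.4g} s"
        return f"not reached (final fraction {self.final_fraction:.3f})"


def elution_halflife(times: np.ndarray, amounts: np.ndarray) -> HalfLife:
    """First time the amount falls to half its initial value.

    Linear interpolation between grid points.  If the series never halves
    within the window, reports ``reached=False`` with the final fraction.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(amounts, dtype=float)
    if t.size < 2 or a[0] <= 0:
        raise ValueError("need a positive initial amount and ≥ 2 samples")
    target = 0.5 * a[0]
    below = np.nonzero(a <= target)[0]
    if below.size == 0:
        return HalfLife(None, False, float(a[-1] / a[0]))
    k = below[0]
    if k == 0:
        return HalfLife(0.0, True, float(a[-1] / a[0]))
    frac = (a[k - 1] - target) / (a[k - 1] - a[k])
    t_half = t[k - 1] + frac * (t[k] - t[k - 1])
    return HalfLife(float(t_half), True, float(a[-1] / a[0]))


def equilibrium_partition_check(traj: Trajectory, t: float) -> dict:
    """Compare the kinetic free fraction at time ``t`` with the closed-form
    two-site equilibrium (diagnostic for the binding-equilibrium limit)."""
    s = traj.at(t)
    total = s.total_thrombin
    kinetic = s.iia_free / total if total > 0 else 1.0
    eq = equilibrium_free_fraction(total, s.fibrin, traj.params.sites)
    return {"time_s": t, "kinetic_free_fraction": kinetic,
            "equilibrium_free_fraction": eq}
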