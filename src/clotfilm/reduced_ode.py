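"""The 8-ODE thin-film coagulation cascade and its scenario transforms.

State vector (all μM):

====  =========  ====================================================
idx   name       meaning
====  =========  ====================================================
0     tf_star    TF/FVIIa extrinsic tenase complex ("TF*")
1     xa         prothrombinase surrogate FXa/FVa
2     ixa        intrinsic tenase surrogate FIXa/FVIIIa
3     xia        FXIa
4     fibrin     fibrin monomer incorporated into the clot
5     iia_free   free thrombin
6     es         thrombin bound to the weak E-domain site
7     gs         thrombin bound to the strong γ′ site
====  =========  ====================================================

The cascade is linear in the enzymes; the only nonlinearity is reversible
thrombin adsorption to fibrin sites, whose total capacity grows with fibrin
(θ_E = 1.6·fibrin, θ_γ = 0.3·fibrin, scenario-scalable for γ′).  Free
thrombin and FXIa elute from the core with rate k_elute; all proteases are
inhibited first order with rate k_i (k_i,TF for TF*).  Bound thrombin is
catalytically silent here and protected from inhibition — a deliberate model
reading (real fibrin-bound thrombin retains some activity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .parameters import (
    LN2,
    BindingSite,
    ModelParameters,
    ParameterValidationError,
    default_parameters,
)

__all__ = [
    "STATE_NAMES",
    "CoreState",
    "Scenario",
    "Trajectory",
    "SolverError",
    "rhs",
    "simulate",
    "apply_scenario",
    "pathway_decomposition",
    "PathwayDecomposition",
    "equilibrium_free_fraction",
]

logger = logging.getLogger(__name__)

STATE_NAMES = ("tf_star", "xa", "ixa", "xia", "fibrin", "iia_free", "es", "gs")

NEGATIVITY_TOLERANCE = -1e-9  # μM; below this a solve is considered broken


class SolverError(RuntimeError):
    """Stiff integration failed or produced an unphysical state."""


class CoreState(NamedTuple):
    tf_star: float
    xa: float
    ixa: float
    xia: float
    fibrin: float
    iia_free: float
    es: float
    gs: float

    @property
    def total_thrombin(self) -> float:
        return self.iia_free + self.es + self.gs


@dataclass(frozen=True)
class Scenario:
    """In-silico experiment toggles applied on top of the baseline.

    gprp
        Block fibrin polymerization/binding (Gly-Pro-Arg-Pro peptide).
        ``gprp_mode`` selects zeroing the fibrin-generation reaction
        ("alpha5_zero", default) or making both binding sites infinitely
        weak ("kd_inf", K_D → 1e7 μM).
    hemophilia
        Severe hemophilia A/B: no intrinsic-tenase path (α2 = α3 = 0).
    no_fxia_feedback
        Knock out thrombin→FXIa feedback (α6 = α7 = 0).
    no_tf_ixase
        TF* cannot make FIXa (α2 = 0).
    gamma_prime_scale
        Multiplies the γ′ site density (0.5 / 1 / 2 for 50–200% of normal
        γ′-fibrinogen).
    escape_halflife
        Free-species elution half-life in seconds (k_elute = ln2/τ).
    """

    gprp: bool = False
    hemophilia: bool = False
    no_fxia_feedback: bool = False
    no_tf_ixase: bool = False
    gamma_prime_scale: float = 1.0
    escape_halflife: float = 2.0
    gprp_mode: str = "alpha5_zero"

    def __post_init__(self) -> None:
        if self.gamma_prime_scale <= 0:
            raise ParameterValidationError("gamma_prime_scale must be positive")
        if self.escape_halflife <= 0:
            raise ParameterValidationError("escape_halflife must be positive")
        if self.gprp_mode not in ("alpha5_zero", "kd_inf"):
            raise ParameterValidationError(
                f"gprp_mode must be 'alpha5_zero' or 'kd_inf', got {self.gprp_mode!r}"
            )


BASELINE = Scenario()


def apply_scenario(params: ModelParameters, scenario: Scenario) -> ModelParameters:
    """Return the parameter set transformed by a scenario.

    Reaction knockouts zero the reaction's k_cat (so the derived α is zero
    and the α-consistency invariant is preserved).  Toggles compose; unusual
    combinations are allowed but logged.
    """
    p = params
    notes: list[str] = []
    if scenario.escape_halflife != 2.0 or p.k_elute != LN2 / 2.0:
        p = replace(p, k_elute=LN2 / scenario.escape_halflife)
    if scenario.gamma_prime_scale != 1.0:
        p = p.replace_site(
            "gamma_prime",
            sites_per_monomer=params.site_gamma.sites_per_monomer
            * scenario.gamma_prime_scale,
        )
        notes.append(f"gamma_prime_scale={scenario.gamma_prime_scale}")
    if scenario.hemophilia:
        p = p.replace_reaction(2, kcat=0.0).replace_reaction(3, kcat=0.0)
        notes.append("hemophilia: alpha2=alpha3=0")
    if scenario.no_tf_ixase:
        p = p.replace_reaction(2, kcat=0.0)
        notes.append("no_tf_ixase: alpha2=0")
    if scenario.no_fxia_feedback:
        p = p.replace_reaction(6, kcat=0.0).replace_reaction(7, kcat=0.0)
        notes.append("no_fxia_feedback: alpha6=alpha7=0")
    if scenario.gprp:
        if scenario.gprp_mode == "alpha5_zero":
            p = p.replace_reaction(5, kcat=0.0)
            notes.append("gprp: alpha5=0")
        else:
            # K_D → 1e7 μM for both sites with k_r held (k_f re-derived):
            # same vanishing equilibrium occupancy without a 1e9 s⁻¹ rate.
            p = p.replace_site("E", Kd=1e7, kr=params.site_e.kr)
            p = p.replace_site("gamma_prime", Kd=1e7, kr=params.site_gamma.kr)
            notes.append("gprp: Kd=1e7 uM both sites")
    if scenario.gprp and (scenario.hemophilia or scenario.no_fxia_feedback):
        logger.info("composed scenario toggles: %s", "; ".join(notes))
    elif notes:
        logger.debug("scenario transforms: %s", "; ".join(notes))
    return p


class _Coeffs(NamedTuple):
    """Scalar coefficients of the RHS, pre-folded for the hot loop."""

    a1: float
    a2: float
    a3: float
    a4: float   # η4·α4
    a5: float   # η5·α5
    a6: float   # η6·α6
    a7: float
    ke: float
    ki: float
    kitf: float
    kfE: float
    krE: float
    kfG: float
    krG: float
    sE: float   # E sites per fibrin monomer
    sG: float   # γ′ sites per fibrin monomer (scenario-scaled)


def _coeffs(p: ModelParameters) -> _Coeffs:
    r = p.reactions
    return _Coeffs(
        a1=r[0].rate, a2=r[1].rate, a3=r[2].rate, a4=r[3].rate,
        a5=r[4].rate, a6=r[5].rate, a7=r[6].rate,
        ke=p.k_elute, ki=p.k_i, kitf=p.k_i_tf,
        kfE=p.site_e.kf, krE=p.site_e.kr,
        kfG=p.site_gamma.kf, krG=p.site_gamma.kr,
        sE=p.site_e.sites_per_monomer, sG=p.site_gamma.sites_per_monomer,
    )


def _rhs(t: float, y: np.ndarray, c: _Coeffs) -> np.ndarray:
    T, X, I9, I11, F, C, E, G = y
    dE = c.kfE * C * (c.sE * F - E) - c.krE * E
    dG = c.kfG * C * (c.sG * F - G) - c.krG * G
    return np.array([
        -c.kitf * T,
        c.a1 * T + c.a3 * I9 - c.ki * X,
        c.a2 * T + c.a7 * I11 - c.ki * I9,
        c.a6 * C - (c.ke + c.ki) * I11,
        c.a5 * C,
        c.a4 * X - dE - dG - (c.ke + c.ki) * C,
        dE,
        dG,
    ])


def _jac(t: float, y: np.ndarray, c: _Coeffs) -> np.ndarray:
    T, X, I9, I11, F, C, E, G = y
    J = np.zeros((8, 8))
    J[0, 0] = -c.kitf
    J[1, 0] = c.a1; J[1, 2] = c.a3; J[1, 1] = -c.ki
    J[2, 0] = c.a2; J[2, 3] = c.a7; J[2, 2] = -c.ki
    J[3, 5] = c.a6; J[3, 3] = -(c.ke + c.ki)
    J[4, 5] = c.a5
    # binding derivatives
    dE_dC = c.kfE * (c.sE * F - E)
    dE_dE = -(c.kfE * C + c.krE)
    dE_dF = c.kfE * C * c.sE
    dG_dC = c.kfG * (c.sG * F - G)
    dG_dG = -(c.kfG * C + c.krG)
    dG_dF = c.kfG * C * c.sG
    J[6, 5] = dE_dC; J[6, 6] = dE_dE; J[6, 4] = dE_dF
    J[7, 5] = dG_dC; J[7, 7] = dG_dG; J[7, 4] = dG_dF
    J[5, 1] = c.a4
    J[5, 5] = -(dE_dC + dG_dC) - (c.ke + c.ki)
    J[5, 6] = -dE_dE
    J[5, 7] = -dG_dG
    J[5, 4] = -(dE_dF + dG_dF)
    return J


def rhs(t: float, state: Sequence[float] | CoreState,
        params: ModelParameters) -> np.ndarray:
    """Time derivative of the 8-state cascade at ``state`` (μM/s).

    ``iia_free`` (index 5) is the thrombin species that drives fibrin
    generation and FXIa feedback and that elutes; bound thrombin only
    exchanges with it through the two site ODEs.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (8,):
        raise ValueError(f"state must have 8 entries, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise SolverError(f"non-finite state passed to rhs at t={t}: {y}")
    return _rhs(t, y, _coeffs(params))


@dataclass(frozen=True)
class Trajectory:
    """Result of a cascade integration on an output grid."""

    times: np.ndarray            # s, strictly increasing
    states: np.ndarray           # (n_times, 8), μM
    params: ModelParameters      # scenario-resolved parameters
    scenario: Scenario
    solver_info: dict = field(compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, 8):
            raise ValueError("states must be (n_times, 8)")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def tf_star(self) -> np.ndarray: return self["tf_star"]
    @property
    def xa(self) -> np.ndarray: return self["xa"]
    @property
    def ixa(self) -> np.ndarray: return self["ixa"]
    @property
    def xia(self) -> np.ndarray: return self["xia"]
    @property
    def fibrin(self) -> np.ndarray: return self["fibrin"]
    @property
    def iia_free(self) -> np.ndarray: return self["iia_free"]
    @property
    def es(self) -> np.ndarray: return self["es"]
    @property
    def gs(self) -> np.ndarray: return self["gs"]

    @property
    def total_thrombin(self) -> np.ndarray:
        """Free + E-bound + γ′-bound thrombin, μM."""
        return self.iia_free + self.es + self.gs

    def at(self, t: float) -> CoreState:
        """State at time ``t`` (linear interpolation between grid points)."""
        vals = [float(np.interp(t, self.times, self.states[:, k])) for k in range(8)]
        return CoreState(*vals)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=[f"{n}_uM" for n in STATE_NAMES])
        df.insert(0, "time_s", self.times)
        df["total_thrombin_uM"] = self.total_thrombin
        return df


def simulate(params: ModelParameters | None = None,
             scenario: Scenario | None = None,
             t_end: float = 800.0,
             output_grid: np.ndarray | None = None,
             rtol: float = 1e-8,
             atol: float = 1e-12) -> Trajectory:
    """Integrate the cascade from the quiescent initial state.

    Initial condition: everything zero except TF* = ``params.tf_star_0``.
    A BDF stiff solver with an analytic Jacobian is used; the thrombin–fibrin
    association rates (k_f·θ up to ~10⁴ s⁻¹) make the system stiff.  Small
    negative excursions within ``NEGATIVITY_TOLERANCE`` are clipped; anything
    below that aborts with :class:`SolverError`.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    base = params if params is not None else default_parameters()
    scen = scenario if scenario is not None else BASELINE
    p = apply_scenario(base, scen)
    c = _coeffs(p)
    if output_grid is None:
        output_grid = np.linspace(0.0, t_end, max(int(round(2 * t_end)), 2) + 1)
    grid = np.asarray(output_grid, dtype=float)

    y0 = np.zeros(8)
    y0[0] = p.tf_star_0
    sol = solve_ivp(_rhs, (float(grid[0]), float(grid[-1])), y0, method="BDF",
                    jac=_jac, args=(c,), rtol=rtol, atol=atol, t_eval=grid)
    if not sol.success:
        raise SolverError(
            f"BDF integration failed: {sol.message} "
            f"(nfev={sol.nfev}, last t={sol.t[-1] if sol.t.size else 'n/a'})"
        )
    states = sol.y.T.copy()
    worst = states.min()
    if worst < NEGATIVITY_TOLERANCE:
        raise SolverError(
            f"state went negative beyond tolerance: min={worst:.3e} μM"
        )
    np.clip(states, 0.0, None, out=states)
    info = {"method": "BDF", "rtol": rtol, "atol": atol,
            "nfev": int(sol.nfev), "njev": int(sol.njev), "nlu": int(sol.nlu)}
    return Trajectory(times=grid, states=states, params=p, scenario=scen,
                      solver_info=info)


@dataclass(frozen=True)
class PathwayDecomposition:
    """Baseline run and its knockout companions on a shared grid.

    The FXIa-feedback contribution to a species is computed as the
    difference (baseline − no-feedback), valid because the cascade is
    linear in the enzyme concentrations upstream of binding.
    """

    baseline: Trajectory
    no_fxia_feedback: Trajectory
    no_tf_ixase: Trajectory
    hemophilia: Trajectory

    def fxia_pathway(self, species: str) -> np.ndarray:
        """Contribution of the thrombin→FXIa feedback loop to ``species``."""
        return self.baseline[species] - self.no_fxia_feedback[species]


def pathway_decomposition(params: ModelParameters | None = None,
                          t_end: float = 800.0,
                          output_grid: np.ndarray | None = None) -> PathwayDecomposition:
    """Run baseline plus the three knockout variants on one output grid."""
    if output_grid is None:
        output_grid = np.linspace(0.0, t_end, max(int(round(2 * t_end)), 2) + 1)
    runs = {}
    for name, scen in (
        ("baseline", Scenario()),
        ("no_fxia_feedback", Scenario(no_fxia_feedback=True)),
        ("no_tf_ixase", Scenario(no_tf_ixase=True)),
        ("hemophilia", Scenario(hemophilia=True)),
    ):
        runs[name] = simulate(params, scen, t_end=t_end, output_grid=output_grid)
    return PathwayDecomposition(**runs)


def equilibrium_free_fraction(iia_total: float, fibrin: float,
                              sites: Sequence[BindingSite],
                              gamma_prime_scale: float = 1.0) -> float:
    """Free fraction of thrombin at two-site binding equilibrium.

    Solves  free + Σ_s θ_s·free/(K_D,s + free) = total  for the free
    concentration by bracketed root finding (residual tolerance 1e-12 of the
    total).  In the dilute limit the fraction tends to the closed form
    1/(1 + Σ θ_s/K_D,s); with no fibrin (or infinitely weak sites) it is 1.
    """
    if iia_total < 0 or fibrin < 0:
        raise ParameterValidationError("iia_total and fibrin must be non-negative")
    thetas = []
    for s in sites:
        spm = s.sites_per_monomer * (gamma_prime_scale if "gamma" in s.name else 1.0)
        thetas.append((spm * fibrin, s.Kd))
    dilute = 1.0 / (1.0 + sum(th / kd for th, kd in thetas if kd > 0 and th > 0))
    if iia_total == 0.0 or fibrin == 0.0:
        return dilute if fibrin > 0 else 1.0
    total = iia_total

    def residual(free: float) -> float:
        return free + sum(th * free / (kd + free) for th, kd in thetas) - total

    free = brentq(residual, 0.0, total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    return free / total
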