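"""Kinetic and geometric parameterization of the thin-film clotting model.

The reduced model treats the 15-μm "core" of a clot forming on a
collagen/tissue-factor patch as a well-mixed thin film.  Zymogen substrates
are held at plasma levels, so each Michaelis–Menten reaction linearizes to a
first-order rate α = k_cat·[S]0/(Km+[S]0) in the enzyme concentration,
optionally scaled by an effectiveness factor η ≤ 1 when substrate delivery
into the core is transport-limited.  Thrombin reversibly adsorbs to fibrin at
a weak E-domain site and a strong γ′-chain site ("antithrombin-I" activity).

Units: concentrations in μM, time in s, lengths in μm throughout.  pM and nM
values (initial TF/FVIIa, FXI zymogen) are converted at the boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterValidationError",
    "ConfigError",
    "ReactionSpec",
    "BindingSite",
    "CoreGeometry",
    "ModelParameters",
    "compute_alpha",
    "compute_kr",
    "default_parameters",
    "load_config",
    "surface_density_to_concentration",
]

LN2 = math.log(2.0)
AVOGADRO = 6.02214076e23


class ParameterValidationError(ValueError):
    """A kinetic or geometric parameter is out of its physical range."""


class ConfigError(ParameterValidationError):
    """A configuration file contains unknown or invalid entries."""


def _require_finite_nonneg(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v) or v < 0:
            raise ParameterValidationError(
                f"{name}: expected finite non-negative values, got {values!r}"
            )


def compute_alpha(kcat: float, Km: float, S0: float) -> float:
    """Linearized first-order rate α = k_cat·S0/(Km+S0) in s⁻¹.

    With substrate clamped at its plasma level S0, the Michaelis–Menten rate
    becomes first order in enzyme: dP/dt = α·[E].  Saturation (S0 ≫ Km)
    recovers k_cat; zero substrate gives zero.
    """
    _require_finite_nonneg("compute_alpha", kcat, Km, S0)
    if Km + S0 <= 0:
        raise ParameterValidationError("compute_alpha: Km + S0 must be positive")
    return kcat * S0 / (Km + S0)


def compute_kr(Kd: float, kf: float) -> float:
    """Dissociation rate k_r = k_f·K_D (s⁻¹) for a reversible binding site."""
    _require_finite_nonneg("compute_kr", Kd, kf)
    return kf * Kd


@dataclass(frozen=True)
class ReactionSpec:
    """One linearized enzymatic reaction of the cascade.

    ``alpha`` is always derived from (kcat, Km, S0); construct via
    :meth:`make` or :meth:`with_overrides` so it can never drift out of sync.
    """

    id: int
    substrate: str
    enzyme: str
    S0: float          # μM
    kcat: float        # s⁻¹
    Km: float          # μM
    eta: float         # dimensionless effectiveness factor
    alpha: float       # derived, s⁻¹

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 7:
            raise ParameterValidationError(f"reaction id must be 1–7, got {self.id}")
        if self.S0 < 0 or self.Km <= 0 or self.kcat < 0:
            raise ParameterValidationError(
                f"reaction {self.id}: S0 ≥ 0, Km > 0, kcat ≥ 0 required"
            )
        if not 0.0 <= self.eta <= 1.0:
            raise ParameterValidationError(
                f"reaction {self.id}: eta must be in [0, 1], got {self.eta}"
            )
        expected = compute_alpha(self.kcat, self.Km, self.S0)
        if abs(self.alpha - expected) > 1e-12 * max(expected, 1e-300):
            raise ParameterValidationError(
                f"reaction {self.id}: alpha={self.alpha} inconsistent with "
                f"kcat·S0/(Km+S0)={expected}"
            )

    @classmethod
    def make(cls, id: int, substrate: str, enzyme: str,
             S0: float, kcat: float, Km: float, eta: float) -> "ReactionSpec":
        return cls(id, substrate, enzyme, S0, kcat, Km, eta,
                   alpha=compute_alpha(kcat, Km, S0))

    def with_overrides(self, **kw: float) -> "ReactionSpec":
        """Return a copy with kinetic fields replaced and α re-derived."""
        fields = {"S0": self.S0, "kcat": self.kcat, "Km": self.Km, "eta": self.eta}
        unknown = set(kw) - set(fields)
        if unknown:
            raise ConfigError(f"reaction {self.id}: unknown fields {sorted(unknown)}")
        fields.update(kw)
        return ReactionSpec.make(self.id, self.substrate, self.enzyme,
                                 fields["S0"], fields["kcat"], fields["Km"],
                                 fields["eta"])

    @property
    def rate(self) -> float:
        """Effective first-order rate η·α (s⁻¹) entering the ODEs."""
        return self.eta * self.alpha


@dataclass(frozen=True)
class BindingSite:
    """A reversible thrombin binding site on fibrin.

    ``kr`` is derived as k_f·K_D.  ``sites_per_monomer`` is the stoichiometric
    site density per fibrin monomer (1.6 for the E-domain, 0.3 for γ′).
    """

    name: str
    Kd: float                 # μM
    kf: float                 # μM⁻¹ s⁻¹
    kr: float                 # s⁻¹, derived
    sites_per_monomer: float  # dimensionless

    def __post_init__(self) -> None:
        _require_finite_nonneg(f"site {self.name}", self.Kd, self.kf, self.kr)
        if self.sites_per_monomer <= 0:
            raise ParameterValidationError(
                f"site {self.name}: sites_per_monomer must be positive"
            )
        expected = compute_kr(self.Kd, self.kf)
        if abs(self.kr - expected) > 1e-12 * max(expected, 1e-300):
            raise ParameterValidationError(
                f"site {self.name}: kr={self.kr} inconsistent with kf·Kd={expected}"
            )

    @classmethod
    def make(cls, name: str, Kd: float, kf: float,
             sites_per_monomer: float) -> "BindingSite":
        return cls(name, Kd, kf, compute_kr(Kd, kf), sites_per_monomer)

    def with_overrides(self, *, Kd: float | None = None, kf: float | None = None,
                       kr: float | None = None,
                       sites_per_monomer: float | None = None) -> "BindingSite":
        """Copy with fields replaced.

        If ``kr`` is given it is held fixed and k_f is re-derived from the
        (possibly new) K_D; otherwise k_r is re-derived from k_f·K_D.
        """
        Kd = self.Kd if Kd is None else Kd
        spm = self.sites_per_monomer if sites_per_monomer is None else sites_per_monomer
        if kr is not None:
            if kf is not None:
                raise ConfigError(f"site {self.name}: give kf or kr, not both")
            if Kd <= 0:
                raise ParameterValidationError(
                    f"site {self.name}: Kd must be positive when deriving kf from kr"
                )
            return BindingSite(self.name, Kd, kr / Kd, kr, spm)
        kf = self.kf if kf is None else kf
        return BindingSite.make(self.name, Kd, kf, spm)


@dataclass(frozen=True)
class CoreGeometry:
    """Thin-film core geometry over the collagen/TF patch."""

    delta: float = 15.0          # core thickness, μm
    porosity: float = 0.5        # void fraction
    patch_length: float = 250.0  # μm
    patch_width: float = 250.0   # μm

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ParameterValidationError("porosity must be in (0, 1)")
        if min(self.delta, self.patch_length, self.patch_width) <= 0:
            raise ParameterValidationError("geometry lengths must be positive")

    @property
    def area(self) -> float:
        """Patch area, μm²."""
        return self.patch_length * self.patch_width

    @property
    def v_pore(self) -> float:
        """Pore volume of the core, μm³ (= area·δ·porosity)."""
        return self.area * self.delta * self.porosity


@dataclass(frozen=True)
class ModelParameters:
    """Full parameterization of the 8-ODE thin-film cascade.

    Defaults are the baseline parameter set: seven linearized reactions with
    (η1, η2, η3, η7) = 1, η4 = 0.18, η5 = 0.05, η6 = 0.36; E-domain and
    γ′ binding sites; 15 μm core at 50% porosity on a 250×250 μm patch;
    TF* = 2.2 pM with a 3-min inhibition half-life; free-species elution
    half-life of 2 s and a 1-min protease inhibition half-life.
    """

    reactions: tuple[ReactionSpec, ...]
    sites: tuple[BindingSite, BindingSite]   # (E-domain, γ′)
    geometry: CoreGeometry
    tf_star_0: float = 2.2e-6        # μM (2.2 pM)
    k_elute: float = LN2 / 2.0       # s⁻¹, free thrombin & FXIa escape
    k_i: float = LN2 / 60.0          # s⁻¹, protease inhibition
    k_i_tf: float = LN2 / 180.0      # s⁻¹, TF* inhibition
    tat_fraction: float = 0.7        # eluted thrombin captured as TAT
    provenance: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if len(self.reactions) != 7 or [r.id for r in self.reactions] != list(range(1, 8)):
            raise ParameterValidationError("expected reactions 1–7 in order")
        if len(self.sites) != 2:
            raise ParameterValidationError("expected exactly 2 binding sites")
        _require_finite_nonneg("rates", self.tf_star_0, self.k_elute,
                               self.k_i, self.k_i_tf)
        if not 0.0 <= self.tat_fraction <= 1.0:
            raise ParameterValidationError("tat_fraction must be in [0, 1]")

    def reaction(self, rid: int) -> ReactionSpec:
        return self.reactions[rid - 1]

    @property
    def site_e(self) -> BindingSite:
        return self.sites[0]

    @property
    def site_gamma(self) -> BindingSite:
        return self.sites[1]

    def replace_reaction(self, rid: int, **kw: float) -> "ModelParameters":
        reactions = list(self.reactions)
        reactions[rid - 1] = reactions[rid - 1].with_overrides(**kw)
        return replace(self, reactions=tuple(reactions))

    def replace_site(self, name: str, **kw: float) -> "ModelParameters":
        sites = list(self.sites)
        idx = {"E": 0, "gamma_prime": 1}.get(name)
        if idx is None:
            raise ConfigError(f"unknown binding site {name!r}")
        sites[idx] = sites[idx].with_overrides(**kw)
        return replace(self, sites=(sites[0], sites[1]))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "reactions": {
                str(r.id): {"substrate": r.substrate, "enzyme": r.enzyme,
                            "S0_uM": r.S0, "kcat_per_s": r.kcat, "Km_uM": r.Km,
                            "eta": r.eta, "alpha_per_s": r.alpha}
                for r in self.reactions
            },
            "sites": {
                s.name: {"Kd_uM": s.Kd, "kf_per_uM_s": s.kf, "kr_per_s": s.kr,
                         "sites_per_monomer": s.sites_per_monomer}
                for s in self.sites
            },
            "geometry": {"delta_um": self.geometry.delta,
                         "porosity": self.geometry.porosity,
                         "patch_length_um": self.geometry.patch_length,
                         "patch_width_um": self.geometry.patch_width},
            "tf_star_0_pM": self.tf_star_0 * 1e6,
            "k_elute_per_s": self.k_elute,
            "k_i_per_s": self.k_i,
            "k_i_tf_per_s": self.k_i_tf,
            "tat_fraction": self.tat_fraction,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def default_parameters() -> ModelParameters:
    """The baseline parameterization (Michaelis–Menten table + binding sites).

    FXI's plasma level is 31 nM and is stored converted to 0.031 μM.
    """
    reactions = (
        ReactionSpec.make(1, "FX", "TF/FVIIa", S0=0.17, kcat=1.15, Km=0.24, eta=1.0),
        ReactionSpec.make(2, "FIX", "TF/FVIIa", S0=0.09, kcat=1.8, Km=0.42, eta=1.0),
        ReactionSpec.make(3, "FX", "FIXa/FVIIIa", S0=0.17, kcat=8.2, Km=0.082, eta=1.0),
        ReactionSpec.make(4, "prothrombin", "FXa/FVa", S0=1.4, kcat=30.0, Km=0.3, eta=0.18),
        ReactionSpec.make(5, "fibrinogen", "FIIa", S0=18.0, kcat=80.0, Km=6.5, eta=0.05),
        ReactionSpec.make(6, "FXI", "FIIa", S0=0.031, kcat=1.3e-4, Km=0.05, eta=0.36),
        ReactionSpec.make(7, "FIX", "FXIa", S0=0.09, kcat=0.21, Km=0.2, eta=1.0),
    )
    sites = (
        BindingSite.make("E", Kd=2.8, kf=100.0, sites_per_monomer=1.6),
        BindingSite.make("gamma_prime", Kd=0.1, kf=100.0, sites_per_monomer=0.3),
    )
    return ModelParameters(reactions=reactions, sites=sites, geometry=CoreGeometry())


def surface_density_to_concentration(density_per_um2: float,
                                     active_fraction: float,
                                     geometry: CoreGeometry) -> float:
    """Homogenize a surface site density over the core pore volume, in μM.

    For the default geometry, 1 TF molecule/μm² with 1% active as TF/FVIIa
    over V_pore = 250·250·15·0.5 μm³ gives ≈ 2.2 pM, reproducing the
    baseline ``tf_star_0``.
    """
    _require_finite_nonneg("surface_density", density_per_um2, active_fraction)
    molecules = density_per_um2 * geometry.area * active_fraction
    moles = molecules / AVOGADRO
    litres = geometry.v_pore * 1e-15  # μm³ → L
    return moles / litres * 1e6       # mol/L → μM


# -- configuration loading ------------------------------------------------
#
# Flat YAML schema: every key is listed in _CONFIG_KEYS; unknown keys are
# rejected by name.  Kinetic overrides re-derive α and k_r automatically.

def _set_reaction(rid: int, fname: str):
    def setter(p: ModelParameters, v: float) -> ModelParameters:
        return p.replace_reaction(rid, **{fname: float(v)})
    return setter


def _set_site(site: str, fname: str):
    def setter(p: ModelParameters, v: float) -> ModelParameters:
        return p.replace_site(site, **{fname: float(v)})
    return setter


def _set_geometry(fname: str):
    def setter(p: ModelParameters, v: float) -> ModelParameters:
        return replace(p, geometry=replace(p.geometry, **{fname: float(v)}))
    return setter


def _set_scalar(fname: str, scale: float = 1.0):
    def setter(p: ModelParameters, v: float) -> ModelParameters:
        return replace(p, **{fname: float(v) * scale})
    return setter


_CONFIG_KEYS: dict[str, object] = {}
for _rid in range(1, 8):
    for _f in ("S0", "kcat", "Km", "eta"):
        _CONFIG_KEYS[f"reaction{_rid}_{_f}"] = _set_reaction(_rid, _f)
for _site, _label in (("E", "site_E"), ("gamma_prime", "site_gamma")):
    for _f in ("Kd", "kf", "sites_per_monomer"):
        _CONFIG_KEYS[f"{_label}_{_f}"] = _set_site(_site, _f)
for _f in ("delta", "porosity", "patch_length", "patch_width"):
    _CONFIG_KEYS[f"geometry_{_f}_um" if _f != "porosity" else "geometry_porosity"] = \
        _set_geometry(_f)
_CONFIG_KEYS["tf_star_0_pM"] = _set_scalar("tf_star_0", 1e-6)
_CONFIG_KEYS["tf_star_0_nM"] = _set_scalar("tf_star_0", 1e-3)
_CONFIG_KEYS["tf_star_0_uM"] = _set_scalar("tf_star_0")
_CONFIG_KEYS["k_elute_per_s"] = _set_scalar("k_elute")
_CONFIG_KEYS["k_i_per_s"] = _set_scalar("k_i")
_CONFIG_KEYS["k_i_tf_per_s"] = _set_scalar("k_i_tf")
_CONFIG_KEYS["tat_fraction"] = _set_scalar("tat_fraction")


def load_config(source: str | Path | Mapping[str, float] | None) -> ModelParameters:
    """Merge a flat YAML config (or mapping) of overrides onto the defaults.

    Unknown keys raise :class:`ConfigError` naming the offending key; values
    are validated by the same invariants as the defaults.  All applied
    overrides are recorded in ``ModelParameters.provenance``.
    """
    if source is None:
        overrides: Mapping[str, float] = {}
    elif isinstance(source, Mapping):
        overrides = dict(source)
    else:
        loaded = yaml.safe_load(Path(source).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {source} must be a mapping of key: value")
        overrides = loaded

    params = default_parameters()
    log: list[str] = []
    for key in overrides:
        setter = _CONFIG_KEYS.get(key)
        if setter is None:
            raise ConfigError(f"unknown config key {key!r}")
        try:
            params = setter(params, overrides[key])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid value for {key!r}: {exc}") from exc
        log.append(f"{key}={overrides[key]}")
    return replace(params, provenance=tuple(log))
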