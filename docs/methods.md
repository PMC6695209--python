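# Methods

## Thin-film cascade model

The core of a clot forming on a collagen/TF patch under venous flow is
treated as a well-mixed thin film (δ = 15 μm, porosity 0.5, 250×250 μm
footprint).  The key assumption is separation of transport and reaction:
plasma zymogens (FIX, FX, FXI, prothrombin, fibrinogen) diffuse into the
film fast enough that their intraclot concentrations stay at plasma levels,
so every Michaelis–Menten reaction becomes first order in its enzyme with
rate α = k_cat[S]₀/(K_m+[S]₀).  Where delivery is *not* fast (large
substrates, dense fibrin), an effectiveness factor η = actual/ideal rate
multiplies α: η₄ = 0.18 (prothrombin at prothrombinase), η₅ = 0.05
(fibrinogen, 340 kDa, strongly diffusion-limited), η₆ = 0.36 (FXI at
thrombin).  All other η are 1.

Cofactor generation (FVa, FVIIIa) is taken as non-rate-limiting, so "IXa"
denotes the intrinsic tenase complex FIXa/FVIIIa and "Xa" the
prothrombinase complex FXa/FVa.  Inhibition (TFPI, ATIII, C1-inh,
α₂-macroglobulin lumped) is pseudo-first-order with k_i = ln2/60 s⁻¹ for
the proteases and k_i,TF = ln2/180 s⁻¹ for the TF/FVIIa trigger, which
starts at TF*₀ = 2.2 pM (1 TF molecule/μm² with 1% bound as FVIIa,
homogenized over the pore volume — `surface_density_to_concentration`
reproduces this value from the geometry).  Free thrombin and FXIa elute
with k_elute = ln2/2 s⁻¹, the measured ~2-s escape half-life of albumin
from a clot core and also the diffusion time across ~15 μm.

Thrombin binds fibrin reversibly at two sites, treated as
kinetically-controlled adsorption with diffusion-limited association
(k_f = 100 μM⁻¹s⁻¹ both): the weak E-domain site (K_D = 2.8 μM,
1.6 sites per fibrin monomer) and the strong γ′-chain site (K_D = 0.1 μM,
0.3 sites per monomer).  Site capacity tracks fibrin instantaneously
(θ = stoichiometry × fibrin(t)); no polymerization delay is modelled.

**Interpretation choice (documented prominently):** the thrombin that
drives fibrin generation, FXIa feedback and elution is the *free* pool;
fibrin-bound thrombin is catalytically silent and protected from
inhibition in this model.  Real fibrin-bound thrombin retains some
activity, so scenarios probing bound-thrombin function are outside the
model's scope.  FIXa and FXa do not elute (platelet-surface-bound by
construction); only free IIa and XIa do.

### Effluent observables

The assayable fluxes are J_F1.2 = η₄α₄·Xa·δ (the prothrombin activation
fragment escapes as fast as thrombin is generated) and
J_TAT = 0.7·k_elute·IIa·δ (70% of eluted thrombin is captured by
antithrombin; the remainder by other inhibitors and is not reported
separately).  These use the film thickness δ as printed, although
V_pore/area = δ·porosity = 7.5 μm; an opt-in `porosity_corrected` mode
applies the extra factor of 0.5.  The fibrin mass conversion is anchored
to the plasma equivalence 9 μM ↔ 3 mg/mL (exactly 3 μM per mg/mL).

### Numerics

`scipy.integrate.solve_ivp` with the BDF method, analytic Jacobian,
rtol 1e-8, atol 1e-12 μM.  The binding terms (k_f·θ up to ~10⁴ s⁻¹ at
late-time fibrin levels) make the system stiff.  Non-negativity is
enforced by tolerance plus post-hoc clipping at −1e-9 μM (a hard error
below that).  Halving the tolerances moves all reported observables by
< 0.1%.  One 800-s baseline solve takes well under a second.

Scenario knockouts (α_i = 0) zero the reaction's k_cat so the derived α
stays consistent with its defining formula and η keeps its transport
meaning.  GPRP is modelled as α₅ = 0 by default; the alternative reading
(binding abolished, K_D → 10⁷ μM) is provided, implemented by holding k_r
and deriving k_f = k_r/K_D so the equilibrium is identical without
introducing a 10⁹ s⁻¹ rate.

The two-site equilibrium free fraction (the closed-form oracle used to
validate the kinetic binding) solves
free·(1 + Σ θ_s/(K_D,s + free)) = total by bracketed Brent root-finding;
in the dilute limit it reduces to 1/(1 + θ_E/K_E + θ_γ/K_γ).

## Channel transport model

The companion 2D simulation represents thrombin loading into and elution
from a porous fibrin zone (250×15 μm, leading edge 150 μm from the inlet)
in a 1000×60 μm channel at 200 s⁻¹ wall shear rate.  Thrombin enters as a
prescribed bottom-wall flux J(t) over the clot footprint, advects and
diffuses, and binds the fibrin sites (capacities 1.6 and 0.3 × fibrin(t),
uniform in the zone).  The printed transport equations carry no porosity
factor in the storage term and no inhibition sink, and none is applied.

Because the empirical input series (F1.2-calibrated flux, D-dimer-
calibrated fibrin) are not published, the `fixtures` module generates
stand-ins: either coupled from the thin-film model's own output
(J = η₄α₄·Xa·δ, fibrin from the trajectory) or as parametric saturating
ramps.  Published channel-study values (61 nM free / 5.5 μM total at
500 s, 1.1 h elution half-life) therefore serve only as qualitative-order
references; the quantitative checks are conservation, grid convergence and
the binding-retardation oracle.

Parameters not stated anywhere and chosen once as field-standard values:
thrombin diffusivity D = 60 μm²/s free (Stokes–Einstein scale for a
~36 kDa protein), reduced to 15 μm²/s in the clot by a porosity/tortuosity
factor ε/τ² = 0.25; clot permeability 10⁻³ μm² (platelet-thrombus
literature order, making the clot interior diffusion-dominated).  Both are
configurable.

### Velocity solve

Steady incompressible Stokes flow with a Brinkman drag μ/k inside the clot,
on a staggered MAC grid, assembled as one sparse saddle-point system and
solved directly.  The inlet carries a fully developed parabolic profile
scaled to the requested clean-channel wall shear; the outlet imposes zero
boundary pressure with ∂u/∂x = 0; walls are no-slip with a quadratic ghost
closure (exact for parabolic profiles, so the empty channel reproduces
Poiseuille flow and the set wall shear to machine precision).  Both the
viscous and drag terms scale with μ, so the velocity is independent of the
viscosity value.  The discrete divergence vanishes in every cell to solver
precision.

### Transport solve

Cell-centred finite volumes (x downstream, y up from the bottom wall,
fluxes on faces): conservative first-order upwind advection and central
diffusion with harmonic-mean face diffusivities, advanced by backward
Euler.  The transport operator is constant in time and an M-matrix, so a
single sparse LU factorization serves the whole run and the update is
unconditionally stable and positivity-preserving.  The stiff binding
kinetics are operator-split: each step solves the per-cell backward-Euler
two-site system exactly (the local total is conserved within the split
step, reducing it to one scalar Newton iteration, vectorized over clot
cells).  The default substep is 0.05 s; halving it moves the reported
clot averages by ~0.3%.

The clot is an immersed rectangle: cells partially covered carry
proportional site capacity, Brinkman drag and boundary flux, so the
represented clot has the exact prescribed footprint on every grid.  The
global budget (influx − outlet efflux − storage) closes to round-off by
construction, and is audited on every run.

Problem sizes: the reference channel run uses a 50×30-cell grid (800 s
loading + elution in roughly a minute); the grid-convergence check
compares 100×60 against 200×120 at 500 s (≈ 0.3% change; the 50×30 grid
is ≈ 3% from converged).  Elution half-life studies use a 25×15 grid with
a dilutely pre-loaded, equilibrated clot (`equilibrate_clot`), mirroring
the elution-only channel study; at 90 μM fibrin the measured washout
retardation matches the equilibrium factor 1 + θ_E/K_E + θ_γ/K_γ ≈ 322
within a few percent.

## What the synthetic inputs do and do not represent

The ODE-coupled fixtures reproduce the *shape* of thrombin delivery and
fibrin growth a real clot imposes (sigmoidal rise, late feedback
acceleration) but not the measured magnitudes of any particular
experiment, and the parametric ramps are idealized.  Passing transport
tests therefore demonstrates correct physics (conservation, retardation,
convergence), not agreement with any specific effluent time series.
Platelet deposition, clot growth and moving boundaries, FVIIa generation,
arterial shear and fibrinolysis are out of scope throughout.

## Known limitations and discrepancies

Integrating the eight equations exactly as printed, with the printed
parameter set, reproduces the published *instantaneous* levels —
prothrombinase ≈ 15 nM, free thrombin ≈ 90 nM (≈ 1% free against ≈ 30
before the fibrin excess accumulates), FXIa ≈ 4.5–5 pM — but yields about
2× the published *cumulative* quantities: total thrombin ≈ 36 μM (vs
~18 μM) and fibrin ≈ 191 μM (vs ~90 μM) at 800 s, and intrinsic tenase
≈ 47 pM at 200 s (vs ~30 pM, which matches the TF-driven pathway alone).
An integral-balance argument shows the printed rate set cannot
simultaneously produce the published fibrin, total thrombin and
prothrombinase values, so the discrepancy is inherent to the published
parameterization rather than to this implementation; the affected
acceptance checks are kept at their published values and fail honestly.
The escape-time fold-change (4 s vs 2 s) computes to 2.76 against a
published ">3-fold" under the same conditions.

Other limitations: first-order upwinding makes the coarse channel grids
numerically diffusive (quantified above); the thin-film model has no
spatial resolution inside the core; inhibition kinetics are lumped
first-order; bound thrombin is fully inert.
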