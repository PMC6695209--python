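"""Channel-flow transport: velocity field, conservation, binding retardation."""

import numpy as np
import pytest

from clotfilm import (
    ChannelGeometry,
    TransportParams,
    VelocityField,
    equilibrate_clot,
    run_elution,
    run_loading,
    solve_velocity,
    spatial_averages,
)
from clotfilm.parameters import ParameterValidationError


class TestGeometry:
    def test_clot_must_sit_inside_channel(self):
        with pytest.raises(ParameterValidationError):
            ChannelGeometry(clot_x0=900.0, clot_length=250.0)
        with pytest.raises(ParameterValidationError):
            ChannelGeometry(clot_height=60.0)

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ParameterValidationError, match="coarse"):
            ChannelGeometry(nx=10, ny=8)

    @pytest.mark.parametrize("nx,ny", [(25, 15), (50, 30), (100, 60)])
    def test_clot_fraction_recovers_exact_area(self, nx, ny):
        g = ChannelGeometry(nx=nx, ny=ny)
        area = g.clot_frac.sum() * g.dx * g.dy
        assert area == pytest.approx(250.0 * 15.0, rel=1e-12)


@pytest.fixture(scope="module")
def clean():
    return solve_velocity(ChannelGeometry(), TransportParams(permeability=1e12))


@pytest.fixture(scope="module")
def with_clot():
    return solve_velocity(ChannelGeometry(), TransportParams())


class TestVelocity:
    def test_clean_channel_is_poiseuille(self, clean):
        g = clean.geometry
        y = g.y_centers
        exact = 200.0 / g.height * y * (g.height - y)
        mid = clean.u[g.nx // 2, :]
        assert np.allclose(mid, exact, rtol=1e-8)

    def test_clean_wall_shear_matches_setting(self, clean):
        assert clean.wall_shear(75.0) == pytest.approx(200.0, rel=0.01)

    def test_divergence_free(self, clean, with_clot):
        for vel in (clean, with_clot):
            assert vel.diagnostics["relative_divergence"] < 1e-8

    def test_clot_damps_interior_flow(self, with_clot):
        g = with_clot.geometry
        uc = 0.5 * (with_clot.u[1:, :] + with_clot.u[:-1, :])
        interior = g.clot_frac > 0.999
        assert np.abs(uc[interior]).max() < 0.01 * np.abs(with_clot.u).max()

    def test_impermeable_limit_stops_clot_flow_and_conserves_flux(self):
        g = ChannelGeometry()
        vel = solve_velocity(g, TransportParams(permeability=1e-8))
        uc = 0.5 * (vel.u[1:, :] + vel.u[:-1, :])
        assert np.abs(uc[g.clot_frac > 0.999]).max() < 1e-3
        through = vel.u.sum(axis=1) * g.dy  # volumetric flux per column
        assert np.allclose(through, through[0], rtol=1e-8)


class TestConservation:
    def test_sealed_domain_budget_identity(self):
        """Uniform influx into a quiescent sealed channel with no binding:
        stored mass equals the time integral of the imposed flux."""
        g = ChannelGeometry()
        tp = TransportParams()
        hist = run_loading(g, tp, J=1.0, fibrin=0.0, t_end=50.0,
                           velocity=VelocityField.zero(g))
        assert hist.efflux[-1] == 0.0
        assert hist.stored[-1] == pytest.approx(1.0 * 50.0 * 250.0, rel=1e-9)
        assert hist.budget_closure() < 1e-9

    def test_loading_budget_closes(self, loading_run):
        hist, _ = loading_run
        assert hist.budget_closure() < 0.01

    def test_averages_identity(self, loading_run):
        hist, _ = loading_run
        df = spatial_averages(hist)
        assert np.allclose(df["total_uM"],
                           df["free_uM"] + df["e_bound_uM"] + df["gamma_bound_uM"],
                           atol=1e-9)
        stored_change = df["stored_uM_um2"] - df["stored_uM_um2"].iloc[0]
        net = df["influx_uM_um2"] - df["efflux_uM_um2"]
        denom = max(df["influx_uM_um2"].iloc[-1], 1.0)
        assert np.abs(stored_change - net).max() / denom < 0.01


class TestLoading:
    def test_no_flux_stays_empty(self):
        g = ChannelGeometry(nx=25, ny=15)
        hist = run_loading(g, TransportParams(), J=0.0, fibrin=90.0, t_end=5.0)
        assert hist.stored[-1] == 0.0
        assert np.all(hist.clot_total == 0.0)

    def test_bound_dominates_and_caps_respected(self, loading_run, ode_series,
                                                tparams, channel):
        hist, _ = loading_run
        _, fib = ode_series
        i500 = np.searchsorted(hist.times, 500.0)
        free_frac = hist.clot_free[i500] / hist.clot_total[i500]
        assert free_frac < 0.05           # bound ≫ free
        assert free_frac > 1e-4           # ~1% order
        fib_end = float(fib(800.0))
        caps_e = tparams.sites[0].sites_per_monomer * fib_end * channel.clot_frac
        caps_g = tparams.sites[1].sites_per_monomer * fib_end * channel.clot_frac
        assert np.all(hist.final.es <= caps_e + 1e-9)
        assert np.all(hist.final.gs <= caps_g + 1e-9)

    def test_boundary_layer_scaling_without_binding(self):
        """With no binding or drag, the quasi-steady wall concentration under
        a constant wall flux grows downstream like x^(1/3) (Lévêque/Graetz
        boundary-layer behaviour in shear flow)."""
        g = ChannelGeometry(nx=100, ny=60)
        tp = TransportParams(permeability=1e12, D_clot=60.0)
        hist = run_loading(g, tp, J=1.0, fibrin=0.0, t_end=40.0)
        c_wall = hist.final.c[:, 0]
        cols = np.nonzero(g.clot_bottom_frac > 0.999)[0][2:]  # skip leading edge
        x_rel = g.x_centers[cols] - 150.0
        slope = np.polyfit(np.log(x_rel), np.log(c_wall[cols]), 1)[0]
        assert slope == pytest.approx(1.0 / 3.0, abs=0.0667)  # within 20%


class TestElution:
    def test_site_free_washout_is_fast(self, washout_halflives):
        assert washout_halflives[0.0] < 60.0

    def test_halflife_monotone_in_fibrin(self, washout_halflives):
        hls = [washout_halflives[f] for f in (0.0, 9.0, 30.0, 90.0)]
        assert hls[0] < hls[1] < hls[2] < hls[3]

    def test_retardation_matches_equilibrium_factor(self, washout_halflives,
                                                    tparams):
        """Binding retards washout by ≈ (1 + θ_E/K_E + θ_γ/K_γ)."""
        R = 1.0 + 1.6 * 90 / 2.8 + 0.3 * 90 / 0.1
        ratio = washout_halflives[90.0] / washout_halflives[0.0]
        assert R / 2 < ratio < R * 2

    def test_fast_kinetics_reach_local_equilibrium_limit(self, tparams):
        """Scaling both binding rates ×10 at fixed K_D barely changes the
        half-life: the default kinetics already track local equilibrium."""
        geom = ChannelGeometry(nx=25, ny=15)
        fast = TransportParams(sites=tuple(
            s.with_overrides(kf=s.kf * 10) for s in tparams.sites))
        hls = {}
        for tp in (tparams, fast):
            state = equilibrate_clot(geom, tp, fibrin=9.0, total_clot_avg=0.01)
            res = run_elution(state, tp, t_end=2000.0, geometry=geom,
                              fibrin=9.0, stop_when_halved=True)
            hls[tp.sites[0].kf] = res.half_life.halflife
        assert hls[1000.0] == pytest.approx(hls[100.0], rel=0.05)

    def test_requires_fibrin_when_bound_present(self, tparams):
        geom = ChannelGeometry(nx=25, ny=15)
        state = equilibrate_clot(geom, tparams, fibrin=9.0, total_clot_avg=0.01)
        with pytest.raises(ValueError, match="fibrin"):
            run_elution(state, tparams, t_end=10.0, geometry=geom)

    def test_elution_decreases_clot_load(self, elution_after_loading):
        res, _ = elution_after_loading
        assert res.history.clot_total[-1] < res.history.clot_total[0]
        assert res.history.budget_closure() < 0.01
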