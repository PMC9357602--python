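"""Method-of-lines delay simulator: operators, history, integration."""

import math

import numpy as np
import pytest

from turingdelay.dde_simulator import (
    Grid,
    History,
    SimulationResult,
    apply_banded,
    build_laplacian,
    delayed_term,
    simulate,
)
from turingdelay.delay_kernels import KernelSpec, kernel_laplace
from turingdelay.reaction_models import (
    Kinetics,
    ModelSpec,
    delayed_reactants,
    steady_state,
)


def _steady_fields(model, m):
    us, vs = steady_state(model)
    return np.full(m, us), np.full(m, vs)


class TestLaplacian:
    def test_constant_field_annihilated(self):
        g = Grid(50)
        lu, lv = build_laplacian(g)
        f = np.full(g.m, 3.7)
        assert np.max(np.abs(apply_banded(lu, f))) == 0.0
        assert np.max(np.abs(apply_banded(lv, f))) == 0.0

    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_cosine_eigenfunctions_neumann(self, k):
        g = Grid(80)
        lu, _ = build_laplacian(g)
        f = np.cos(k * np.pi * g.x)
        ev = -(2.0 / g.dx ** 2) * (1.0 - math.cos(k * math.pi * g.dx))
        got = apply_banded(lu, f) / g.dx ** 2
        np.testing.assert_allclose(got, ev * f, atol=1e-9 * abs(ev) + 1e-9)

    def test_mixed_bc_dirichlet_rows(self):
        g = Grid(50)
        lu, lv = build_laplacian(g, "dirichlet_u_neumann_v")
        f = np.sin(np.pi * g.x)          # vanishes at both boundaries
        got = apply_banded(lu, f)[1:-1] / g.dx ** 2
        np.testing.assert_allclose(got, -np.pi ** 2 * f[1:-1], rtol=2e-3)
        # inhibitor operator unchanged (still Neumann)
        assert np.max(np.abs(apply_banded(lv, np.full(g.m, 1.0)))) == 0.0

    def test_unknown_bc_rejected(self):
        with pytest.raises(ValueError):
            build_laplacian(Grid(10), "periodic")


class TestHistory:
    def test_constant_history_returns_ic(self):
        u0 = np.array([1.0, 2.0, 3.0])
        v0 = np.array([0.5, 0.6, 0.7])
        h = History.constant(u0, v0, t_back=2.0)
        for t in (-2.0, -1.3, 0.0):
            u, v = h(t)
            np.testing.assert_array_equal(u, u0)
            np.testing.assert_array_equal(v, v0)

    def test_query_outside_interval_raises(self):
        h = History.constant(np.ones(3), np.ones(3), t_back=1.0)
        with pytest.raises(ValueError, match="outside"):
            h(-2.0)
        with pytest.raises(ValueError, match="outside"):
            h(0.5)

    def test_cubic_interpolation_of_smooth_signal(self):
        # knots of exp(t) with exact slopes: cubic Hermite is O(h^4)
        t = np.linspace(-1.0, 0.0, 21)
        vals = np.exp(t)[:, None] * np.ones((1, 3))
        h = History(t, vals, vals, du=vals, dv=vals)
        for tq in (-0.525, -0.11, -0.99):
            u, _ = h(tq)
            assert u[0] == pytest.approx(math.exp(tq), abs=1e-7)


class TestDelayedTerm:
    def test_steady_history_reproduces_steady_reactants(self, li_model,
                                                        gm1_model):
        for model in (li_model, gm1_model):
            us, vs = steady_state(model)
            h = History.constant(np.full(5, us), np.full(5, vs), t_back=3.0)
            F, G = delayed_reactants(model)
            for kern in (KernelSpec.dirac(1.0), KernelSpec.gaussian(1.0, 0.3),
                         KernelSpec.skew(1.0, 0.3, 10.0)):
                Fv, Gv = delayed_term(h, kern, 0.0, model)
                np.testing.assert_allclose(Fv, F(us, vs), rtol=1e-12)
                if G is not None:
                    np.testing.assert_allclose(Gv, G(us, vs), rtol=1e-12)

    def test_dirac_lookup_on_exponential_history(self, li_model):
        # u(t) = e^(mu t), v constant 1; LI reactant F = u^2 v
        mu = 0.8
        t = np.linspace(-3.0, 0.0, 301)
        u = np.exp(mu * t)[:, None] * np.ones((1, 2))
        du = mu * u
        h = History(t, u, np.ones_like(u), du=du, dv=np.zeros_like(u))
        Fv, _ = delayed_term(h, KernelSpec.dirac(1.0), 0.0, li_model)
        assert Fv[0] == pytest.approx(math.exp(-2.0 * mu), rel=1e-8)

    def test_distributed_average_matches_kernel_transform(self, li_model):
        """On an exponential history the delay average is E(lam) exactly."""
        mu = 0.8
        t = np.linspace(-3.0, 0.0, 601)
        u = np.exp(0.5 * mu * t)[:, None] * np.ones((1, 2))  # u^2 v = e^(mu t)
        du = 0.5 * mu * u
        h = History(t, u, np.ones_like(u), du=du, dv=np.zeros_like(u))
        kern = KernelSpec.gaussian(1.0, 0.25)
        Fv, _ = delayed_term(h, kern, 0.0, li_model)
        assert Fv[0] == pytest.approx(kernel_laplace(kern, mu).real, abs=1e-6)


class TestSimulate:
    KERNELS = [KernelSpec.dirac(0.5), KernelSpec.gaussian(0.5, 0.15)]

    @pytest.mark.parametrize("kin,ab", [
        (Kinetics.LI, (0.1, 0.9)), (Kinetics.GM1, (0.75, 0.5)),
        (Kinetics.GM2, (0.75, 0.5)),
    ])
    @pytest.mark.parametrize("bc", ["neumann_neumann"])
    def test_steady_state_preserved(self, kin, ab, bc):
        model = ModelSpec(kin, *ab)
        us, vs = steady_state(model)
        for kern in self.KERNELS:
            u0, v0 = _steady_fields(model, 64)
            sim = simulate(model, kern, u0, v0, t_end=1.0, dt=1e-3, bc=bc)
            assert np.max(np.abs(sim.u - us)) < 1e-10
            assert np.max(np.abs(sim.v - vs)) < 1e-10

    def test_skew_kernel_preserves_steady_state(self, li_model):
        u0, v0 = _steady_fields(li_model, 64)
        sim = simulate(li_model, KernelSpec.skew(0.5, 0.15, -10.0), u0, v0,
                       t_end=1.0, dt=1e-3)
        assert np.max(np.abs(sim.u - steady_state(li_model)[0])) < 1e-10

    def test_mixed_bc_keeps_activator_clamped(self, li_model):
        us, vs = steady_state(li_model)
        m = 64
        rng = np.random.default_rng(0)
        u0 = us * (1 + 0.01 * rng.standard_normal(m))
        v0 = vs * (1 + 0.01 * rng.standard_normal(m))
        sim = simulate(li_model, KernelSpec.dirac(0.5), u0, v0, t_end=0.5,
                       dt=1e-3, bc="dirichlet_u_neumann_v")
        assert np.max(np.abs(sim.u[1:, 0])) == 0.0
        assert np.max(np.abs(sim.u[1:, -1])) == 0.0

    def test_neumann_mass_conserved_without_reaction(self, li_model):
        m = 100
        x = np.linspace(0, 1, m)
        u0 = 1.0 + 0.3 * np.cos(3 * np.pi * x)
        v0 = 1.0 + 0.1 * np.cos(np.pi * x)
        sim = simulate(li_model, KernelSpec.dirac(0.5), u0, v0, t_end=1.0,
                       dt=1e-3, reaction=False)
        w = np.ones(m)
        w[0] = w[-1] = 0.5        # trapezoid mass of the Neumann stencil
        for f0, f1 in ((sim.u[0], sim.u[-1]), (sim.v[0], sim.v[-1])):
            assert abs(np.dot(w, f1) - np.dot(w, f0)) < 1e-10

    def test_dominant_mode_growth_matches_linear_theory(self):
        """Small-domain regime: simulated mode growth within 5% of Re(lam_k)."""
        from scipy.fft import dct

        from turingdelay.linear_stability import max_growth_rate

        model = ModelSpec(Kinetics.LI, 0.4, 1.8, eps2=0.001, L2=0.2)
        kern = KernelSpec.dirac(0.2)
        disp = max_growth_rate(model, kern, k_max=30)
        us, vs = steady_state(model)
        m = 200
        rng = np.random.default_rng(7)
        u0 = us * (1 + 1e-5 * rng.standard_normal(m))
        v0 = vs * (1 + 1e-5 * rng.standard_normal(m))
        sim = simulate(model, kern, u0, v0, t_end=6.0, dt=1e-3, out_dt=0.2)
        amps = np.array([abs((dct(sim.u[i] - us, type=1) / (m - 1))[disp.argmax_k])
                         for i in range(len(sim.t))])
        slope = np.polyfit(sim.t[5:], np.log(amps[5:]), 1)[0]
        assert slope == pytest.approx(disp.max_re, rel=0.05)

    def test_grid_and_step_convergence(self, li_model):
        """Halving dt and doubling m changes the field by < 1% (max norm)."""
        us, vs = steady_state(li_model)
        rng = np.random.default_rng(3)
        coarse_noise = rng.standard_normal(101)

        def run(m, dt):
            x = np.linspace(0, 1, m)
            noise = np.interp(x, np.linspace(0, 1, 101), coarse_noise)
            u0 = us * (1 + 0.01 * noise)
            v0 = vs * (1 + 0.01 * noise[::-1])
            return simulate(li_model, KernelSpec.dirac(1.0), u0, v0,
                            t_end=20.0, dt=dt, out_dt=20.0)

        ref = run(100, 1e-3)
        fine = run(200, 5e-4)
        scale = np.max(np.abs(ref.u[-1] - us))
        diff = np.max(np.abs(fine.u[-1][::2] - ref.u[-1]))
        assert diff < 0.01 * max(scale, 1.0)

    def test_blowup_detected(self):
        # strongly negative inhibitor makes GM kinetics explode
        model = ModelSpec(Kinetics.GM2, 0.75, 0.5)
        m = 32
        u0 = np.full(m, 1e5)
        v0 = np.full(m, 1e-6)
        with pytest.raises(RuntimeError, match="blew up"):
            simulate(model, KernelSpec.dirac(0.1), u0, v0, t_end=5.0,
                     dt=1e-2)

    def test_early_stop_at_threshold(self, li_model):
        us, vs = steady_state(li_model)
        rng = np.random.default_rng(5)
        m = 100
        u0 = us * (1 + 0.01 * rng.standard_normal(m))
        v0 = vs * (1 + 0.01 * rng.standard_normal(m))
        sim = simulate(li_model, KernelSpec.dirac(0.5), u0, v0, t_end=500.0,
                       dt=1e-3, out_dt=0.25, stop_threshold=0.1)
        assert sim.stopped_at_threshold
        assert sim.t[-1] < 500.0
        assert np.max(np.abs(sim.u[-1] - us)) > 0.1

    def test_hdf5_round_trip(self, li_model, tmp_path):
        u0, v0 = _steady_fields(li_model, 32)
        sim = simulate(li_model, KernelSpec.dirac(0.2), u0, v0, t_end=0.2,
                       dt=1e-3, seed=11)
        path = str(tmp_path / "sim.h5")
        sim.to_hdf5(path)
        back = SimulationResult.from_hdf5(path)
        np.testing.assert_array_equal(back.u, sim.u)
        assert back.meta["seed"] == 11
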