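"""Transcendental dispersion solver: roots, scans, discrepancy statistics."""

import numpy as np
import pytest

from turingdelay.delay_kernels import KernelSpec
from turingdelay.linear_stability import (
    characteristic_residual,
    contour_points,
    distributed_vs_fixed_discrepancy,
    hausdorff_distance,
    max_growth_rate,
    rightmost_root,
    skew_growth_curve,
    turing_space_scan,
)
from turingdelay.reaction_models import (
    Kinetics,
    ModelSpec,
    dispersion_coefficients,
)


def _quadratic_rightmost(model, k):
    """Zero-delay oracle: explicit quadratic formula, larger real part."""
    c = dispersion_coefficients(model, k)
    roots = np.roots([1.0, c.alpha + c.gamma, c.beta + c.delta + c.chi])
    return roots[np.argmax(roots.real)]


SAMPLERS = [
    (Kinetics.LI, lambda r: (r.uniform(0.0, 1.4), r.uniform(0.05, 2.0))),
    (Kinetics.GM1, lambda r: (r.uniform(0.0, 1.0), r.uniform(0.1, 4.0))),
    (Kinetics.GM2, lambda r: (r.uniform(0.0, 1.0), r.uniform(0.1, 4.0))),
]


class TestZeroDelayOracle:
    @pytest.mark.parametrize("kin,sampler", SAMPLERS)
    def test_rightmost_root_matches_quadratic(self, kin, sampler, rng):
        """200 random (a, b, k) per model against the quadratic formula."""
        checked = 0
        while checked < 200:
            a, b = sampler(rng)
            try:
                m = ModelSpec(kin, a, b)
            except ValueError:
                continue
            k = int(rng.integers(0, 51))
            oracle = _quadratic_rightmost(m, k)
            if oracle.real < -20:        # outside the solver's search window
                continue
            lam, res = rightmost_root(m, KernelSpec.dirac(0.0), k)
            assert lam.real == pytest.approx(oracle.real, abs=1e-10)
            assert abs(lam.imag) == pytest.approx(abs(oracle.imag), abs=1e-10)
            checked += 1

    def test_zero_delay_residual_is_explicit_quadratic(self, li_model):
        lam = 0.3 + 0.7j
        c = dispersion_coefficients(li_model, 10)
        expect = (lam * lam + (c.alpha + c.gamma) * lam
                  + (c.beta + c.delta + c.chi))
        got = characteristic_residual(li_model, KernelSpec.dirac(0.0), 10, lam)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_quadratic_roots_annihilate_residual(self, li_model):
        m = ModelSpec(Kinetics.LI, 0.1, 0.9)
        c = dispersion_coefficients(m, 10)
        for root in np.roots([1.0, c.alpha + c.gamma,
                              c.beta + c.delta + c.chi]):
            res = characteristic_residual(m, KernelSpec.dirac(0.0), 10, root)
            assert abs(res) < 1e-10


class TestRightmostRoot:
    def test_reported_root_satisfies_residual_invariant(self, li_model):
        for kern in (KernelSpec.dirac(1.0), KernelSpec.gaussian(1.0, 0.3)):
            for k in (0, 4, 9):
                lam, res = rightmost_root(li_model, kern, k)
                assert res < 1e-8
                assert abs(characteristic_residual(li_model, kern, k, lam)) \
                    < 1e-7

    def test_continuity_in_delay(self, li_model):
        """The k=0 root is continuous along the delay continuation path."""
        taus = np.arange(0.0, 1.01, 0.05)
        roots = [rightmost_root(li_model, KernelSpec.dirac(t), 0)[0]
                 for t in taus]
        re = np.array([r.real for r in roots])
        steps = np.abs(np.diff(re))
        # no jumps an order of magnitude above the local secant scale
        for s1, s2 in zip(steps[:-1], steps[1:]):
            assert s2 < 10 * s1 + 1e-6

    def test_stable_point_stays_stable_under_small_delay(self):
        # Routh-Hurwitz stable at tau = 0 and continued to small delay
        m = ModelSpec(Kinetics.LI, 1.4, 0.1)
        c = dispersion_coefficients(m, 3)
        assert c.alpha + c.gamma > 0 and c.beta + c.delta + c.chi > 0
        lam, _ = rightmost_root(m, KernelSpec.dirac(0.1), 3)
        assert lam.real < 0


class TestMaxGrowthRate:
    def test_turing_unstable_point(self, li_model):
        d = max_growth_rate(li_model, KernelSpec.dirac(0.0))
        assert d.max_re > 0
        assert d.argmax_k != 0
        # verified against the quadratic oracle over every k
        oracle = max(range(51),
                     key=lambda k: _quadratic_rightmost(li_model, k).real)
        assert d.argmax_k == oracle

    def test_stable_point(self):
        d = max_growth_rate(ModelSpec(Kinetics.LI, 1.4, 0.1),
                            KernelSpec.dirac(0.0))
        assert d.max_re < 0

    def test_delay_reduces_growth_magnitude(self, li_model):
        d0 = max_growth_rate(li_model, KernelSpec.dirac(0.0))
        d1 = max_growth_rate(li_model, KernelSpec.dirac(1.0))
        assert 0 < d1.max_re < d0.max_re

    def test_residuals_of_reported_roots(self, li_model):
        d = max_growth_rate(li_model, KernelSpec.gaussian(1.0, 0.99 / 3))
        finite = np.isfinite(d.lam)
        assert finite.any()
        assert np.all(d.residual[finite] < 1e-8)


class TestTuringScan:
    A_GRID = np.linspace(0.0, 1.4, 15)
    B_GRID = np.linspace(0.0, 2.0, 21)

    def test_turing_region_signs(self, li_model):
        scan = turing_space_scan(li_model, KernelSpec.dirac(0.0),
                                 self.A_GRID, self.B_GRID, k_max=30)
        mask = scan.turing_mask
        assert mask.any()
        assert np.all(scan.re_lambda0[mask] < 0)
        assert np.all(scan.max_re_nonzero[mask] > 0)

    def test_li_inhomogeneous_contour_tau_invariant(self):
        """The k != 0 marginal line of the LI model does not move with tau.

        At a marginal inhomogeneous mode the root is real and zero, where
        the kernel transform is identically one, so the contour is exactly
        delay-independent; grids only add interpolation error.
        """
        m = ModelSpec(Kinetics.LI, 0.1, 0.9)
        cell = max(self.A_GRID[1] - self.A_GRID[0],
                   self.B_GRID[1] - self.B_GRID[0])
        contours = []
        for tau in (0.0, 0.5, 1.5):
            scan = turing_space_scan(m, KernelSpec.dirac(tau),
                                     self.A_GRID, self.B_GRID, k_max=30)
            contours.append(scan.contour_inhomogeneous)
        for other in contours[1:]:
            assert hausdorff_distance(contours[0], other) < cell

    def test_gm1_turing_space_shrinks_with_delay(self):
        m = ModelSpec(Kinetics.GM1, 0.5, 1.0)
        ag = np.linspace(0.0, 1.0, 11)
        bg = np.linspace(0.1, 4.0, 14)
        n0 = turing_space_scan(m, KernelSpec.dirac(0.0), ag, bg,
                               k_max=30).turing_cell_count()
        n1 = turing_space_scan(m, KernelSpec.dirac(0.3), ag, bg,
                               k_max=30).turing_cell_count()
        assert n1 < n0

    def test_gm2_turing_space_grows_with_delay(self):
        m = ModelSpec(Kinetics.GM2, 0.5, 1.0)
        ag = np.linspace(0.0, 1.0, 11)
        bg = np.linspace(0.1, 4.0, 14)
        n0 = turing_space_scan(m, KernelSpec.dirac(0.0), ag, bg,
                               k_max=30).turing_cell_count()
        n1 = turing_space_scan(m, KernelSpec.dirac(0.3), ag, bg,
                               k_max=30).turing_cell_count()
        assert n1 > n0

    def test_contour_extraction_linear_field(self):
        ag = np.linspace(0, 1, 11)
        bg = np.linspace(0, 1, 11)
        A, B = np.meshgrid(ag, bg, indexing="ij")
        pts = contour_points(ag, bg, A - 0.35)     # vertical line a = 0.35
        assert len(pts) > 0
        np.testing.assert_allclose(pts[:, 0], 0.35, atol=1e-12)


class TestDiscrepancy:
    def test_narrow_kernel_limit(self, li_model):
        out = distributed_vs_fixed_discrepancy(
            li_model, 0.2, [0.02], grid_shape=(5, 7), k_max=20)
        assert out[0.02] < 5e-6

    def test_monotone_in_sigma_fraction(self, li_model):
        out = distributed_vs_fixed_discrepancy(
            li_model, 0.2, [0.99, 0.2, 0.1], grid_shape=(8, 11), k_max=30)
        assert out[0.99] > out[0.2] > out[0.1]

    def test_invalid_fraction_rejected(self, li_model):
        with pytest.raises(ValueError):
            distributed_vs_fixed_discrepancy(li_model, 0.2, [1.5])


class TestSkewGrowthCurve:
    TAUS = np.array([0.0, 0.2, 0.4])

    def test_rho_zero_equals_symmetric(self, li_model):
        sym = skew_growth_curve(li_model, 0.0, 0.99, self.TAUS, k_max=20)
        for i, tau in enumerate(self.TAUS):
            kern = (KernelSpec.dirac(0.0) if tau == 0
                    else KernelSpec.gaussian(tau, 0.99 * tau / 3))
            ref = max_growth_rate(li_model, kern, k_max=20).max_re
            assert sym[i] == pytest.approx(ref, abs=1e-9)

    def test_zero_delay_endpoint_shared(self, li_model):
        ref = max_growth_rate(li_model, KernelSpec.dirac(0.0),
                              k_max=20).max_re
        for rho in (-10.0, 0.0, 10.0):
            cur = skew_growth_curve(li_model, rho, 0.99,
                                    np.array([0.0, 0.1]), k_max=20)
            assert cur[0] == pytest.approx(ref, abs=1e-12)

    def test_skew_sign_ordering_and_closeness_at_small_tau(self, li_model):
        """Negative skew gives the slightly higher growth rate, positive
        skew the slightly lower one, and both stay near the fixed-delay
        value on the unit scale of the growth rate."""
        tau = np.array([0.2])
        fixed = max_growth_rate(li_model, KernelSpec.dirac(0.2),
                                k_max=20).max_re
        hi = skew_growth_curve(li_model, -10.0, 0.99, tau, k_max=20)[0]
        lo = skew_growth_curve(li_model, 10.0, 0.99, tau, k_max=20)[0]
        assert lo < hi
        assert abs(hi - fixed) < 0.05 and abs(lo - fixed) < 0.05
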