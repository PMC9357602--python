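"""Linear stability of delayed reaction-diffusion systems.

Perturbations ``exp(lam_k t) cos(k pi x)`` of the homogeneous steady state
grow or decay according to the transcendental characteristic equation

    D_k(lam) = lam^2 + alpha_k lam + beta_k
               + (gamma_k lam + delta_k) E(lam) + chi_k E(lam)^2 = 0,

where ``E(lam)`` is the delay kernel's Laplace-type transform.  With zero
delay ``E = 1`` and ``D_k`` is an explicit quadratic; for nonzero delay the
rightmost root is tracked by homotopy continuation in the delay: the kernel's
time-like parameters are scaled from 0 to their nominal values in increments
of at most ``cont_step`` (default 0.05) and both quadratic branches are
Newton-corrected at each leg, with step-halving on failure.  A real-axis scan
for sign changes of the (real-valued) ``D_k`` supplements the continued
branches with real roots born away from them; the rightmost candidate is
reported together with its residual ``|D_k|``.

A Turing instability at parameters ``(a, b)`` requires ``Re(lam_0) < 0``
(stable homogeneous mode) together with ``max_{k != 0} Re(lam_k) > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .delay_kernels import KernelSpec, kernel_mean, laplace_nodes
from .reaction_models import (
    Kinetics,
    ModelSpec,
    dispersion_coefficient_arrays,
    dispersion_coefficients,
)

__all__ = [
    "DispersionResult",
    "TuringScan",
    "characteristic_residual",
    "rightmost_root",
    "max_growth_rate",
    "turing_space_scan",
    "distributed_vs_fixed_discrepancy",
    "skew_growth_curve",
    "contour_points",
    "hausdorff_distance",
]

# residual acceptance threshold (absolute, relative to coefficient scale)
_RESIDUAL_TOL = 1e-8

# roots left of this line are abandoned: strongly damped modes are irrelevant
# to the rightmost root, and their continued branches diverge to Re -> -inf
# once delay switches on (the quasi-polynomial roots do not persist).
_RE_FLOOR = -25.0


class _Transform:
    """Vectorized kernel transform ``E(lam)`` and its derivative.

    Point masses use the exact ``exp(-lam tau)``; continuous kernels a fixed
    Gauss-Legendre rule (near machine precision for these smooth, compactly
    supported integrands), with weights normalized so ``E(0) = 1`` exactly.
    """

    def __init__(self, kernel: KernelSpec, num_nodes: int = 32):
        self.kernel = kernel
        if kernel.is_pointmass:
            self.tau = kernel.tau
            self.s = None
        else:
            self.s, self.w = laplace_nodes(kernel, "legendre", num_nodes)

    def E(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam)
        if self.s is None:
            return np.exp(-lam * self.tau)
        ex = np.exp(-np.multiply.outer(lam, self.s))
        return ex @ self.w

    def E_dE(self, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lam = np.asarray(lam)
        if self.s is None:
            e = np.exp(-lam * self.tau)
            return e, -self.tau * e
        ex = np.exp(-np.multiply.outer(lam, self.s))
        return ex @ self.w, -(ex @ (self.w * self.s))


def _char_poly(lam, coeffs, E):
    al, be, ga, de, ch = coeffs
    return lam * lam + al * lam + be + (ga * lam + de) * E + ch * E * E


def _char_deriv(lam, coeffs, E, dE):
    al, _, ga, de, ch = coeffs
    return 2.0 * lam + al + ga * E + (ga * lam + de) * dE + 2.0 * ch * E * dE


def characteristic_residual(model: ModelSpec, kernel: KernelSpec, k: int,
                            lam: complex) -> complex:
    """Evaluate ``D_k(lam)`` (zero at a dispersion root)."""
    c = dispersion_coefficients(model, k)
    tr = _Transform(kernel)
    coeffs = (c.alpha, c.beta, c.gamma, c.delta, c.chi)
    return complex(_char_poly(np.complex128(lam), coeffs, tr.E(np.complex128(lam))))


# ---------------------------------------------------------------------------
# root tracking (vectorized over parameter points)
# ---------------------------------------------------------------------------

def _coeff_scale(coeffs):
    al, be, ga, de, ch = coeffs
    return np.maximum(1.0, np.abs(al) + np.abs(be) + np.abs(ga)
                      + np.abs(de) + np.abs(ch))


def _quadratic_roots(coeffs):
    """Roots of the zero-delay quadratic ``lam^2 + (a+g) lam + (b+d+c)``."""
    al, be, ga, de, ch = coeffs
    A = (al + ga).astype(complex)
    B = (be + de + ch).astype(complex)
    sq = np.sqrt(A * A - 4.0 * B)
    return 0.5 * (-A + sq), 0.5 * (-A - sq)


def _newton(lam, coeffs, transform, tol, max_iter=100):
    """Damped complex Newton on ``D``; returns (lam, done mask).

    Operates on the active subset only.  Points with NaN coefficients, NaN
    iterates, or iterates abandoned below ``_RE_FLOOR`` are marked NaN and
    count as done (a deliberately dropped branch); points still above
    tolerance after ``max_iter`` are returned with done = False.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=complex)).copy()
    scale = _coeff_scale(coeffs) * np.ones(lam.shape)
    tol_arr = tol * scale
    lam[lam.real < _RE_FLOOR] = np.nan
    done = ~(np.isfinite(scale) & np.isfinite(lam))
    lam[done] = np.nan
    idx = np.nonzero(~done)[0]
    cs = [np.asarray(c) * np.ones(lam.shape) for c in coeffs]
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(max_iter):
            if idx.size == 0:
                break
            sub = tuple(c[idx] for c in cs)
            l = lam[idx]
            E, dE = transform.E_dE(l)
            D = _char_poly(l, sub, E)
            absD = np.abs(D)
            drop = ~np.isfinite(D)
            conv = ~drop & (absD <= tol_arr[idx])
            if drop.any():
                lam[idx[drop]] = np.nan
                done[idx[drop]] = True
            if conv.any():
                done[idx[conv]] = True
            keep = ~(drop | conv)
            idx = idx[keep]
            if idx.size == 0:
                break
            l, E, dE, D, absD = l[keep], E[keep], dE[keep], D[keep], absD[keep]
            sub = tuple(c[keep] for c in sub)
            dD = _char_deriv(l, sub, E, dE)
            dD = np.where(dD == 0, 1e-30, dD)
            step = D / dD
            new_l = l - step
            for _ in range(8):  # step-halving safeguard
                E2, _ = transform.E_dE(new_l)
                newD = _char_poly(new_l, sub, E2)
                worse = np.isfinite(newD) & (np.abs(newD) > absD)
                if not worse.any():
                    break
                step = np.where(worse, 0.5 * step, step)
                new_l = l - step
            sunk = new_l.real < _RE_FLOOR
            if sunk.any():
                lam[idx[sunk]] = np.nan
                done[idx[sunk]] = True
            lam[idx] = np.where(sunk, np.nan, new_l)
            idx = idx[~sunk]
    return lam, done


# imaginary kicks applied to stalled iterates: two real roots that collide
# during continuation re-emerge as a complex pair that a (numerically) real
# Newton iterate cannot reach, so failed points are retried off-axis
_IM_KICKS = (1e-6, 1e-3, 0.05, 0.3)


def _newton_kicked(lam, sign, coeffs, transform, tol):
    res, ok = _newton(lam, coeffs, transform, tol)
    for kick in _IM_KICKS:
        if ok.all():
            break
        seed = np.where(ok, res, lam + sign * 1j * kick)
        res2, ok2 = _newton(seed, coeffs, transform, tol)
        res = np.where(ok, res, res2)
        ok = ok | ok2
    return res, ok


def _advance_leg(branches, coeffs, kernel, f_from, f_to, num_nodes, tol,
                 depth=3):
    """Continue all root branches from kernel scale ``f_from`` to ``f_to``,
    retrying stalled points off-axis and halving the leg as a last resort."""
    tr = _Transform(kernel.scaled(f_to), num_nodes)
    out = [_newton_kicked(lam, sgn, coeffs, tr, tol)
           for sgn, lam in zip((1.0, -1.0), branches)]
    if depth <= 0 or all(ok.all() for _, ok in out):
        return out
    mid = 0.5 * (f_from + f_to)
    half = _advance_leg(branches, coeffs, kernel, f_from, mid, num_nodes,
                        tol, depth - 1)
    return _advance_leg([lam for lam, _ in half], coeffs, kernel, mid, f_to,
                        num_nodes, tol, depth - 1)


def _continued_roots(coeffs, kernel, num_nodes=32, cont_step=0.05,
                     tol=1e-12):
    r1, r2 = _quadratic_roots(coeffs)
    mean = kernel_mean(kernel)
    if mean == 0.0:
        return r1, r2
    r1 = np.where(r1.real < _RE_FLOOR, np.nan + 0j, r1)
    r2 = np.where(r2.real < _RE_FLOOR, np.nan + 0j, r2)
    # seed the branches marginally off the real axis: roots that collide on
    # the axis during continuation re-emerge as a complex pair, which a
    # purely real Newton iterate could never reach
    r1 = r1 + 1e-9j
    r2 = r2 - 1e-9j
    nlegs = max(1, int(math.ceil(mean / cont_step)))
    fracs = np.linspace(0.0, 1.0, nlegs + 1)
    for f_from, f_to in zip(fracs[:-1], fracs[1:]):
        (n1, ok1), (n2, ok2) = _advance_leg([r1, r2], coeffs, kernel,
                                            f_from, f_to, num_nodes, tol)
        # a branch that cannot be continued (typically a strongly damped
        # root departing leftward, or a collision) falls back to its
        # sibling's verified finite iterate; conjugate/collided pairs
        # share Re.  A deliberately dropped (NaN) sibling is no rescue.
        fin1 = ok1 & np.isfinite(n1)
        fin2 = ok2 & np.isfinite(n2)
        r1 = np.where(ok1, n1, np.where(fin2, n2, np.nan + 0j))
        r2 = np.where(ok2, n2, np.where(fin1, n1, np.nan + 0j))
    return r1, r2


def _real_E_grid(kernel, grid, num_nodes):
    """``E`` on a real ``lam`` grid (independent of model and wavenumber)."""
    if kernel.is_pointmass:
        return np.exp(-grid * kernel.tau)
    s, w = laplace_nodes(kernel, "legendre", num_nodes)
    return np.exp(-np.multiply.outer(grid, s)) @ w


def _real_axis_roots(coeffs, kernel, num_nodes=32, lo=-20.0, hi=20.0,
                     step=0.05, refine_iter=48, _E_grid_cache=None):
    """Rightmost real-axis sign change of ``D`` per parameter point.

    ``D`` is real-valued on the real axis; the scan brackets its rightmost
    sign change on a uniform grid and refines it by bisection.  Returns a
    complex array with NaN where no sign change lies in the window.
    """
    grid = np.arange(lo, hi + 0.5 * step, step)
    cs = [np.atleast_1d(np.asarray(c, float)).ravel() for c in coeffs]
    P = cs[1].shape[0]
    with np.errstate(over="ignore", invalid="ignore"):
        Eg = (_E_grid_cache if _E_grid_cache is not None
              else _real_E_grid(kernel, grid, num_nodes))
        b_lo = np.full(P, np.nan)
        b_hi = np.full(P, np.nan)
        d_lo = np.full(P, np.nan)
        # chunk the (lam, point) product to bound memory
        chunk = max(2, int(4e6 // max(P, 1)))
        start = 0
        D_edge = None
        while start < len(grid) - 1:
            stop = min(len(grid), start + chunk + 1)
            lamc = grid[start:stop, None]
            Ec = Eg[start:stop, None]
            al, be, ga, de, ch = cs
            D = (lamc * lamc + al * lamc + be + (ga * lamc + de) * Ec
                 + ch * Ec * Ec)
            if D_edge is not None:
                D = np.vstack([D_edge, D])
                lam0 = grid[start - 1]
            else:
                lam0 = grid[start]
            s0, s1 = D[:-1], D[1:]
            hit = (s0 * s1 <= 0) & np.isfinite(s0) & np.isfinite(s1) \
                & ~((s0 == 0) & (s1 == 0))
            any_hit = hit.any(axis=0)
            if any_hit.any():
                ridx = hit.shape[0] - 1 - np.argmax(hit[::-1], axis=0)
                cols = np.nonzero(any_hit)[0]
                rows = ridx[cols]
                off = start - (1 if D_edge is not None else 0)
                b_lo[cols] = grid[off + rows]
                b_hi[cols] = grid[off + rows + 1]
                d_lo[cols] = D[rows, cols]
            D_edge = D[-1:].copy()
            start = stop - 1
        have = np.isfinite(b_lo)
        if not have.any():
            return np.full(P, np.nan, dtype=complex)
        tr = _Transform(kernel, num_nodes)
        lo_a = np.where(have, b_lo, 0.0)
        hi_a = np.where(have, b_hi, 1.0)
        f_lo = d_lo.copy()
        for _ in range(refine_iter):
            mid = 0.5 * (lo_a + hi_a)
            Em = np.real(tr.E(mid))
            f_mid = (mid * mid + cs[0] * mid + cs[1]
                     + (cs[2] * mid + cs[3]) * Em + cs[4] * Em * Em)
            left = f_lo * f_mid <= 0
            hi_a = np.where(left, mid, hi_a)
            lo_a = np.where(left, lo_a, mid)
            f_lo = np.where(left, f_lo, f_mid)
        out = (0.5 * (lo_a + hi_a)).astype(complex)
        out[~have] = np.nan
    return out


def _rightmost_grid(coeffs, kernel, num_nodes=32, cont_step=0.05,
                    real_window=(-20.0, 20.0), real_step=0.05,
                    E_grid_cache=None):
    """Rightmost root per parameter point: continuation + real-axis scan."""
    r1, r2 = _continued_roots(coeffs, kernel, num_nodes, cont_step)
    candidates = [r1, r2]
    if not (kernel.is_pointmass and kernel.tau == 0.0):
        rr = _real_axis_roots(coeffs, kernel, num_nodes,
                              real_window[0], real_window[1], real_step,
                              _E_grid_cache=E_grid_cache)
        candidates.append(rr)
    tr = _Transform(kernel, num_nodes)
    scale = _coeff_scale(coeffs)
    best = np.full(r1.shape, np.nan, dtype=complex)
    best_res = np.full(r1.shape, np.inf)
    with np.errstate(over="ignore", invalid="ignore"):
        for cand in candidates:
            res = np.abs(_char_poly(cand, coeffs, tr.E(cand)))
            good = np.isfinite(cand) & (res <= _RESIDUAL_TOL * scale)
            take = good & (np.isnan(best) | (cand.real > best.real))
            best = np.where(take, cand, best)
            best_res = np.where(take, res, best_res)
    return best, best_res


# ---------------------------------------------------------------------------
# public per-point API
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    """Rightmost characteristic roots per wavenumber and the dominant mode."""

    k: np.ndarray                 # integer wavenumbers
    lam: np.ndarray               # rightmost root per k
    residual: np.ndarray          # |D_k| at the reported root
    max_re: float = field(init=False)
    argmax_k: int = field(init=False)

    def __post_init__(self) -> None:
        re = np.where(np.isfinite(self.lam.real), self.lam.real, -np.inf)
        i = int(np.argmax(re))    # ties resolve to the smallest k
        self.max_re = float(re[i])
        self.argmax_k = int(self.k[i])

    def max_re_nonzero(self) -> tuple[float, int]:
        """Max growth rate over the spatially inhomogeneous modes (k != 0)."""
        mask = self.k != 0
        re = np.where(np.isfinite(self.lam.real[mask]),
                      self.lam.real[mask], -np.inf)
        i = int(np.argmax(re))
        return float(re[i]), int(self.k[mask][i])


def _model_coeffs(model: ModelSpec, k: int):
    al, be, ga, de, ch = dispersion_coefficient_arrays(
        model.kinetics, np.array([model.a]), np.array([model.b]),
        model.eps2, model.L2, k)
    return al, be, ga, de, ch


def rightmost_root(model: ModelSpec, kernel: KernelSpec, k: int,
                   num_nodes: int = 32, cont_step: float = 0.05,
                   real_step: float = 0.01) -> tuple[complex, float]:
    """Rightmost root of ``D_k`` and its residual ``|D_k(root)|``."""
    coeffs = _model_coeffs(model, k)
    lam, res = _rightmost_grid(coeffs, kernel, num_nodes, cont_step,
                               real_step=real_step)
    if not np.isfinite(lam[0]):
        raise RuntimeError(
            f"no root with acceptable residual found at k={k} "
            f"(best residual {res[0]:g})")
    return complex(lam[0]), float(res[0])


def max_growth_rate(model: ModelSpec, kernel: KernelSpec, k_max: int = 50,
                    num_nodes: int = 32, cont_step: float = 0.05,
                    real_step: float = 0.05) -> DispersionResult:
    """Rightmost roots for every integer ``k`` in ``[0, k_max]``."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ks = np.arange(k_max + 1)
    lams = np.empty(k_max + 1, dtype=complex)
    ress = np.empty(k_max + 1)
    for k in ks:
        coeffs = _model_coeffs(model, int(k))
        lam, res = _rightmost_grid(coeffs, kernel, num_nodes, cont_step,
                                   real_step=real_step)
        # NaN marks "no root right of the search window" at this k; such
        # strongly damped modes cannot carry the maximum.
        lams[k], ress[k] = lam[0], res[0]
    if not np.isfinite(lams).any():
        raise RuntimeError("dispersion solve found no admissible root at any k")
    return DispersionResult(ks, lams, ress)


# ---------------------------------------------------------------------------
# grid scans
# ---------------------------------------------------------------------------

def _max_re_grids(kinetics: Kinetics, a_grid, b_grid, eps2, L2, kernel,
                  k_max=50, num_nodes=32, cont_step=0.05, real_step=0.05):
    """Per-(a,b) ``Re(lam_0)``, ``max_{k>=1} Re(lam_k)`` and its argmax.

    Points with undefined steady state (e.g. LI at a = b = 0) yield NaN.
    """
    A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
    a, b = A.ravel(), B.ravel()
    re0 = None
    max_knz = np.full(a.shape, -np.inf)
    arg_knz = np.zeros(a.shape, dtype=int)
    lam_grid = np.arange(-20.0, 20.0 + 0.025, real_step)
    Eg = _real_E_grid(kernel, lam_grid, num_nodes)
    for k in range(0, k_max + 1):
        coeffs = dispersion_coefficient_arrays(kinetics, a, b, eps2, L2, k)
        lam, _res = _rightmost_grid(coeffs, kernel, num_nodes, cont_step,
                                    real_step=real_step, E_grid_cache=Eg)
        re = lam.real
        if k == 0:
            re0 = re
        else:
            better = np.isfinite(re) & (re > max_knz)
            arg_knz = np.where(better, k, arg_knz)
            max_knz = np.where(better, re, max_knz)
    bad = ~np.isfinite(re0)
    max_knz[bad] = np.nan
    shape = (len(a_grid), len(b_grid))
    return (re0.reshape(shape), max_knz.reshape(shape),
            arg_knz.reshape(shape))


@dataclass
class TuringScan:
    """Growth-rate field over an ``(a, b)`` grid with marginal contours."""

    a_grid: np.ndarray
    b_grid: np.ndarray
    re_lambda0: np.ndarray        # Re(lam_0), shape (na, nb)
    max_re_nonzero: np.ndarray    # max over k != 0, shape (na, nb)
    argmax_k: np.ndarray
    contour_homogeneous: np.ndarray   # (a, b) points where Re(lam_0) = 0
    contour_inhomogeneous: np.ndarray  # points where max_{k!=0} Re = 0

    @property
    def max_re(self) -> np.ndarray:
        return np.fmax(self.re_lambda0, self.max_re_nonzero)

    @property
    def turing_mask(self) -> np.ndarray:
        """Grid cells inside the Turing space."""
        return (self.re_lambda0 < 0) & (self.max_re_nonzero > 0)

    def turing_cell_count(self) -> int:
        return int(np.count_nonzero(self.turing_mask))


def contour_points(a_grid, b_grid, Z) -> np.ndarray:
    """Zero-level points of ``Z`` by linear interpolation along grid lines."""
    a_grid = np.asarray(a_grid, float)
    b_grid = np.asarray(b_grid, float)
    Z = np.asarray(Z, float)
    pts = []
    # along b (fixed a row)
    z0, z1 = Z[:, :-1], Z[:, 1:]
    hit = (z0 * z1 <= 0) & np.isfinite(z0) & np.isfinite(z1) & (z0 != z1)
    ii, jj = np.nonzero(hit)
    t = z0[ii, jj] / (z0[ii, jj] - z1[ii, jj])
    pts.append(np.column_stack([a_grid[ii],
                                b_grid[jj] + t * (b_grid[jj + 1] - b_grid[jj])]))
    # along a (fixed b column)
    z0, z1 = Z[:-1, :], Z[1:, :]
    hit = (z0 * z1 <= 0) & np.isfinite(z0) & np.isfinite(z1) & (z0 != z1)
    ii, jj = np.nonzero(hit)
    t = z0[ii, jj] / (z0[ii, jj] - z1[ii, jj])
    pts.append(np.column_stack([a_grid[ii] + t * (a_grid[ii + 1] - a_grid[ii]),
                                b_grid[jj]]))
    out = np.vstack(pts) if pts else np.empty((0, 2))
    return out


def hausdorff_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    if len(P) == 0 or len(Q) == 0:
        return math.inf
    from scipy.spatial.distance import cdist

    d = cdist(P, Q)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def turing_space_scan(model: ModelSpec, kernel: KernelSpec, a_grid,
                      b_grid, k_max: int = 50, num_nodes: int = 32,
                      cont_step: float = 0.05,
                      real_step: float = 0.05) -> TuringScan:
    """Scan the ``(a, b)`` plane for the Turing space and its stability lines."""
    a_grid = np.asarray(a_grid, float)
    b_grid = np.asarray(b_grid, float)
    if len(a_grid) < 2 or len(b_grid) < 2:
        raise ValueError("grids need at least two points each")
    re0, knz, argk = _max_re_grids(model.kinetics, a_grid, b_grid,
                                   model.eps2, model.L2, kernel, k_max,
                                   num_nodes, cont_step, real_step)
    return TuringScan(
        a_grid, b_grid, re0, knz, argk,
        contour_homogeneous=contour_points(a_grid, b_grid, re0),
        contour_inhomogeneous=contour_points(a_grid, b_grid, knz),
    )


def distributed_vs_fixed_discrepancy(
    model: ModelSpec, tau: float, sigma_fractions: Sequence[float],
    a_window=(0.0, 1.4), b_window=(0.0, 2.0), grid_shape=(71, 101),
    k_max: int = 50, n: int = 3, num_nodes: int = 32,
    cont_step: float = 0.05, real_step: float = 0.05,
) -> dict[float, float]:
    """Grid maximum of ``|max_k Re lam_k(distributed) - max_k Re lam_k(fixed)|``.

    For each fraction ``c``, the symmetric kernel uses ``sigma = c * tau/n``;
    the fixed-delay reference is the Dirac kernel with the same mean ``tau``.
    """
    for c in sigma_fractions:
        if not (0.0 < c < 1.0):
            raise ValueError("sigma fractions must lie in (0, 1)")
    a_grid = np.linspace(a_window[0], a_window[1], grid_shape[0])
    b_grid = np.linspace(b_window[0], b_window[1], grid_shape[1])

    def max_re_field(kernel):
        re0, knz, _ = _max_re_grids(model.kinetics, a_grid, b_grid,
                                    model.eps2, model.L2, kernel, k_max,
                                    num_nodes, cont_step, real_step)
        return np.fmax(re0, knz)

    fixed = max_re_field(KernelSpec.dirac(tau))
    out = {}
    for c in sigma_fractions:
        dist = max_re_field(KernelSpec.gaussian(tau, c * tau / n, n=n))
        out[float(c)] = float(np.nanmax(np.abs(dist - fixed)))
    return out


def skew_growth_curve(model: ModelSpec, rho: float, omega_fraction: float,
                      tau_grid, k_max: int = 50, n: int = 3,
                      num_nodes: int = 32) -> np.ndarray:
    """``max_k Re(lam_k)`` against mean delay for the skew kernel.

    For each ``tau`` the location ``mu(tau)`` is solved with the scale coupled
    as ``omega = omega_fraction * mu / n``; ``tau = 0`` collapses to the
    no-delay case.
    """
    from .delay_kernels import location_from_mean

    tau_grid = np.asarray(tau_grid, float)
    if np.any(np.diff(tau_grid) <= 0) or np.any(tau_grid < 0):
        raise ValueError("tau_grid must be positive and strictly increasing")
    out = np.empty(len(tau_grid))
    for i, tau in enumerate(tau_grid):
        if tau == 0.0:
            kern = KernelSpec.dirac(0.0)
        elif rho == 0.0:
            kern = KernelSpec.gaussian(tau, omega_fraction * tau / n, n=n)
        else:
            mu, om = location_from_mean(tau, rho, omega_fraction=omega_fraction,
                                        n=n)
            kern = KernelSpec.skew(mu, om, rho, n=n)
        out[i] = max_growth_rate(model, kern, k_max, num_nodes).max_re
    return out
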