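"""Method-of-lines simulation of delayed reaction-diffusion systems.

The domain ``[0, 1]`` is discretised on ``m`` equally spaced points with the
standard three-point Laplacian; homogeneous Neumann conditions enter through
reflected ghost points, and the mixed set clamps the activator to zero at the
boundary (Dirichlet) while keeping Neumann for the inhibitor.  The resulting
system of ``m`` delay differential equations per species is advanced by a
first-order IMEX scheme: diffusion implicitly (backward Euler, tridiagonal
Thomas solves), reaction and delayed terms explicitly.  Past states are held
in a ring buffer of (value, slope) pairs and queried by piecewise-cubic
Hermite interpolation; the distributed-delay integral is approximated by a
composite Simpson rule over the kernel's truncation window, with discrete
weights normalised to unit mass so that homogeneous steady states are
preserved exactly.

The compute kernel is JIT-compiled with numba; the Python-level
:class:`History` and :func:`delayed_term` mirror its conventions for use in
analysis and tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from typing import Callable, Optional

import numpy as np
from numba import njit

from .delay_kernels import KernelSpec, laplace_nodes
from .reaction_models import Kinetics, ModelSpec, steady_state

__all__ = [
    "Grid",
    "History",
    "SimulationResult",
    "build_laplacian",
    "delayed_term",
    "simulate",
    "SIMPSON_NODES",
]

# composite Simpson rule over the truncation window: 50 intervals
SIMPSON_NODES = 51

_MODEL_CODE = {Kinetics.LI: 0, Kinetics.GM1: 1, Kinetics.GM2: 2}
_BC_CODE = {"neumann_neumann": 0, "dirichlet_u_neumann_v": 1}


@dataclass(frozen=True)
class Grid:
    """Uniform spatial grid on ``[0, 1]`` inclusive of both endpoints."""

    m: int = 500

    def __post_init__(self) -> None:
        if self.m < 3:
            raise ValueError("grid needs at least 3 points")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.m)

    @property
    def dx(self) -> float:
        return 1.0 / (self.m - 1)


def build_laplacian(grid: Grid, bc: str = "neumann_neumann"):
    """Banded (scipy ``ab``-layout) three-point Laplacians for ``u`` and ``v``.

    Each operator is a ``(3, m)`` array of (super, main, sub) diagonals of the
    unscaled Laplacian (apply ``D/dx^2`` scaling outside).  Neumann boundary
    rows use reflected ghost points, ``2 (u_2 - u_1)``; Dirichlet rows (the
    activator in the mixed case) are zero rows — the boundary value is held
    at 0 by the integrator.
    """
    if bc not in _BC_CODE:
        raise ValueError(f"unknown boundary conditions {bc!r}")
    m = grid.m

    def neumann() -> np.ndarray:
        ab = np.zeros((3, m))
        ab[0, 1:] = 1.0       # super-diagonal
        ab[1, :] = -2.0       # main
        ab[2, :-1] = 1.0      # sub
        ab[0, 1] = 2.0        # reflected ghost at x = 0
        ab[2, -2] = 2.0       # reflected ghost at x = 1
        return ab

    lap_v = neumann()
    if bc == "neumann_neumann":
        lap_u = neumann()
    else:
        lap_u = neumann()
        lap_u[:, 0] = 0.0
        lap_u[:, -1] = 0.0
        lap_u[0, 1] = 0.0
        lap_u[2, -2] = 0.0
    return lap_u, lap_v


def apply_banded(ab: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Apply a ``(3, m)`` banded operator to a field (dense oracle helper)."""
    m = len(f)
    out = ab[1] * f
    out[:-1] += ab[0, 1:] * f[1:]
    out[1:] += ab[2, :-1] * f[:-1]
    return out


# ---------------------------------------------------------------------------
# history interpolation (python mirror of the compiled kernel's buffer logic)
# ---------------------------------------------------------------------------

class History:
    """Piecewise-cubic interpolant of ``(u, v)`` fields over past times.

    Stores knot values and slopes at uniformly spaced times; evaluation
    outside the covered interval raises (never extrapolates).  The final
    segment falls back to linear interpolation when its right-end slope is
    not yet known (only reachable when the minimum delay is below ``dt``).
    """

    def __init__(self, t_knots: np.ndarray, u: np.ndarray, v: np.ndarray,
                 du: Optional[np.ndarray] = None,
                 dv: Optional[np.ndarray] = None):
        self.t = np.asarray(t_knots, float)
        if len(self.t) < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("history needs at least two increasing knots")
        self.u = np.asarray(u, float)
        self.v = np.asarray(v, float)
        self.du = np.zeros_like(self.u) if du is None else np.asarray(du, float)
        self.dv = np.zeros_like(self.v) if dv is None else np.asarray(dv, float)

    @classmethod
    def constant(cls, u0: np.ndarray, v0: np.ndarray, t_back: float,
                 t0: float = 0.0) -> "History":
        """Constant history equal to the initial fields on ``[t0-t_back, t0]``."""
        t = np.array([t0 - max(t_back, 1e-12), t0])
        return cls(t, np.vstack([u0, u0]), np.vstack([v0, v0]))

    def __call__(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        if t < self.t[0] - 1e-12 or t > self.t[-1] + 1e-12:
            raise ValueError(
                f"history query at t={t:g} outside covered interval "
                f"[{self.t[0]:g}, {self.t[-1]:g}]")
        j = int(np.clip(np.searchsorted(self.t, t, side="right") - 1,
                        0, len(self.t) - 2))
        h = self.t[j + 1] - self.t[j]
        th = (t - self.t[j]) / h
        h00 = (1 + 2 * th) * (1 - th) ** 2
        h10 = th * (1 - th) ** 2
        h01 = th * th * (3 - 2 * th)
        h11 = th * th * (th - 1)
        u = (h00 * self.u[j] + h * h10 * self.du[j]
             + h01 * self.u[j + 1] + h * h11 * self.du[j + 1])
        v = (h00 * self.v[j] + h * h10 * self.dv[j]
             + h01 * self.v[j + 1] + h * h11 * self.dv[j + 1])
        return u, v


def delayed_term(history: History, kernel: KernelSpec, t: float,
                 model: ModelSpec):
    """Kernel-averaged delayed reactant fields ``(F, G)`` at time ``t``.

    The Dirac kernel looks up ``F(u(t - tau), v(t - tau))`` pointwise; the
    continuous families integrate ``K(s) F(u(t-s), v(t-s))`` by composite
    Simpson over the truncation window (``SIMPSON_NODES`` nodes, weights
    normalised to unit mass).  ``G`` is ``None`` for the LI model.
    """
    from .reaction_models import delayed_reactants

    F, G = delayed_reactants(model)
    if kernel.is_pointmass:
        lags, wts = np.array([kernel.tau]), np.array([1.0])
    else:
        lags, wts = laplace_nodes(kernel, "simpson", SIMPSON_NODES)
    Facc = None
    Gacc = None
    for s, w in zip(lags, wts):
        u_s, v_s = history(t - s)
        f = w * F(u_s, v_s)
        Facc = f if Facc is None else Facc + f
        if G is not None:
            g = w * G(u_s, v_s)
            Gacc = g if Gacc is None else Gacc + g
    return Facc, Gacc


# ---------------------------------------------------------------------------
# compiled time stepper
# ---------------------------------------------------------------------------

@njit(cache=True)
def _thomas(sub, dia, sup, rhs, out, cp, dp):  # pragma: no cover - compiled
    m = dia.shape[0]
    cp[0] = sup[0] / dia[0]
    dp[0] = rhs[0] / dia[0]
    for i in range(1, m):
        w = dia[i] - sub[i] * cp[i - 1]
        cp[i] = sup[i] / w
        dp[i] = (rhs[i] - sub[i] * dp[i - 1]) / w
    out[m - 1] = dp[m - 1]
    for i in range(m - 2, -1, -1):
        out[i] = dp[i] - cp[i] * out[i + 1]


@njit(cache=True)
def _interp_fields(tq, dt, n_lo, nbuf, ubuf, vbuf, subuf, svbuf, slope_upto,
                   uq, vq):  # pragma: no cover - compiled
    """Hermite-interpolate (u, v) at time tq from the ring buffer.

    Knot n lives at row (n - n_lo) % nbuf and time n*dt; slopes are valid up
    to knot ``slope_upto`` (newest segment falls back to linear).
    """
    m = ubuf.shape[1]
    fn = tq / dt
    j = int(math.floor(fn))
    th = fn - j
    if th < 1e-12 and j >= n_lo:
        r = (j - n_lo) % nbuf
        for i in range(m):
            uq[i] = ubuf[r, i]
            vq[i] = vbuf[r, i]
        return
    r0 = (j - n_lo) % nbuf
    r1 = (j + 1 - n_lo) % nbuf
    if j + 1 <= slope_upto:
        h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
        h10 = th * (1.0 - th) ** 2
        h01 = th * th * (3.0 - 2.0 * th)
        h11 = th * th * (th - 1.0)
        for i in range(m):
            uq[i] = (h00 * ubuf[r0, i] + dt * h10 * subuf[r0, i]
                     + h01 * ubuf[r1, i] + dt * h11 * subuf[r1, i])
            vq[i] = (h00 * vbuf[r0, i] + dt * h10 * svbuf[r0, i]
                     + h01 * vbuf[r1, i] + dt * h11 * svbuf[r1, i])
    else:
        for i in range(m):
            uq[i] = (1.0 - th) * ubuf[r0, i] + th * ubuf[r1, i]
            vq[i] = (1.0 - th) * vbuf[r0, i] + th * vbuf[r1, i]


@njit(cache=True)
def _lap_neumann(f, out):  # pragma: no cover - compiled
    m = f.shape[0]
    out[0] = 2.0 * (f[1] - f[0])
    for i in range(1, m - 1):
        out[i] = f[i - 1] - 2.0 * f[i] + f[i + 1]
    out[m - 1] = 2.0 * (f[m - 2] - f[m - 1])


@njit(cache=True)
def _run_core(u, v, dt, nsteps, out_every, model, a, b, cu, cv, bc,
              lags, wts, ubuf, vbuf, subuf, svbuf, n_lo,
              sub_u, dia_u, sup_u, sub_v, dia_v, sup_v,
              out_u, out_v, out_t,
              u_star, stop_threshold,
              ):  # pragma: no cover - compiled
    """Advance the IMEX scheme; returns (status, steps_done, samples_done).

    status: 0 ok, 1 blow-up, 2 stopped at threshold crossing.
    """
    m = u.shape[0]
    nbuf = ubuf.shape[0]
    nq = lags.shape[0]
    uq = np.empty(m)
    vq = np.empty(m)
    Fa = np.empty(m)
    Ga = np.empty(m)
    lap = np.empty(m)
    rhs = np.empty(m)
    cp = np.empty(m)
    dp = np.empty(m)
    ru = np.empty(m)
    rv = np.empty(m)
    slope_upto = -1
    nsample = 0
    crossed = -1.0
    for n in range(nsteps):
        t = n * dt
        # delayed reactant fields
        for i in range(m):
            Fa[i] = 0.0
            Ga[i] = 0.0
        for q in range(nq):
            tq = t - lags[q]
            _interp_fields(tq, dt, n_lo, nbuf, ubuf, vbuf, subuf, svbuf,
                           slope_upto, uq, vq)
            w = wts[q]
            if model == 0:      # LI: F = u^2 v
                for i in range(m):
                    Fa[i] += w * uq[i] * uq[i] * vq[i]
            elif model == 1:    # GM1: F = u^2 / v, G = u^2
                for i in range(m):
                    Fa[i] += w * uq[i] * uq[i] / vq[i]
                    Ga[i] += w * uq[i] * uq[i]
            else:               # GM2: F = G = u^2
                for i in range(m):
                    Fa[i] += w * uq[i] * uq[i]
        # reaction rates
        if model == 0:
            for i in range(m):
                ru[i] = a - u[i] - 2.0 * u[i] * u[i] * v[i] + 3.0 * Fa[i]
                rv[i] = b - u[i] * u[i] * v[i]
        elif model == 1:
            for i in range(m):
                ru[i] = a - b * u[i] + Fa[i]
                rv[i] = Ga[i] - v[i]
        elif model == 2:
            for i in range(m):
                ru[i] = a - b * u[i] + Fa[i] / v[i]
                rv[i] = Fa[i] - v[i]
        else:                   # diagnostic mode: reactions disabled
            for i in range(m):
                ru[i] = 0.0
                rv[i] = 0.0
        # store slopes of the current knot (explicit full right-hand side)
        r = (n - n_lo) % nbuf
        _lap_neumann(u, lap)
        if bc == 1:
            lap[0] = 0.0
            lap[m - 1] = 0.0
        for i in range(m):
            subuf[r, i] = cu * lap[i] + ru[i]
        _lap_neumann(v, lap)
        for i in range(m):
            svbuf[r, i] = cv * lap[i] + rv[i]
        if bc == 1:
            subuf[r, 0] = 0.0
            subuf[r, m - 1] = 0.0
        slope_upto = n
        # implicit diffusion step
        for i in range(m):
            rhs[i] = u[i] + dt * ru[i]
        if bc == 1:
            rhs[0] = 0.0
            rhs[m - 1] = 0.0
        _thomas(sub_u, dia_u, sup_u, rhs, u, cp, dp)
        for i in range(m):
            rhs[i] = v[i] + dt * rv[i]
        _thomas(sub_v, dia_v, sup_v, rhs, v, cp, dp)
        # blow-up guard
        amax = 0.0
        for i in range(m):
            if abs(u[i]) > amax:
                amax = abs(u[i])
            if abs(v[i]) > amax:
                amax = abs(v[i])
        if amax > 1e6 or amax != amax:
            return 1, n + 1, nsample
        # write the new knot
        r = (n + 1 - n_lo) % nbuf
        for i in range(m):
            ubuf[r, i] = u[i]
            vbuf[r, i] = v[i]
        # sample output
        if (n + 1) % out_every == 0:
            for i in range(m):
                out_u[nsample, i] = u[i]
                out_v[nsample, i] = v[i]
            out_t[nsample] = (n + 1) * dt
            nsample += 1
            if stop_threshold > 0.0:
                dev = 0.0
                for i in range(m):
                    d = abs(u[i] - u_star)
                    if d > dev:
                        dev = d
                if dev > stop_threshold:
                    return 2, n + 1, nsample
    return 0, nsteps, nsample


# ---------------------------------------------------------------------------
# result container and driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Space-time fields on the uniform grid plus solver metadata."""

    t: np.ndarray                 # sampled times, shape (nt,)
    x: np.ndarray                 # grid coordinates, shape (m,)
    u: np.ndarray                 # activator field, shape (nt, m)
    v: np.ndarray                 # inhibitor field, shape (nt, m)
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        if self.u.shape != (len(self.t), len(self.x)):
            raise ValueError("field shapes inconsistent with t and x")

    @property
    def stopped_at_threshold(self) -> bool:
        return self.meta.get("status") == "threshold"

    def final_profile(self) -> np.ndarray:
        return self.u[-1]

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name, arr in (("x", self.x), ("t", self.t),
                              ("u", self.u), ("v", self.v)):
                f.create_dataset(name, data=arr)
            for key, val in self.meta.items():
                f.attrs[key] = val if val is not None else "none"

    @classmethod
    def from_hdf5(cls, path: str) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["t"][:], f["x"][:], f["u"][:], f["v"][:],
                       dict(f.attrs))


def _implicit_banded(lap: np.ndarray, r: float, dirichlet: bool):
    """Diagonals of ``I - r * Lap`` for the Thomas solver."""
    m = lap.shape[1]
    dia = 1.0 - r * lap[1]
    sup = np.zeros(m)
    sub = np.zeros(m)
    sup[:-1] = -r * lap[0, 1:]
    sub[1:] = -r * lap[2, :-1]
    if dirichlet:
        dia[0] = dia[-1] = 1.0
        sup[0] = 0.0
        sub[-1] = 0.0
    return sub, dia, sup


def simulate(
    model: ModelSpec,
    kernel: KernelSpec,
    u0: np.ndarray,
    v0: np.ndarray,
    t_end: float,
    dt: float = 1e-3,
    bc: str = "neumann_neumann",
    grid: Optional[Grid] = None,
    history: Optional[Callable[[float], tuple[np.ndarray, np.ndarray]]] = None,
    history_slope: Optional[Callable[[float], tuple[np.ndarray, np.ndarray]]] = None,
    out_dt: Optional[float] = None,
    stop_threshold: float = 0.0,
    reaction: bool = True,
    seed: Optional[int] = None,
) -> SimulationResult:
    """Integrate the delayed reaction-diffusion system.

    ``u0, v0`` are the initial fields at ``t = 0``.  ``history`` (a callable
    ``t -> (u, v)`` on ``[-tau2, 0]``) defaults to the constant history equal
    to the initial conditions; ``history_slope`` optionally supplies its time
    derivative for cubic interpolation of time-dependent histories.  With
    ``stop_threshold > 0`` the run ends at the first output sample where
    ``max_x |u - u*| `` exceeds the threshold (time-to-pattern searches).
    ``reaction=False`` disables the kinetics (diffusion-only diagnostics).
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    grid = grid or Grid(len(np.atleast_1d(u0)))
    m = grid.m
    u0 = np.array(u0, dtype=float)
    v0 = np.array(v0, dtype=float)
    if u0.shape != (m,) or v0.shape != (m,):
        raise ValueError("initial fields must match the grid")

    if kernel.is_pointmass:
        lags = np.array([kernel.tau])
        wts = np.array([1.0])
    else:
        lags, wts = laplace_nodes(kernel, "simpson", SIMPSON_NODES)
    tau2 = float(lags.max())

    nsteps = int(round(t_end / dt))
    out_dt = out_dt if out_dt is not None else max(dt, t_end / 400.0)
    out_every = max(1, int(round(out_dt / dt)))
    n_hist = int(math.ceil(tau2 / dt)) + 1
    nbuf = n_hist + 3
    n_lo = -(n_hist + 1)

    ubuf = np.empty((nbuf, m))
    vbuf = np.empty((nbuf, m))
    subuf = np.zeros((nbuf, m))
    svbuf = np.zeros((nbuf, m))
    for n in range(n_lo, 1):
        r = (n - n_lo) % nbuf
        tn = n * dt
        if n == 0 or history is None:
            hu, hv = (u0, v0) if n == 0 else (u0, v0)
        else:
            hu, hv = history(max(tn, -tau2))
        ubuf[r], vbuf[r] = hu, hv
        if history_slope is not None and n < 0:
            su, sv = history_slope(max(tn, -tau2))
            subuf[r], svbuf[r] = su, sv

    lap_u, lap_v = build_laplacian(grid, bc)
    cu = model.eps2 / model.L2 / grid.dx ** 2
    cv = 1.0 / model.L2 / grid.dx ** 2
    dirichlet = bc == "dirichlet_u_neumann_v"
    sub_u, dia_u, sup_u = _implicit_banded(lap_u, dt * cu, dirichlet)
    sub_v, dia_v, sup_v = _implicit_banded(lap_v, dt * cv, False)

    n_out = nsteps // out_every
    out_u = np.empty((n_out, m))
    out_v = np.empty((n_out, m))
    out_t = np.empty(n_out)

    u_star, _ = steady_state(model)
    code = _MODEL_CODE[model.kinetics] if reaction else 3
    status, steps, nsample = _run_core(
        u0.copy(), v0.copy(), dt, nsteps, out_every, code,
        model.a, model.b, cu, cv, _BC_CODE[bc],
        lags, wts, ubuf, vbuf, subuf, svbuf, n_lo,
        sub_u, dia_u, sup_u, sub_v, dia_v, sup_v,
        out_u, out_v, out_t, u_star, float(stop_threshold))
    if status == 1:
        raise RuntimeError(
            f"solution blew up (|u| or |v| > 1e6) at t = {steps * dt:g}")

    t_samples = np.concatenate([[0.0], out_t[:nsample]])
    u_all = np.vstack([u0[None, :], out_u[:nsample]])
    v_all = np.vstack([v0[None, :], out_v[:nsample]])
    meta = {
        "dt": dt, "m": m, "bc": bc, "steps": steps,
        "model": model.kinetics.value, "a": model.a, "b": model.b,
        "eps2": model.eps2, "L2": model.L2,
        "kernel": str(kernel.to_dict()),
        "status": {0: "completed", 2: "threshold"}[status],
        "seed": seed if seed is not None else -1,
        "rng": "pcg64",
    }
    return SimulationResult(t_samples, grid.x, u_all, v_all, meta)
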