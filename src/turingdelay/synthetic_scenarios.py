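"""Synthetic inputs: seeded initial conditions, histories, and named presets.

Every input the analysis consumes is generated here: multiplicative Gaussian
perturbations of the homogeneous steady state (the standard initial
condition), a deterministic structured surrogate for single-mode initial
data, constant or oscillatory history functions, and an immutable registry
of named presets covering the simulated parameter regimes.

Random fields are drawn from numpy's PCG64 generator; the algorithm name is
recorded in output metadata so that "same seed, same field" holds across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace
from typing import Optional

import numpy as np

from .dde_simulator import Grid
from .delay_kernels import KernelSpec
from .reaction_models import ModelSpec, steady_state

__all__ = [
    "ScenarioSpec",
    "random_ic",
    "structured_ic_surrogate",
    "history_function",
    "PRESETS",
]

RNG_ALGORITHM = "pcg64"


def random_ic(model: ModelSpec, grid: Grid, sigma_IC: float,
              seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative Gaussian perturbation of the steady state.

    ``u0 = u*(1 + r_u(x))``, ``v0 = v*(1 + r_v(x))`` with ``r_u, r_v`` iid
    zero-mean Gaussians of standard deviation ``sigma_IC`` per grid point.
    Identical seeds give bit-identical fields.
    """
    if sigma_IC < 0:
        raise ValueError("sigma_IC must be >= 0")
    us, vs = steady_state(model)
    rng = np.random.default_rng(seed)
    ru = rng.standard_normal(grid.m)
    rv = rng.standard_normal(grid.m)
    return us * (1.0 + sigma_IC * ru), vs * (1.0 + sigma_IC * rv)


def structured_ic_surrogate(model: ModelSpec, grid: Grid,
                            amplitude: float = 0.1,
                            mode: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic deterministic low-mode perturbation (structured-IC stand-in).

    A smooth single-bump profile: the activator is raised and the inhibitor
    depressed by ``amplitude`` times a Gaussian bump centred mid-domain,
    modulated by ``cos(mode * pi * x)`` for ``mode > 1``.  This is a
    synthetic surrogate for structured initial data whose exact algebraic
    form is not part of this package; it is deterministic (no seed) and used
    for qualitative robustness studies only.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    us, vs = steady_state(model)
    x = grid.x
    bump = np.exp(-((x - 0.5) ** 2) / 0.02)
    if mode > 1:
        bump = bump * np.cos(mode * np.pi * x)
    return us * (1.0 + amplitude * bump), vs * (1.0 - amplitude * bump)


def history_function(ic: tuple[np.ndarray, np.ndarray], kind: str,
                     model: Optional[ModelSpec] = None,
                     r_scale: float = 0.0, w: float = 1.0,
                     seed: int = 0, grid: Optional[Grid] = None):
    """History callable(s) on ``[-tau2, 0]`` for the simulator.

    ``constant`` returns the initial fields for every past time.
    ``oscillatory`` returns the steady state multiplied by
    ``1 + r(x) sin(w t)`` with ``r(x)`` a seeded Gaussian field of standard
    deviation ``r_scale``; its analytic time derivative is supplied for
    cubic history interpolation.  Returns ``(history, history_slope)``
    where ``history_slope`` is ``None`` for the constant kind.
    """
    u0, v0 = ic
    if kind == "constant":
        def hist(t):
            return u0, v0
        return hist, None
    if kind == "oscillatory":
        if model is None or grid is None:
            raise ValueError("oscillatory history needs model and grid")
        us, vs = steady_state(model)
        rng = np.random.default_rng(seed)
        ru = r_scale * rng.standard_normal(grid.m)
        rv = r_scale * rng.standard_normal(grid.m)

        def hist(t):
            s = np.sin(w * t)
            return us * (1.0 + ru * s), vs * (1.0 + rv * s)

        def slope(t):
            c = w * np.cos(w * t)
            return us * ru * c, vs * rv * c

        return hist, slope
    raise ValueError(f"unknown history kind {kind!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified simulation scenario (model, kernel, inputs, run)."""

    name: str
    model: ModelSpec
    kernel: KernelSpec
    ic_kind: str = "random"            # random | structured_surrogate | steady
    sigma_IC: float = 0.01
    seed: int = 0
    history_kind: str = "constant"     # constant | oscillatory
    history_r_scale: float = 0.0
    history_w: float = 1.0
    bc: str = "neumann_neumann"
    t_end: float = 100.0
    dt: float = 1e-3
    m: int = 500
    threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_IC < 0:
            raise ValueError("sigma_IC must be >= 0")
        if self.ic_kind not in ("random", "structured_surrogate", "steady"):
            raise ValueError(f"unknown ic_kind {self.ic_kind!r}")
        if self.history_kind not in ("constant", "oscillatory"):
            raise ValueError(f"unknown history_kind {self.history_kind!r}")

    def build_ic(self, grid: Optional[Grid] = None):
        grid = grid or Grid(self.m)
        if self.ic_kind == "random":
            return random_ic(self.model, grid, self.sigma_IC, self.seed)
        if self.ic_kind == "structured_surrogate":
            return structured_ic_surrogate(self.model, grid,
                                           amplitude=max(self.sigma_IC, 1e-3))
        us, vs = steady_state(self.model)
        return np.full(grid.m, us), np.full(grid.m, vs)

    def build_history(self, ic, grid: Optional[Grid] = None):
        return history_function(ic, self.history_kind, model=self.model,
                                r_scale=self.history_r_scale,
                                w=self.history_w, seed=self.seed,
                                grid=grid or Grid(self.m))

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        d = {
            "name": self.name, "ic_kind": self.ic_kind,
            "sigma_IC": self.sigma_IC, "seed": self.seed,
            "history_kind": self.history_kind,
            "history_r_scale": self.history_r_scale,
            "history_w": self.history_w, "bc": self.bc,
            "t_end": self.t_end, "dt": self.dt, "m": self.m,
            "threshold": self.threshold, "rng": RNG_ALGORITHM,
        }
        d["model"] = self.model.to_dict()
        d["kernel"] = self.kernel.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        d.pop("rng", None)
        model = ModelSpec.from_dict(d.pop("model"))
        kernel = KernelSpec.from_dict(d.pop("kernel"))
        return cls(model=model, kernel=kernel, **d)


def _p(name, kinetics, a, b, tau, *, sigma=None, eps2=0.001, L2=4.5,
       sigma_IC=0.01, threshold=0.1, t_end=100.0, m=500, **kw) -> ScenarioSpec:
    model = ModelSpec(kinetics, a, b, eps2=eps2, L2=L2)
    if sigma is None:
        kern = KernelSpec.dirac(tau)
    else:
        kern = KernelSpec.gaussian(tau, sigma)
    return ScenarioSpec(name=name, model=model, kernel=kern,
                        sigma_IC=sigma_IC, threshold=threshold,
                        t_end=t_end, m=m, **kw)


#: Immutable registry of the simulated parameter regimes.
PRESETS: dict[str, ScenarioSpec] = {
    # LI patterning, fixed delay (space-time pattern comparisons)
    "li_pattern_tau1": _p("li_pattern_tau1", "LI", 0.1, 0.9, 1.0),
    "li_pattern_tau16": _p("li_pattern_tau16", "LI", 0.1, 0.9, 16.0,
                           t_end=600.0),
    # LI distributed-delay companions
    "li_pattern_tau1_gauss": _p("li_pattern_tau1_gauss", "LI", 0.1, 0.9, 1.0,
                                sigma=0.99 / 3),
    # small-skew regime (eps2 = 0.01)
    "li_pattern_tau01_eps001": _p("li_pattern_tau01_eps001", "LI", 0.1, 0.9,
                                  0.1, eps2=0.01, t_end=40.0),
    # linear-theory regime (small domain)
    "li_linear_small_domain": _p("li_linear_small_domain", "LI", 0.4, 1.8,
                                 0.2, L2=0.2, sigma_IC=1e-5, t_end=60.0),
    # time-to-pattern sweeps
    "li_tau_sweep": _p("li_tau_sweep", "LI", 0.1, 0.9, 1.0, sigma_IC=1e-5,
                       t_end=400.0),
    "gm1_tau_sweep": _p("gm1_tau_sweep", "GM1", 0.75, 0.5, 0.5,
                        sigma_IC=1e-3, threshold=10.0, t_end=200.0),
    "gm2_tau_sweep": _p("gm2_tau_sweep", "GM2", 0.75, 0.5, 1.0,
                        sigma_IC=1e-3, threshold=10.0, t_end=400.0),
    # initial-condition robustness (larger random perturbation)
    "li_large_ic": _p("li_large_ic", "LI", 0.1, 0.9, 1.0, sigma_IC=0.1),
    "li_small_ic": _p("li_small_ic", "LI", 0.1, 0.9, 1.0, sigma_IC=1e-3),
    # mixed boundary conditions
    "li_mixed_bc_tau1": _p("li_mixed_bc_tau1", "LI", 0.1, 0.9, 1.0,
                           bc="dirichlet_u_neumann_v"),
}
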