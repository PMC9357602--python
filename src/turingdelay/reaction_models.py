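"""Delayed reaction kinetics: the LI Schnakenberg model and two GM variants.

All three models are two-species activator(u)-inhibitor(v) systems in
nondimensional form with kinetic parameters ``a, b``, diffusion ratio
``eps2`` and domain-size scaling ``L2``:

* ``LI`` (ligand-internalisation Schnakenberg): the delay acts only on the
  activator autocatalysis ``u^2 v``;
    du/dt = a - u - 2 u^2 v + 3 <u_s^2 v_s>,   dv/dt = b - u^2 v
* ``GM1`` (Gierer-Meinhardt, fully delayed activator source):
    du/dt = a - b u + <u_s^2 / v_s>,           dv/dt = <u_s^2> - v
* ``GM2`` (Gierer-Meinhardt, instantaneous inhibitor in the source):
    du/dt = a - b u + <u_s^2> / v,             dv/dt = <u_s^2> - v

where ``< . >`` denotes the delay-kernel average of the enclosed expression
over past states.  Delayed-term values are passed into :func:`kinetic_rhs`
rather than computed here, so the same kinetics serve the linearised
analysis, the fixed-delay simulator and the distributed-delay simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Kinetics",
    "ModelSpec",
    "DispersionCoefficients",
    "steady_state",
    "kinetic_rhs",
    "delayed_reactants",
    "dispersion_coefficients",
    "dispersion_coefficient_arrays",
]


class Kinetics(str, Enum):
    LI = "LI"
    GM1 = "GM1"
    GM2 = "GM2"


@dataclass(frozen=True)
class ModelSpec:
    """Kinetics identity with parameters and implied steady state."""

    kinetics: Kinetics
    a: float
    b: float
    eps2: float = 0.001
    L2: float = 4.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "kinetics", Kinetics(self.kinetics))
        if self.a < 0:
            raise ValueError("feed parameter a must be >= 0")
        if self.eps2 <= 0:
            raise ValueError("diffusion ratio eps2 must be > 0")
        if self.L2 <= 0:
            raise ValueError("domain scaling L2 must be > 0")
        if self.kinetics == Kinetics.LI:
            if self.a + self.b <= 0:
                raise ValueError("LI model requires a + b > 0")
        else:
            if self.b <= 0:
                raise ValueError("GM models require b > 0")

    def to_dict(self) -> dict:
        return {"kinetics": self.kinetics.value, "a": self.a, "b": self.b,
                "eps2": self.eps2, "L2": self.L2}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(Kinetics(d["kinetics"]), float(d["a"]), float(d["b"]),
                   float(d.get("eps2", 0.001)), float(d.get("L2", 4.5)))


@dataclass(frozen=True)
class DispersionCoefficients:
    """Real coefficients of the transcendental dispersion relation

    ``lam^2 + alpha_k lam + beta_k + (gamma_k lam + delta_k) E(lam)
      + chi_k E(lam)^2 = 0``.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    chi: float


def steady_state(model: ModelSpec) -> tuple[float, float]:
    """Unique positive homogeneous steady state ``(u*, v*)``.

    LI: ``(a+b, b/(a+b)^2)``; GM: ``((a+1)/b, ((a+1)/b)^2)``.
    """
    if model.kinetics == Kinetics.LI:
        s = model.a + model.b
        return s, model.b / (s * s)
    u = (model.a + 1.0) / model.b
    return u, u * u


def kinetic_rhs(model: ModelSpec, u, v, F_val, G_val=None):
    """Reaction rates given pre-computed delayed-term values.

    ``F_val`` is the kernel-averaged delayed reactant: ``<u^2 v>`` for LI,
    ``<u^2/v>`` for GM1 and ``<u^2>`` for GM2.  ``G_val`` is ``<u^2>`` for
    both GM variants and unused for LI.  With the no-delay substitutions
    (``F_val``/``G_val`` evaluated at the instantaneous state) these reduce
    to the classical Schnakenberg / Gierer-Meinhardt rates.
    """
    a, b = model.a, model.b
    if model.kinetics == Kinetics.LI:
        du = a - u - 2.0 * u * u * v + 3.0 * F_val
        dv = b - u * u * v
        return du, dv
    if np.any(np.asarray(v) == 0):
        raise ZeroDivisionError("GM kinetics are singular at v = 0")
    if G_val is None:
        raise ValueError("GM kinetics require the delayed G value <u^2>")
    if model.kinetics == Kinetics.GM1:
        du = a - b * u + F_val
    else:  # GM2: delayed numerator over instantaneous inhibitor
        du = a - b * u + F_val / v
    dv = G_val - v
    return du, dv


def delayed_reactants(model: ModelSpec):
    """The reactant functions ``F(u, v)`` (and ``G``) that the kernel averages.

    Returns ``(F, G)`` callables; ``G`` is ``None`` for the LI model, whose
    inhibitor dynamics are undelayed.
    """
    if model.kinetics == Kinetics.LI:
        return (lambda u, v: u * u * v), None
    if model.kinetics == Kinetics.GM1:
        return (lambda u, v: u * u / v), (lambda u, v: u * u)
    return (lambda u, v: u * u), (lambda u, v: u * u)


def dispersion_coefficients(model: ModelSpec, k: int) -> DispersionCoefficients:
    """Dispersion-relation coefficients at integer wavenumber ``k``."""
    if k < 0 or int(k) != k:
        raise ValueError("wavenumber k must be a nonnegative integer")
    al, be, ga, de, ch = dispersion_coefficient_arrays(
        model.kinetics, np.array([model.a]), np.array([model.b]),
        model.eps2, model.L2, int(k))
    return DispersionCoefficients(float(al[0]), float(be[0]), float(ga[0]),
                                  float(de[0]), float(ch[0]))


def dispersion_coefficient_arrays(kinetics: Kinetics, a, b, eps2: float,
                                  L2: float, k: int):
    """Vectorized dispersion coefficients over arrays of ``(a, b)``.

    Follows the per-model closed forms (evaluated at the steady state); used
    both for single parameter points and for Turing-space grid scans.
    """
    kinetics = Kinetics(kinetics)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    q = (k * math.pi) ** 2
    qu = eps2 / L2 * q          # activator diffusion times k^2 pi^2
    qv = 1.0 / L2 * q           # inhibitor diffusion times k^2 pi^2
    if kinetics == Kinetics.LI:
        with np.errstate(divide="ignore", invalid="ignore"):
            u = a + b
            v = b / (u * u)
            uv = u * v              # = b/(a+b)
            alpha = qu + qv + u * u + 4.0 * uv + 1.0
            beta = (qv + u * u) * (qu + 4.0 * uv + 1.0) - 4.0 * u ** 3 * v
            gamma = -6.0 * uv
            delta = -6.0 * uv * qv
            chi = np.zeros_like(alpha)
        return alpha, beta, gamma, delta, chi
    u = (a + 1.0) / b
    v = u * u
    r = 2.0 * u / v             # = 2/u
    alpha = qu + qv + b + 1.0
    beta = (qu + b) * (qv + 1.0)
    gamma = -r + np.zeros_like(beta)
    delta = -r * (qv + 1.0)
    chi = 2.0 * u ** 3 / (v * v) + np.zeros_like(beta)  # = 2/u
    if kinetics == Kinetics.GM2:
        delta = delta + chi
        chi = np.zeros_like(beta)
    return alpha, beta, gamma, delta + np.zeros_like(beta), chi
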