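"""Delay-kernel families for distributed gene-expression time delays.

A delay kernel is a probability density ``K(s)`` of delay times ``s`` on a
finite truncation window ``[tau1, tau2]`` of strictly positive delays.  Three
families are supported:

* ``dirac`` — a fixed delay ``tau`` (a point mass; the sigma -> 0 limit of the
  Gaussian family),
* ``gaussian`` — a truncated Gaussian with mean ``tau`` and spread ``sigma``,
  truncated symmetrically at ``tau +- n*sigma``,
* ``skew_gaussian`` — a truncated skew-normal with location ``mu``, scale
  ``omega`` and skew factor ``rho``, truncated at ``mu +- n*omega``.

The window half-width multiplier ``n`` (default 3) and the positivity of
``tau1`` bound the admissible spreads: ``sigma < tau/n`` (``sigma_max``) and
``omega < mu/n`` (``omega_max``).

The kernel enters linear stability analysis only through its Laplace-type
transform ``E(lam) = int K(s) exp(-lam*s) ds``, provided by
:func:`kernel_laplace`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Union

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erf, ndtr

__all__ = [
    "KernelFamily",
    "KernelSpec",
    "standard_normal_cdf",
    "owens_t",
    "kernel_pdf",
    "kernel_mean",
    "truncated_skew_mean",
    "location_from_mean",
    "kernel_laplace",
    "sigma_max",
    "omega_max",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


class KernelFamily(str, Enum):
    DIRAC = "dirac"
    GAUSSIAN = "gaussian"
    SKEW_GAUSSIAN = "skew_gaussian"


def sigma_max(tau: float, n: int = 3) -> float:
    """Largest admissible spread of the symmetric kernel, ``tau / n``."""
    return tau / n


def omega_max(mu: float, n: int = 3) -> float:
    """Largest admissible scale of the skew kernel, ``mu / n``."""
    return mu / n


@dataclass(frozen=True)
class KernelSpec:
    """A delay distribution: family, parameters and truncation window.

    Use the constructors :meth:`dirac`, :meth:`gaussian` and :meth:`skew`
    rather than the raw dataclass, which validates on construction.
    """

    family: KernelFamily
    tau: float = 0.0        # mean delay (dirac / gaussian families)
    sigma: float = 0.0      # spread (gaussian family)
    mu: float = 0.0         # location (skew family)
    omega: float = 0.0      # scale (skew family)
    rho: float = 0.0        # skew factor (skew family)
    n: int = 3              # truncation half-width multiplier

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("truncation multiplier n must be a positive integer")
        if self.family == KernelFamily.DIRAC:
            if self.tau < 0:
                raise ValueError("dirac kernel requires tau >= 0")
            if self.sigma != 0.0:
                raise ValueError("dirac kernel has sigma = 0 by definition")
        elif self.family == KernelFamily.GAUSSIAN:
            if self.tau <= 0:
                raise ValueError("gaussian kernel requires tau > 0")
            if self.sigma < 0:
                raise ValueError("gaussian kernel requires sigma >= 0")
            if self.sigma > 0 and self.tau - self.n * self.sigma <= 0:
                raise ValueError(
                    f"truncation window must contain positive delays only: "
                    f"tau - n*sigma = {self.tau - self.n * self.sigma:g} <= 0 "
                    f"(sigma_max = tau/n = {self.tau / self.n:g})"
                )
        elif self.family == KernelFamily.SKEW_GAUSSIAN:
            if self.omega <= 0:
                raise ValueError("skew kernel requires omega > 0")
            if self.mu - self.n * self.omega <= 0:
                raise ValueError(
                    f"truncation window must contain positive delays only: "
                    f"mu - n*omega = {self.mu - self.n * self.omega:g} <= 0 "
                    f"(omega_max = mu/n = {self.mu / self.n:g})"
                )
        else:  # pragma: no cover
            raise ValueError(f"unknown kernel family {self.family!r}")

    # -- constructors -------------------------------------------------------
    @classmethod
    def dirac(cls, tau: float) -> "KernelSpec":
        return cls(family=KernelFamily.DIRAC, tau=float(tau))

    @classmethod
    def gaussian(cls, tau: float, sigma: float, n: int = 3) -> "KernelSpec":
        return cls(family=KernelFamily.GAUSSIAN, tau=float(tau),
                   sigma=float(sigma), n=n)

    @classmethod
    def skew(cls, mu: float, omega: float, rho: float, n: int = 3) -> "KernelSpec":
        return cls(family=KernelFamily.SKEW_GAUSSIAN, mu=float(mu),
                   omega=float(omega), rho=float(rho), n=n)

    # -- derived quantities -------------------------------------------------
    @property
    def tau1(self) -> float:
        """Lower truncation bound (minimum delay)."""
        if self.family == KernelFamily.GAUSSIAN:
            return self.tau - self.n * self.sigma
        if self.family == KernelFamily.SKEW_GAUSSIAN:
            return self.mu - self.n * self.omega
        return self.tau

    @property
    def tau2(self) -> float:
        """Upper truncation bound (maximum delay)."""
        if self.family == KernelFamily.GAUSSIAN:
            return self.tau + self.n * self.sigma
        if self.family == KernelFamily.SKEW_GAUSSIAN:
            return self.mu + self.n * self.omega
        return self.tau

    @property
    def is_pointmass(self) -> bool:
        return self.family == KernelFamily.DIRAC or (
            self.family == KernelFamily.GAUSSIAN and self.sigma == 0.0
        )

    def scaled(self, factor: float) -> "KernelSpec":
        """Scale all time-like parameters by ``factor`` (mean scales likewise).

        Used by the delay-continuation root finder, which homotopes the kernel
        from zero delay to its nominal parameters.
        """
        if factor == 0.0:
            return KernelSpec.dirac(0.0)
        if self.family == KernelFamily.SKEW_GAUSSIAN:
            return replace(self, mu=self.mu * factor, omega=self.omega * factor)
        return replace(self, tau=self.tau * factor, sigma=self.sigma * factor)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {"family": self.family.value, "n": self.n}
        if self.family == KernelFamily.SKEW_GAUSSIAN:
            d.update(mu=self.mu, omega=self.omega, rho=self.rho)
        else:
            d.update(tau=self.tau)
            if self.family == KernelFamily.GAUSSIAN:
                d.update(sigma=self.sigma)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        fam = KernelFamily(d["family"])
        n = int(d.get("n", 3))
        if fam == KernelFamily.DIRAC:
            return cls.dirac(float(d["tau"]))
        if fam == KernelFamily.GAUSSIAN:
            return cls.gaussian(float(d["tau"]), float(d["sigma"]), n=n)
        return cls.skew(float(d["mu"]), float(d["omega"]), float(d["rho"]), n=n)


# ---------------------------------------------------------------------------
# elementary special functions
# ---------------------------------------------------------------------------

def standard_normal_cdf(x):
    """Cumulative distribution function of the standard Gaussian."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("standard_normal_cdf requires finite input")
    out = ndtr(x)
    return float(out) if out.ndim == 0 else out


def owens_t(x: float, rho: float, num_nodes: int = 100_001) -> float:
    """Owen's T function by composite Simpson quadrature.

    ``T(x, rho) = (1/2pi) int_0^rho exp(-x^2 (1+s^2)/2) / (1+s^2) ds``.
    ``num_nodes`` must be odd; the default resolves the integral far below
    1e-10 absolute error for moderate arguments.  Antisymmetric in ``rho``.
    """
    if not (np.isfinite(x) and np.isfinite(rho)):
        raise ValueError("owens_t requires finite arguments")
    if rho == 0.0:
        return 0.0
    if num_nodes < 3 or num_nodes % 2 == 0:
        raise ValueError("num_nodes must be odd and >= 3")
    s = np.linspace(0.0, rho, num_nodes)
    f = np.exp(-0.5 * x * x * (1.0 + s * s)) / (1.0 + s * s)
    h = rho / (num_nodes - 1)
    w = np.ones(num_nodes)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return float(h / 3.0 * np.dot(w, f) / (2.0 * math.pi))


def _skew_cdf(x, rho: float, num_nodes: int = 100_001):
    """CDF of the standard skew-normal, ``Phi(x) - 2 T(x, rho)``."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.array([owens_t(xi, rho, num_nodes) for xi in xs])
    out = ndtr(xs) - 2.0 * t
    return float(out[0]) if np.ndim(x) == 0 else out


def _phi_c(kernel: KernelSpec) -> float:
    """Truncation constant of the symmetric family, ``1/(Phi(n) - Phi(-n))``."""
    n = kernel.n
    return 1.0 / (ndtr(float(n)) - ndtr(float(-n)))


def _psi_c(kernel: KernelSpec, num_nodes: int = 100_001) -> float:
    """Truncation constant of the skew family (skew-normal cdf at +-n)."""
    n = float(kernel.n)
    lo = _skew_cdf(-n, kernel.rho, num_nodes)
    hi = _skew_cdf(n, kernel.rho, num_nodes)
    return 1.0 / (hi - lo)


# ---------------------------------------------------------------------------
# pdf / mean / transform
# ---------------------------------------------------------------------------

def kernel_pdf(kernel: KernelSpec, s):
    """Evaluate the kernel density at delay(s) ``s``.

    Returns 0 outside the truncation window (so quadrature nodes may straddle
    the boundary harmlessly).  The Dirac family has no density.
    """
    if kernel.is_pointmass:
        raise ValueError("a point-mass (dirac) kernel has no density")
    s_arr = np.asarray(s, dtype=float)
    z = np.where(
        (s_arr >= kernel.tau1) & (s_arr <= kernel.tau2), s_arr, np.nan
    )
    if kernel.family == KernelFamily.GAUSSIAN:
        zz = (z - kernel.tau) / kernel.sigma
        out = _phi_c(kernel) / (kernel.sigma * _SQRT2PI) * np.exp(-0.5 * zz * zz)
    else:
        zz = (z - kernel.mu) / kernel.omega
        out = (
            _psi_c(kernel) / kernel.omega
            * math.sqrt(2.0 / math.pi)
            * np.exp(-0.5 * zz * zz)
            * ndtr(kernel.rho * zz)
        )
    out = np.where(np.isnan(z), 0.0, out)
    return float(out) if out.ndim == 0 else out


def truncated_skew_mean(mu: float, omega: float, rho: float,
                        n: int = 3) -> float:
    """Mean of the truncated skew-normal (valid on the closed admissible
    set ``mu - n*omega >= 0``, i.e. including the ``omega_max`` boundary)."""
    if mu - n * omega < 0:
        raise ValueError("truncation window extends to negative delays")
    nf = float(n)
    rho_hat = math.sqrt(1.0 + rho * rho)
    psi_c = 1.0 / (_skew_cdf(nf, rho) - _skew_cdf(-nf, rho))

    def h(z: float) -> float:
        return math.sqrt(2.0 / math.pi) * math.exp(-0.5 * z * z) * ndtr(rho * z)

    bracket = (
        h(-nf) - h(nf)
        + (2.0 * rho / (rho_hat * _SQRT2PI))
        * (ndtr(rho_hat * nf) - ndtr(-rho_hat * nf))
    )
    return mu + omega * psi_c * bracket


def kernel_mean(kernel: KernelSpec) -> float:
    """Mean delay of the kernel.

    Dirac and symmetric Gaussian kernels have mean ``tau`` (the symmetric
    truncation preserves the mean).  For the skew family the truncated
    skew-normal mean is evaluated in closed form:

    ``mean = mu + omega * Psi_c * [ h(z1) - h(z2)
              + (2 rho / (rho_hat sqrt(2 pi))) (Phi(rho_hat z2) - Phi(rho_hat z1)) ]``

    with ``h(z) = sqrt(2/pi) exp(-z^2/2) Phi(rho z)``, ``z_i = -+n`` and
    ``rho_hat = sqrt(1 + rho^2)``.  This form agrees with direct quadrature of
    ``int s K(s) ds`` to machine precision.
    """
    if kernel.family != KernelFamily.SKEW_GAUSSIAN:
        return kernel.tau
    return truncated_skew_mean(kernel.mu, kernel.omega, kernel.rho, kernel.n)


def location_from_mean(
    tau: float,
    rho: float,
    omega: Union[float, None] = None,
    omega_fraction: Union[float, None] = None,
    n: int = 3,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Solve for the skew kernel's location ``mu`` (and scale) given its mean.

    Either ``omega`` is given explicitly, or ``omega_fraction = c`` couples the
    scale to the location through ``omega = c * mu / n`` (a fraction of
    ``omega_max``); the mean equation and the coupling are then solved jointly
    as a single scalar root problem in ``mu``.

    Returns ``(mu, omega)`` with ``kernel_mean(skew(mu, omega, rho)) = tau``
    to within ``tol`` on the mean residual.
    """
    if tau <= 0:
        raise ValueError("mean delay tau must be positive")
    if (omega is None) == (omega_fraction is None):
        raise ValueError("specify exactly one of omega or omega_fraction")
    if omega_fraction is not None and not (0.0 < omega_fraction <= 1.0):
        raise ValueError("omega_fraction must lie in (0, 1]")

    def omega_of(mu: float) -> float:
        return omega if omega is not None else omega_fraction * mu / n

    def residual(mu: float) -> float:
        w = omega_of(mu)
        if mu - n * w < 0:
            # outside the admissible region; push the solver back
            return -tau
        return truncated_skew_mean(mu, w, rho, n=n) - tau

    lo, hi = tau * 1e-2, tau * 1e2
    rlo, rhi = residual(lo), residual(hi)
    if rlo * rhi > 0:
        raise ValueError(
            f"no admissible root of the mean equation in mu bracket "
            f"[{lo:g}, {hi:g}] (residuals {rlo:g}, {rhi:g})"
        )
    mu_star = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16)
    w_star = omega_of(mu_star)
    res = truncated_skew_mean(mu_star, w_star, rho, n=n) - tau
    if abs(res) > tol:
        raise RuntimeError(
            f"mean residual {res:g} above tolerance {tol:g} at mu={mu_star:g}"
        )
    return mu_star, w_star


def kernel_laplace(kernel: KernelSpec, lam: complex) -> complex:
    """Laplace-type transform ``E(lam) = int K(s) exp(-lam s) ds``.

    * dirac: ``exp(-lam tau)`` exactly;
    * gaussian, real ``lam``: closed form
      ``(Phi_c/2) exp(lam^2 sigma^2/2 - lam tau)
        [erf((lam sigma^2 + s - tau)/(sqrt(2) sigma))]_{tau1}^{tau2}``;
    * gaussian with complex ``lam``, and the skew family always: adaptive
      quadrature of ``K(s) exp(-lam s)`` (real and imaginary parts separately).

    ``E(0) = 1`` for every kernel (pdf normalization).
    """
    if not np.isfinite(lam):
        raise ValueError("lam must be finite")
    lam = complex(lam)
    if kernel.is_pointmass:
        val = np.exp(-lam * kernel.tau)
        return complex(val)
    if lam == 0:
        return 1.0 + 0.0j
    if kernel.family == KernelFamily.GAUSSIAN and lam.imag == 0.0:
        lr = lam.real
        t, s = kernel.tau, kernel.sigma
        pref = 0.5 * _phi_c(kernel) * math.exp(0.5 * lr * lr * s * s - lr * t)
        a1 = (lr * s * s + kernel.tau1 - t) / (math.sqrt(2.0) * s)
        a2 = (lr * s * s + kernel.tau2 - t) / (math.sqrt(2.0) * s)
        return complex(pref * (erf(a2) - erf(a1)))

    def fre(s):
        return kernel_pdf(kernel, s) * math.exp(-lam.real * s) * math.cos(lam.imag * s)

    def fim(s):
        return -kernel_pdf(kernel, s) * math.exp(-lam.real * s) * math.sin(lam.imag * s)

    re, re_err = quad(fre, kernel.tau1, kernel.tau2, limit=200, epsabs=1e-12, epsrel=1e-11)
    im, im_err = quad(fim, kernel.tau1, kernel.tau2, limit=200, epsabs=1e-12, epsrel=1e-11)
    scale = max(1.0, abs(re), abs(im))
    if max(re_err, im_err) > 1e-8 * scale:
        raise RuntimeError(
            f"kernel_laplace quadrature did not converge "
            f"(achieved {max(re_err, im_err):g})"
        )
    return complex(re, im)


# ---------------------------------------------------------------------------
# fixed-node quadrature view (used by the dispersion solver and simulator)
# ---------------------------------------------------------------------------

def laplace_nodes(kernel: KernelSpec, rule: str = "legendre",
                  num: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Fixed nodes ``s_j`` and weights ``w_j`` with ``sum w_j ~ int K = 1``,
    such that ``E(lam) ~ sum_j w_j exp(-lam s_j)``.

    ``rule`` is ``"legendre"`` (Gauss-Legendre, used by the dispersion solver;
    near machine precision for these smooth integrands) or ``"simpson"``
    (composite Simpson, the convention used by the time-domain simulator).
    Weights are normalized to sum exactly to one so that the discrete kernel
    is itself a probability distribution (this preserves homogeneous steady
    states of the simulator exactly).
    """
    if kernel.is_pointmass:
        return np.array([kernel.tau]), np.array([1.0])
    a, b = kernel.tau1, kernel.tau2
    if rule == "legendre":
        x, w = np.polynomial.legendre.leggauss(num)
        if kernel.family == KernelFamily.SKEW_GAUSSIAN:
            # split at the location: the cdf factor has a sharp transition
            # there for large |rho| that a single panel resolves poorly
            mid = kernel.mu
            s = np.concatenate([0.5 * (mid - a) * x + 0.5 * (mid + a),
                                0.5 * (b - mid) * x + 0.5 * (b + mid)])
            ws = np.concatenate([0.5 * (mid - a) * w, 0.5 * (b - mid) * w])
            wk = ws * kernel_pdf(kernel, s)
        else:
            s = 0.5 * (b - a) * x + 0.5 * (b + a)
            wk = 0.5 * (b - a) * w * kernel_pdf(kernel, s)
    elif rule == "simpson":
        if num < 3 or num % 2 == 0:
            raise ValueError("simpson rule needs an odd node count >= 3")
        s = np.linspace(a, b, num)
        h = (b - a) / (num - 1)
        w = np.ones(num)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        wk = h / 3.0 * w * kernel_pdf(kernel, s)
    else:
        raise ValueError(f"unknown quadrature rule {rule!r}")
    return s, wk / wk.sum()
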