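# Methods

## The model

Two morphogens, an activator `u` and an inhibitor `v`, react and diffuse on
the unit interval with no-flux (Neumann) boundaries,

    u_t = (eps^2 / L^2) u_xx + f(u, v, <F>),
    v_t = (1 / L^2)     v_xx + g(u, v, <G>),

where `<F> = ∫ K(s) F(u(t-s), v(t-s)) ds` is a delayed reaction step averaged
over a distribution `K(s)` of gene-expression delays on a finite window
`[tau1, tau2]` of strictly positive delays.  `eps^2` is the activator/inhibitor
diffusion ratio (default 0.001) and `L^2` a nondimensional domain-size
scaling (default 4.5).  Three kinetic schemes are implemented:

* **LI** (ligand-internalisation Schnakenberg): delay only in the activator
  autocatalysis, `f = a - u - 2u^2 v + 3<u^2 v>`, `g = b - u^2 v`, steady
  state `(a+b, b/(a+b)^2)`;
* **GM1** (Gierer–Meinhardt, fully delayed source): `f = a - bu + <u^2/v>`,
  `g = <u^2> - v`;
* **GM2** (instantaneous inhibitor in the source): `f = a - bu + <u^2>/v`,
  `g = <u^2> - v`; steady state `((a+1)/b, ((a+1)/b)^2)` for both GM forms.

## Delay kernels

Three families: a Dirac point mass at `tau` (fixed delay), a truncated
Gaussian with mean `tau` and spread `sigma` on `tau ± n sigma`, and a
truncated skew-normal with location `mu`, scale `omega` and skew `rho` on
`mu ± n omega`.  The half-width multiplier is `n = 3` throughout, so
positivity of the window bounds the spreads by `sigma_max = tau/3` and
`omega_max = mu/3`.  Truncation constants use the standard-normal cdf and,
for the skew family, the skew-normal cdf `Phi(x) - 2 T(x, rho)` with Owen's
T function evaluated by composite Simpson quadrature (100,001 nodes by
default; cross-checked against `scipy.special.owens_t` in the tests).

The mean of the truncated skew-normal is evaluated in closed form,

    mean = mu + omega * Psi_c * [ h(-n) - h(n)
           + (2 rho / (rho_hat sqrt(2 pi))) (Phi(rho_hat n) - Phi(-rho_hat n)) ],

with `h(z) = sqrt(2/pi) exp(-z^2/2) Phi(rho z)` and
`rho_hat = sqrt(1 + rho^2)`.  This form was derived from the antiderivative
of `z · 2 phi(z) Phi(rho z)` and agrees with adaptive quadrature of
`∫ s K(s) ds` to machine precision; a superficially similar form in which
the boundary terms carry the truncated (rather than standardized) density
is dimensionally inconsistent and does **not** match quadrature, and is not
used.  `location_from_mean` inverts the mean relation for `mu` (optionally
jointly with the coupling `omega = c · mu / n`) by bracketed Brent iteration
on `mu ∈ [tau/100, 100 tau]` with a 1e-10 residual tolerance; the solve is
performed on the closed admissible set, so the `omega_max` boundary itself
(`tau1 = 0`) can be evaluated even though kernel construction enforces
`tau1 > 0` strictly.

The kernel enters linear stability only through the transform
`E(lam) = ∫ K(s) e^(-lam s) ds`.  The public `kernel_laplace` uses the exact
`e^(-lam tau)` for point masses, the erf closed form for the Gaussian family
at real `lam`, and adaptive quadrature otherwise (the two cross-validated on
the real axis).  The dispersion solver instead evaluates `E` on fixed
Gauss–Legendre nodes (32 by default; the skew family uses two panels split
at `mu`, where the cdf factor turns sharply for large `|rho|`), which is
accurate to ~1e-13 for every admissible kernel used here and vectorizes over
parameter grids.  Node weights are normalised to unit mass so `E(0) = 1`
exactly.

## Linear stability

Perturbations `exp(lam t) cos(k pi x)` obey the transcendental dispersion
relation

    lam^2 + alpha_k lam + beta_k + (gamma_k lam + delta_k) E(lam)
          + chi_k E(lam)^2 = 0,

with per-model closed-form coefficients (validated against a
finite-difference linearisation oracle).  Wavenumbers are integers
`k ∈ [0, 50]`; a Turing instability requires `Re(lam_0) < 0` together with
`max_{k≠0} Re(lam_k) > 0`.

**Root finding.**  At zero delay the relation is an explicit quadratic.  The
rightmost root for a delayed kernel is tracked by homotopy continuation:
kernel time parameters are scaled from 0 to nominal in increments of at most
0.05 and both quadratic branches are corrected at each leg by a damped
complex Newton iteration (tolerance 1e-12 relative to the coefficient scale,
at most 100 iterations, step-halving safeguard).  Numerical choices that
matter:

* branches are seeded marginally off the real axis, and stalled iterates are
  retried with progressively larger imaginary kicks (1e-6 … 0.3, sign-split
  per branch): two real roots that collide during continuation re-emerge as
  a complex pair that a numerically real iterate can never reach;
* a branch that diverges left of `Re = -25` is abandoned — strongly damped
  quasi-polynomial roots do not persist under delay and cannot carry the
  rightmost root; a lost branch falls back to its sibling's verified iterate;
* a real-axis scan (`lam ∈ [-20, 20]`, step 0.05 on grids, 0.01 for the
  scalar API, bisection refinement) supplies real roots born away from the
  continued branches;
* the reported root is the rightmost *verified* candidate: its residual
  `|D_k|` must fall below 1e-8 (scaled); per-`k` entries with no verified
  root right of the search window are reported as missing and cannot carry
  the maximum.

The solver was validated against the explicit quadratic at zero delay
(1e-10), and spot-checked at delayed parameter points against an independent
dense complex-grid search with local refinement (exact agreement).

**Scans.**  Turing-space scans evaluate the dispersion solver vectorized
over an `(a, b)` grid; marginal contours (`Re(lam_0) = 0` and
`max_{k≠0} Re(lam_k) = 0`) are extracted by linear interpolation of sign
changes along grid lines, and contour coincidence is measured by Hausdorff
distance (tolerance: one grid cell).  The distributed-vs-fixed discrepancy
statistic is the grid maximum of `|max_k Re lam_k(gaussian) - max_k Re
lam_k(dirac)|`; the default production grid is 71 × 101 over
`(a, b) ∈ [0, 1.4] × [0, 2]` (tests use coarser grids).  Note that this
field is *not* smooth: along fold curves where two real k = 0 roots merge
into a complex pair, root sensitivity to kernel perturbations is amplified
by `1/|D'|`, so the grid maximum there depends visibly on grid placement.
The LI corner `a = b = 0` has no defined steady state and is masked.

## Time-domain simulation

Method of lines on `m` equally spaced points (default 500; tests and sweeps
use 200), three-point Laplacian, Neumann boundaries via reflected ghost
points, or homogeneous Dirichlet clamping of the activator in the mixed
case.  Time stepping is first-order IMEX: diffusion by backward Euler
(constant tridiagonal Thomas solves), reaction and delayed terms explicit,
default `dt = 1e-3`.  Past states live in a ring buffer of (value, slope)
knots — the slope is the explicit full right-hand side — queried by
piecewise-cubic Hermite interpolation (the newest segment falls back to
linear when its right slope is not yet available, reachable only when the
minimum delay is below `dt`).  The distributed integral uses composite
Simpson with 51 nodes over the truncation window, with discrete weights
normalised to unit mass so homogeneous steady states are preserved to
round-off.  A blow-up guard aborts when `|u|` or `|v|` exceeds 1e6.

Accuracy was established by (i) steady-state preservation for all models,
kernels and boundary sets; (ii) discrete mass conservation of the Neumann
diffusion operator (trapezoid weights, < 1e-10 drift); (iii) dominant-mode
growth rates matching the dispersion root within 5% (0.3% observed);
(iv) grid/step convergence (< 1% field change when halving `dt` and
doubling `m`); and (v) long-time profiles of the zero-delay ODE limit
agreeing with scipy's BDF integrator at `rtol = 1e-8` to < 0.05 in max norm,
including identical spike counts.

## Pattern metrics

The time-to-pattern `T*` is the first sampled time with
`max_x |u - u*| > u_T`, refined by linear interpolation; runs that never
cross report an infinite sentinel and are excluded (never imputed) from
sweep fits.  Mode amplitudes are type-I DCT coefficients of the activator
perturbation, normalised so `A cos(k pi x)` returns `A` at index `k` (the
Neumann eigenbasis).  The linear-theory prediction is
`T = ln(A_k(T*) / A_k(0)) / Re(lam_k)` with the real part of the dominant
root (which is real in the small-domain regime where the prediction is
used).  Spikes are strict interior maxima with prominence above 20% of the
field range, plus boundary points whose adjacent interior slope is negative;
by this rule `1 + 0.5 cos(4 pi x)` counts 3 (one interior, two boundary) and
`1 - 0.5 cos(8 pi x)` counts 4.  Delay sweeps share one seeded initial
perturbation across all delays and fit `T*(tau)` by ordinary least squares.

## Synthetic inputs

The generator reproduces the study's input conditions: multiplicative
Gaussian perturbations `u* (1 + r(x))` with per-point standard deviation
`sigma_IC ∈ {1e-5, 1e-3, 1e-2, 1e-1}` (default 0.01); constant histories
equal to the initial fields; oscillatory histories `u* (1 + r(x) sin(w t))`
with seeded Gaussian `r(x)` (defaults `w ∈ {1, 10}`, `r`-scale `sigma_IC` —
the study conditions leave these open, and the package fixes them once);
and a deterministic structured surrogate (a Gaussian bump, clearly labelled
synthetic) standing in for structured initial data whose exact algebraic
form is defined only in external appendices — it is used for qualitative
robustness checks only, never for quantitative targets.  Random fields come
from numpy's PCG64 generator, recorded in metadata, so identical seeds give
bit-identical fields across platforms.

## Problem sizes used by the tests

Tests run at desk scale as the package's own choice of problem size:
spatial grids `m = 64–200` (production default 500), `(a, b)` scan grids
from 8 × 11 (property checks) through 36 × 51 (contour geometry) to the full
71 × 101 for the discrepancy statistic, delay sweeps subsampled to five
delays spanning the stated ranges, and patterning horizons set from the
dispersion growth rate (e.g. `t_max = 6000` for the slowest GM2 delay).

## Known limitations

* The continuation/real-scan root finder can in principle miss a complex
  root born far from both continued branches and off the real axis; every
  reported root is residual-verified, but completeness is not guaranteed
  (the same caveat applies to any local method for transcendental
  dispersion relations).
* Roots left of `Re = -25` are outside the search region by design.
* The first-order IMEX stepper trades order for unconditional diffusion
  stability; accuracy rests on the convergence and growth-rate checks above
  rather than on a high-order integrator.
* The discrepancy statistic's grid maximum is grid-sensitive near fold
  curves of the `max_k Re(lam_k)` field (see above); values there should be
  read together with the field structure, not as a single universal number.
* Long-time spike counts are a nonlinear, seed-dependent outcome; the
  package reports them as measured (typically 2–4 spikes in the standard LI
  regime), with spike competition pruning onset patterns over time.
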