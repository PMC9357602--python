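# turingdelay

Gene expression is not instantaneous: transcription and translation impose
delays of minutes to hours, comparable to the timescale of developmental
patterning itself.  `turingdelay` is a Python package for analysing how such
delays — fixed, or distributed according to a truncated (skew-)Gaussian
kernel — affect Turing pattern formation in two-species reaction–diffusion
systems.  It is aimed at mathematical biologists studying delayed
activator–inhibitor models (Schnakenberg / Gierer–Meinhardt kinetics) and
provides, as a single tested pipeline:

* **delay kernels**: Dirac (fixed delay), truncated Gaussian `(tau, sigma)`
  and truncated skew-Gaussian `(mu, omega, rho)` distributions, their
  normalising constants, truncated means (closed form + quadrature), Owen's
  T function, and the Laplace-type transform `E(lam) = ∫ K(s) e^(-lam s) ds`;
* **linear stability**: the transcendental dispersion relation
  `lam² + alpha_k lam + beta_k + (gamma_k lam + delta_k) E(lam) + chi_k E(lam)² = 0`
  for the LI (ligand-internalisation Schnakenberg) and GM₁/GM₂
  (Gierer–Meinhardt) models, rightmost-root tracking by delay continuation,
  Turing-space scans over `(a, b)`, and distributed-vs-fixed discrepancy
  statistics;
* **a delay-PDE simulator**: method of lines with a three-point Laplacian,
  Neumann or mixed boundary conditions, ring-buffer history with cubic
  interpolation, Simpson quadrature of the distributed delay integral, and
  an IMEX time stepper (numba-compiled);
* **pattern metrics**: time-to-pattern `T*`, cosine-mode amplitudes (DCT-I),
  the linear-theory prediction `T = ln(A_T/A_0)/Re(lam_k)`, spike counting,
  and `T*`-vs-`tau` sweeps with linear fits;
* **synthetic scenarios**: seeded random initial conditions, history
  functions, and named presets for the standard parameter regimes.

## Worked example

How much does a delay slow patterning, and does the *shape* of the delay
distribution matter?

```python
import numpy as np
from turingdelay import KernelSpec, ModelSpec
from turingdelay.linear_stability import max_growth_rate
from turingdelay.dde_simulator import simulate
from turingdelay.pattern_metrics import time_to_pattern
from turingdelay.synthetic_scenarios import random_ic
from turingdelay.dde_simulator import Grid
from turingdelay.reaction_models import steady_state

model = ModelSpec("LI", a=0.1, b=0.9)          # eps2=0.001, L2=4.5

for kern in (KernelSpec.dirac(0.0),            # no delay
             KernelSpec.dirac(1.0),            # fixed delay, tau = 1
             KernelSpec.gaussian(1.0, 0.33)):  # distributed, same mean
    d = max_growth_rate(model, kern, k_max=50)
    print(kern.family.value, round(d.max_re, 4), d.argmax_k)
```

prints

```
dirac 0.716 4
dirac 0.1203 4
gaussian 0.1209 4
```

The fastest-growing mode is `k = 4` in all three cases; a unit mean delay
cuts its growth rate about six-fold (0.716 → 0.120), which is why patterns
take far longer to appear, while replacing the fixed delay by a broad
Gaussian distribution with the same mean moves the growth rate by less than
one percent (0.1203 → 0.1209).  A full simulation confirms the timing:

```python
us, _ = steady_state(model)
u0, v0 = random_ic(model, Grid(200), sigma_IC=0.01, seed=1)
for tau in (0.0, 1.0):
    sim = simulate(model, KernelSpec.dirac(tau), u0, v0,
                   t_end=60.0, dt=1e-3, out_dt=0.25, stop_threshold=0.1)
    print(tau, round(time_to_pattern(sim, us, threshold=0.1), 2))
```

```
0.0 5.21
1.0 27.07
```

so the delay pushes the onset of patterning from ~5 to ~27 time units with
everything else identical — and sweeps over `tau` (see
`turingdelay.pattern_metrics.tau_sweep`) show this lag grows *linearly*
with the mean delay, for all three kinetic schemes.

## Command line

```bash
turingdelay validate     --config run.cfg
turingdelay dispersion   --config run.cfg --out out/
turingdelay turing-scan  --config run.cfg --out out/
turingdelay discrepancy  --config run.cfg --out out/
turingdelay simulate     --config run.cfg --seed 1 --out out/
turingdelay tau-sweep    --config run.cfg --seed 1 --out out/
```

Configuration is a flat INI file with `[model]`, `[kernel]`, `[scenario]`
and `[analysis]` blocks (see `turingdelay/pipeline_cli.py` for the keys);
outputs are `#`-annotated CSV tables, an HDF5 field container and a JSON
manifest echoing the configuration and seed.

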