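# confcs — FCS in confined bacterial cells

Fluorescence correlation spectroscopy (FCS) measures protein mobility from
intensity fluctuations in a femtoliter confocal volume. Inside a
bacterium, the cell envelope confines the tracer on the same length scale
as the detection volume, and the standard anomalous-diffusion fit then
reports an exponent α ≈ 0.8–0.9 even for a purely Brownian tracer — an
artifact of confinement, not evidence of subdiffusion. `confcs` is a
toolkit for quantifying and correcting this artifact:

* **Simulation** — Brownian or fractional-Brownian point emitters confined
  in a spherocylindrical (capsule-shaped) cell, observed through a 3D
  Gaussian confocal volume; produces synthetic intensity traces with
  optional photobleaching.
* **Correlation** — symmetric-normalized ACF on a log-spaced lag grid,
  multi-segment-line photobleaching detrend, and the chromophore blinking
  multiplier.
* **Models & fitting** — the 3D anomalous-diffusion ACF, the unconfined
  Brownian ACF, and an Ornstein–Uhlenbeck (OU) confined-diffusion ACF in
  which harmonic trapping of width σ ≈ d/2 stands in for the cell width;
  Levenberg–Marquardt fitting, per-cell aggregation over six acquisitions,
  model comparison, Welch t-test.
* **Downstream analyses** — inverse power-law fit of diffusion coefficient
  versus molecular mass (D = A·MM^(−β)), Stokes–Einstein and two-bead
  (dumbbell) reference curves, and buoyant cell density from sedimentation
  profiles via the barometric relation 1/Z₀ = Δρ·V·g/k_BT.

The OU model's central formula, with τ_D = ω₀²/(4D) and
E(τ) = 1 − e^(−2Dτ/σ²):

    G(τ) = G_∞ + (1/N)·B(τ)
           · [1 + (2σ²/ω₀²)·E(τ)/(1 + ω₀²/(8σ²))]^(−1/2)   (lateral, confined)
           · [1 + τ/τ_D]^(−1/2)                             (long axis, free)
           · [1 + (2σ²/(S²ω₀²))·E(τ)/(1 + S²ω₀²/(8σ²))]^(−1/2)  (axial, confined)

where B(τ) = (1 − F_P + F_P·e^(−τ/τ_P))/(1 − F_P) is the blinking term,
N the mean focal occupancy and S = z₀/ω₀ the confocal aspect ratio. It has
one fewer free parameter than the anomalous model and returns the true
diffusion coefficient within ±5% on simulated confined Brownian data at
typical cell widths.

A packaged table of 29 sfGFP fusion constructs (masses 26.9–163 kDa, with
measured diffusion times, anomalous exponents, and — for the 18 freely
diffusing constructs — OU diffusion coefficients) feeds the mass-scaling
analysis.

## Worked example

Simulate one cell's acquisition series (Brownian tracer, D = 10 µm²/s,
cell 5 × 0.85 µm), correlate, apply blinking, and fit both models:

```python
import numpy as np
from confcs import (
    CellGeometry, MotionModel, SimulationConfig, simulate_trace,
    compute_acf, apply_blinking_factor, fit_acf,
)

config = SimulationConfig(
    n_particles=50, dt=1e-5, duration=20.0,
    geometry=CellGeometry(L=5.0, d=0.85),
    motion=MotionModel.brownian(10.0), seed=2,
)
trace = simulate_trace(config)              # 2_000_000 samples
acf = apply_blinking_factor(compute_acf(trace))

# fits of simulated data keep the simulation's own optics (S = z0/omega0 = 4)
anom = fit_acf(acf, model="anomalous", fixed={"S": 4.0})
ou = fit_acf(acf, model="ou", fixed={"omega0": 0.2, "S": 4.0, "sigma": 0.425})
print(f"anomalous: alpha = {anom.params['alpha']:.3f}, "
      f"tau_D = {anom.params['tau_D']*1e6:.0f} us")
print(f"OU:        D = {ou.params['D']:.2f} um^2/s")
```

Output:

```
anomalous: alpha = 0.883, tau_D = 863 us
OU:        D = 10.92 um^2/s
```

The Brownian tracer appears subdiffusive (α ≈ 0.88) under the anomalous
model purely because of confinement, while the OU model recovers the
ansatz D = 10 µm²/s to within single-trace statistical scatter (≈10%;
averaging the six acquisitions of a full measurement brings the mean
within ≈5%). The same chain is available from the shell:

```
confcs simulate --config sim.yaml --out trace.csv
confcs correlate trace.csv --blink --out acf.csv
confcs fit acf.csv --model ou --fix omega0=0.2,S=4,sigma=0.425 --out fit.json
confcs scaling-fit --out beta.json     # packaged construct table
```

The mass-scaling fit on the packaged table prints
`beta = 0.546 +- 0.041 over 18 constructs`: mobility falls off with mass
more steeply than the Stokes–Einstein exponent 0.4, and the two-bead
fusion-shape model accounts for much of the difference.

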