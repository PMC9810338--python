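# Methods

`confcs` implements an in-silico fluorescence correlation spectroscopy
(FCS) experiment for rod-shaped bacteria, together with the estimation and
model-fitting machinery used to analyze both simulated and experimental
intensity traces, and two downstream analyses (mass scaling of diffusion
and sedimentation-based buoyant density). This note records the models,
the default parameters and why they hold their values, the numerical
choices, and the known limitations.

## The physical picture

FCS infers mobility from the fluctuations of fluorescence emitted from a
diffraction-limited confocal volume. In a bacterium the cell width
(0.7–1 µm) is comparable to the axial extent of the detection volume, so a
purely Brownian tracer produces an autocorrelation function (ACF) that
*looks* subdiffusive when fitted with the standard anomalous-diffusion
model: the cell wall truncates long excursions and steepens the apparent
decay. The package quantifies this confinement artifact by simulation and
provides an Ornstein–Uhlenbeck (OU) confined-diffusion model that returns
the true diffusion coefficient directly.

## Simulation model (`geometry`, `simulate`)

Geometry. The cell is a spherocylinder: a cylinder of diameter `d` and
length `L − d` closed by hemispherical caps, long axis along x, centered at
the origin. Defaults `L = 5 µm` (filamentous, division-inhibited cells)
and `d = 0.85 µm` (the center of the typically observed 0.8–0.9 µm range).
Membership is evaluated as distance-to-axis-segment ≤ `d/2`; boundary
points count as inside.

Detection. A 3D Gaussian profile
`I_G = exp(−2[(Δx²+Δy²)/ω₀² + Δz²/z₀²])` with lateral 1/e² waist
`ω₀ = 0.2 µm` and axial waist `z₀ = 0.8 µm`. The focus sits on the long
axis, 1 µm from one cell pole (`x = −L/2 + 1`), mimicking the experimental
placement near a pole and away from the nucleoid.

Motion. `N = 50` independent point emitters (a particle density giving a
mean focal occupancy of order one) move by either

* Brownian steps: independent per-axis Gaussian increments of standard
  deviation `sqrt(2 D Δt)`, so the unconfined 3D MSD is `6 D t`. A step
  that would leave the cell is redrawn, up to 100 attempts, after which
  the particle stays in place and a diagnostic counter increments (the
  bound is never reached at practical step sizes). Specular reflection is
  available as an alternative boundary rule and yields the same stationary
  occupancy — both tested.
* Fractional Brownian motion: increments are fractional Gaussian noise
  with per-axis covariance
  `(Γα/2)(|t+Δt|^α + |t−Δt|^α − 2|t|^α)`, hence per-axis MSD `Γα t^α` and
  3D MSD `3 Γα t^α` unconfined. Sampling uses Davies–Harte circulant
  embedding: the covariance sequence is embedded in a circulant matrix
  whose FFT gives the (provably nonnegative, checked at runtime)
  eigenvalue spectrum; one complex FFT of white noise yields two
  independent exact sample paths. Confinement uses reflection only
  (redraw would break the increment correlation structure): an outside
  point is folded radially through the capsule surface about the nearest
  axis point. `gamma_from_diffusion(D, α)` picks `Γα` so the fBm MSD
  crosses the Brownian MSD of coefficient `D` at 1 ms, the lag scale that
  dominates the ACF decay at these diffusivities.

Initialization is uniform over the cell by rejection sampling — the
stationary law for both boundary rules — so no burn-in is used. Traces
are deterministic given the configuration seed: bulk Gaussian steps come
from a PCG64 stream and boundary redraws from a separately seeded stream,
both derived from the config seed.

The trace is the per-step sum of `I_G` over emitters. Photophysics is
*not* simulated per emitter; the chromophore dark-state (blinking)
component is applied at the ACF level (below), matching how the simulated
curves are meant to be compared with fitted experimental ones. A
first-order photobleaching option (`bleach_rate`, default 0) irreversibly
darkens an emitter with probability `bleach_rate · I_G · Δt` per step; it
exists to exercise the detrending correction and is off in all headline
analyses.

Time step. The reference step is `Δt = 10⁻⁶ s`; the packaged analyses run
at `Δt = 10⁻⁵ s`, which leaves the ACF unchanged on the ≥10 µs lags that
are fitted while keeping a full six-acquisition simulation tractable on a
single core (per-axis step ≈ 17 nm at D = 15 µm²/s, still ≪ ω₀ and d).

## ACF estimation (`acf`)

The estimator is the symmetric-normalized correlator
`C(dt) = ⟨I(t+dt)I(t)⟩/(⟨I(t+dt)⟩⟨I(t)⟩) − 1`, with means over the
overlapping segment, evaluated on a log-spaced grid (16 points per decade)
from one sample interval (simulated data; experimental curves should start
at 2 µs to avoid detector afterpulsing — `min_lag` is a parameter) up to
one tenth of the trace duration. This computes the defined estimator
exactly; no multi-tau binning approximation is involved.

Blinking. Simulated ACFs are multiplied by
`1 + (a/(1+a))·exp(−dt/τ_H)` with `a = 0.1`, `τ_H = 25 µs` — algebraically
identical to the dark-state factor `(1 − F_P + F_P e^(−dt/τ_P))/(1 − F_P)`
at `F_P = 1/12`, so fitted `F_P` values near 1/12 indicate
self-consistency.

Photobleaching detrend. The slow intensity decay is fitted on a
coarse-binned trace (64 bins) by a *continuous* piecewise-linear trend with
2 segments (interior knot chosen by SSE grid search over bin boundaries;
the segment count and bin count are settings). The correction is the
variance-preserving square-root form
`I_c = I/sqrt(f/f₀) + f₀(1 − sqrt(f/f₀))`,
which restores both the mean and the fluctuation amplitude of a stationary
process; a fitted trend that touches zero is an error, not silently
clipped. Detrending is idempotent to <1% on the ACF.

## ACF models (`models`)

All models share the blinking factor and an offset `G_∞`, and satisfy
`G(0⁺) − G_∞ = 1/(N(1−F_P))`.

* Anomalous diffusion:
  `G = G_∞ + (blink/N)·[1+(τ/τ_D)^α]⁻¹·[1+(τ/τ_D)^α/S²]^(−1/2)`,
  with `S = z₀/ω₀`. `α = 1` is the unconfined Brownian model.
* OU confined diffusion: Brownian motion in a harmonic potential of width
  `σ` across the two short cell axes, free along the cell length. With
  `τ_D = ω₀²/(4D)` and `E(τ) = 1 − exp(−2Dτ/σ²)`, each confined axis of
  detection waist `w` (lateral `w = ω₀`, axial `w = Sω₀`) contributes
  `[1 + (2σ²/w²)·E(τ)/(1 + w²/(8σ²))]^(−1/2)`, and the free axis
  `[1 + τ/τ_D]^(−1/2)`.
  The factorization is pinned by three analytic requirements, asserted in
  the test suite: both confined axes share `E(τ)`; `σ → ∞` reduces the
  model to the unconfined Brownian one to better than 10⁻⁹ relative over
  seven decades of lag; and the axial factor is the lateral one under
  `ω₀ → Sω₀`.
* `τ_D ↔ D` conversion: `D = ω₀²/(4 τ_D)`.

## Fitting (`fitting`)

Levenberg–Marquardt least squares (lmfit) with relative tolerance 10⁻¹⁰.
Fixed-parameter conventions for experimental-style fits: `τ_P = 25 µs`,
`S = 8`; the OU model additionally fixes `ω₀ = 0.19 µm` and
`σ = 0.42 µm = d/2`, leaving `{N, F_P, D, G_∞}` free — one fewer free
parameter than the anomalous model's `{N, F_P, τ_D, α, G_∞}`. When fitting
simulated data the optics are fixed to the simulation's own values
(`ω₀ = 0.2`, `z₀ = 0.8`, so `S = 4`) and `σ = d/2` of the simulated cell.
`F_P` is left free (the experimental procedure fits it) even though the
blinking amplitude of simulated curves is known; fixing it is a one-line
override.

Fitting simulated curves with a different aspect ratio than the one that
generated them biases the anomalous exponent (at d = 0.9 µm, S = 8 instead
of the generating S = 4 shifts mean fitted α from 0.874 to 0.909), so the
pipeline holds the detection geometry of simulated-data fits at the
simulation's own ansatz values unless explicitly overridden.

Initialization: `G_∞` from the last-decade mean, amplitude → `N`, `τ_D`
from the half-amplitude lag, `α = 0.85`, `F_P = 0.1`. Bounds:
`α ∈ [0.3, 1.3]`, `F_P ∈ [0, 0.5]`; parameters ending on a bound are
flagged. Fits are unweighted by default; per-lag SEM weights (from
replicate averaging) are optional. Model comparison reports SSR and AIC;
the curves here are strongly correlated across lags, so AIC is a ranking
device, not a calibrated evidence measure.

Aggregation mirrors the acquisition protocol: six sequential 20-s traces
per cell, one fit each, arithmetic mean ± SEM over converged fits.
The two-component variant fixes the fast species entirely (weight 15%,
its `τ_D` and `α`) and fits the slow one — the free-tag contamination
control. Group comparisons use the two-tailed Welch t-test with
Welch–Satterthwaite degrees of freedom (p = 1 by convention when both
samples are constant and equal).

## Mass scaling (`scaling`)

The constructs with a measured FCS diffusion coefficient (the 18 rows of
the packaged table with a populated D column — the operational definition
of "apparently freely diffusing") are fitted with `D = A·MM^(−β)` by
nonlinear least squares, weighted `1/SEM²`; the unweighted variant is an
option and both land in β ∈ [0.45, 0.65] on the packaged table. The
Stokes–Einstein reference uses `R ∝ MM^0.4` (empirical exponent for
not-perfectly-globular proteins) anchored at free sfGFP
(26.9 kDa, 14.7 µm²/s).

Dumbbell model. A GFP fusion is closer to two tethered globules than to
one sphere. The package models it as a rigid two-bead object with
orientationally averaged Oseen coupling: bead mobilities `μᵢ ∝ 1/aᵢ`,
coupling `T ∝ 1/ℓ` with `ℓ = a₁ + a₂ + linker`, and rigid-body mobility

    D = kT·(μ₁μ₂ − T²)/(μ₁ + μ₂ − 2T),

anchored so the isolated tag reproduces its measured D (this absorbs
`kT/6πη` into one constant). The form satisfies the required limits:
partner radius → 0 gives the single-sphere value; equal beads give the
Kirkwood dimer result `D = (kT/2)(μ + T)`; D decreases monotonically in
either radius. Defaults: tag radius 2.4 nm, bead radii `∝ MM^0.4`, linker
0.5 nm (short flexible linker, treated as a rigid spacer — an
approximation that matters little because D depends on ℓ only through the
weak 1/ℓ coupling).

## Sedimentation (`sedimentation`)

Neutrally-density-matched cell suspensions settle to the barometric
profile `n(z) = n₀ e^(−z/Z₀)` with `1/Z₀ = Δρ·V·g/(k_BT)`. The decay
length is fitted on the window `z ∈ [0.25, 0.8] × 50 µm` (channel interior,
away from floor and ceiling artifacts) by Poisson maximum likelihood
(Newton iterations on the concave log-likelihood; Fisher-information
standard errors) — weighted least squares against observed counts is
biased toward downward fluctuations at low counts, so the likelihood is
used directly (log-linear regression remains an option).
A fitted inverse decay length consistent with zero flags `Z₀ = ∞`,
mapping to `Δρ = 0`. Units are audited by a dimensional test vector:
`Z₀` in µm, `V` in µm³, `g = 9.81 m/s²`, `k_BT = 4.11 pN·nm` (25 °C)
give Δρ in kg/m³ ≡ g/L. Cell volume uses the capsule formula
`V = πd³/6 + (L−d)πd²/4`. The profile generator samples bin counts
multinomially from the barometric law on bin centers (1 µm default bins,
the z-stack step).

## Problem sizes and what the tests show

The packaged headline analyses (the acceptance script) use the full
protocol at `Δt = 10⁻⁵ s`: six 20-s traces per condition, D ∈ {5, 10, 15}
µm²/s for OU validation, diameters 0.8/0.9 µm for the apparent-anomaly
band, and six fBm traces at ansatz α = 0.95. The pytest suite runs the
OU-recovery and confinement-anomaly checks at the same six 20-s
acquisitions (trace duration is never shortened: a narrower lag window
shifts the long-lag part of the fit and with it the fitted exponent); the
fBm check uses three acquisitions, its margin to the asserted bound being
wide. Statistical property tests state tolerances that account for their
Monte-Carlo error.

The σ ≃ d/2 calibration is reproduced the way a calibration must be run:
every parameter except σ is held at its ansatz value, including the focal
occupancy N computed from the PSF moments over the cell,
G(0) = (m₂ − m₁²)/(N_p·m₁²) with m_k the k-th moment of the detection
profile under the uniform particle law. Scanning σ with the nuisance
parameters free lets the free D compensate and is not a calibration.

On simulated confined-Brownian data the OU fit carries a small positive
bias that grows toward low D (≈ +4–6% at D = 5 µm²/s, ≈ +2% at
D = 15 µm²/s at d = 0.85 µm): the harmonic approximation is least accurate
when the diffusion time approaches the confinement relaxation time. The
±5% accuracy statement should be read with that gradient in mind; the
boundary rule, time step, trace length, and the handling of the blinking
fraction were each varied and none removes it.

Passing tests demonstrate internal consistency of the simulation,
estimator and models, and reproduce the confinement phenomenology on
synthetic data. They do not validate effects absent from the generator:
real cells have nucleoid exclusion, crowding heterogeneity, membrane
adsorption, detector afterpulsing and shot noise, cell-to-cell variability
in geometry and expression level, and drift — none of which are emulated
(shot noise can be approximated by Poisson-sampling the trace, but the
headline analyses use noiseless detection).

## Known limitations

* The OU model treats hard-wall confinement as a harmonic trap; its σ≃d/2
  calibration is itself established by simulation, and the ±5% accuracy
  claim holds for the tested diameter range (0.7–1 µm), not arbitrarily
  narrow cells.
* The redraw boundary rule slightly distorts the step distribution near
  the wall (it conditions on staying inside); reflection is available and
  statistically indistinguishable at these step sizes.
* Davies–Harte requires the full-trace covariance embedding in memory
  (two FFTs of 2n per particle per pair of axes); traces much longer than
  ~10⁷ steps per particle become FFT-bound.
* The dumbbell model is a far-field (Oseen) approximation evaluated at
  contact-scale separations; it is a shape correction, not a boundary-
  element hydrodynamic calculation.
* AIC comparisons on correlated residuals overstate decisiveness; they are
  used only to rank models on equal footing.
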