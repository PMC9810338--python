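"""Closed-form FCS autocorrelation models.

Three models for the normalized intensity ACF of fluorophores seen through
a 3D Gaussian confocal volume of lateral waist ω₀ and aspect ratio
S = z₀/ω₀, each including the protonation–deprotonation (blinking) term of
GFP-family chromophores:

* anomalous diffusion — MSD ∝ t^α; the diffusion part is
  [1 + (τ/τ_D)^α]⁻¹ [1 + (τ/τ_D)^α/S²]^(−1/2);
* unconfined Brownian — the α = 1 special case;
* Ornstein–Uhlenbeck (OU) confined diffusion — Brownian motion trapped in
  a harmonic potential of width σ across the two short cell axes while the
  long axis stays free; with τ_D = ω₀²/(4D) and the saturating factor
  E(τ) = 1 − exp(−2Dτ/σ²), each confined axis of detection waist w
  contributes [1 + (2σ²/w²)·E(τ)/(1 + w²/(8σ²))]^(−1/2).

The OU parsing is pinned by three analytic requirements: both confined
axes share E(τ) (same σ and D); the σ → ∞ limit reduces exactly to the
unconfined Brownian model; and the axial factor follows from the lateral
one under ω₀ → Sω₀.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ACFModelParams",
    "blinking_term",
    "anomalous_diffusion_factor",
    "eval_anomalous_acf",
    "eval_brownian_acf",
    "eval_ou_acf",
    "eval_two_component_acf",
    "tau_to_D",
    "D_to_tau",
    "MODEL_NAMES",
]

MODEL_NAMES = ("brownian", "anomalous", "ou")

#: fixed-parameter conventions used for fitting experimental curves
DEFAULT_TAU_P = 25e-6  # s, sfGFP protonation-deprotonation lifetime
DEFAULT_S = 8.0  # confocal aspect ratio z0/omega0
DEFAULT_OMEGA0 = 0.19  # µm, lateral beam waist (OU model)
DEFAULT_SIGMA = 0.42  # µm, harmonic confinement width = d/2


@dataclass
class ACFModelParams:
    """Parameter set shared by the ACF models (unused entries may be None).

    N       : mean occupancy of the confocal volume
    F_P     : dark-state fraction, in [0, 1)
    tau_P   : blinking lifetime (s)
    tau_D   : diffusion (residence) time (s)
    alpha   : anomalous-diffusion exponent
    G_inf   : long-lag offset of the ACF
    S       : confocal aspect ratio z0/omega0
    omega0  : lateral waist (µm, OU model)
    sigma   : harmonic confinement width (µm, OU model)
    D       : diffusion coefficient (µm²/s, OU model; tau_D = omega0²/(4D))
    """

    N: float = 1.0
    F_P: float = 0.0
    tau_P: float = DEFAULT_TAU_P
    tau_D: float | None = None
    alpha: float | None = None
    G_inf: float = 0.0
    S: float = DEFAULT_S
    omega0: float | None = None
    sigma: float | None = None
    D: float | None = None

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not 0.0 <= self.F_P < 1.0:
            raise ValueError("F_P must lie in [0, 1)")
        if self.tau_P <= 0:
            raise ValueError("tau_P must be positive")
        if self.S < 1.0:
            raise ValueError("S must be >= 1")
        if self.tau_D is not None and self.tau_D <= 0:
            raise ValueError("tau_D must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.omega0 is not None and self.omega0 <= 0:
            raise ValueError("omega0 must be positive")


def blinking_term(tau, F_P: float, tau_P: float = DEFAULT_TAU_P):
    """(1 − F_P + F_P·e^{−τ/τ_P}) / (1 − F_P); equals 1/(1 − F_P) at τ = 0."""
    if not 0.0 <= F_P < 1.0:
        raise ValueError("F_P must lie in [0, 1)")
    if tau_P <= 0:
        raise ValueError("tau_P must be positive")
    tau = np.asarray(tau, dtype=float)
    return (1.0 - F_P + F_P * np.exp(-tau / tau_P)) / (1.0 - F_P)


def anomalous_diffusion_factor(tau, tau_D: float, alpha: float, S: float = DEFAULT_S):
    """The 3D anomalous-diffusion decay
    [1 + (τ/τ_D)^α]⁻¹ · [1 + (τ/τ_D)^α / S²]^(−1/2)."""
    if tau_D <= 0:
        raise ValueError("tau_D must be positive")
    tau = np.asarray(tau, dtype=float)
    u = (tau / tau_D) ** alpha
    return 1.0 / (1.0 + u) / np.sqrt(1.0 + u / S**2)


def eval_anomalous_acf(
    tau,
    N: float,
    tau_D: float,
    alpha: float,
    G_inf: float = 0.0,
    F_P: float = 0.0,
    tau_P: float = DEFAULT_TAU_P,
    S: float = DEFAULT_S,
):
    """Anomalous-diffusion ACF with blinking:

    G(τ) = G_∞ + (1/N)·blink(τ)·[1+(τ/τ_D)^α]⁻¹·[1+(τ/τ_D)^α/S²]^(−1/2).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    return G_inf + blinking_term(tau, F_P, tau_P) / N * anomalous_diffusion_factor(
        tau, tau_D, alpha, S
    )


def eval_brownian_acf(
    tau,
    N: float,
    tau_D: float,
    G_inf: float = 0.0,
    F_P: float = 0.0,
    tau_P: float = DEFAULT_TAU_P,
    S: float = DEFAULT_S,
):
    """Unconfined 3D Brownian ACF — the α = 1 anomalous model."""
    return eval_anomalous_acf(tau, N, tau_D, 1.0, G_inf, F_P, tau_P, S)


def eval_ou_acf(
    tau,
    N: float,
    D: float,
    G_inf: float = 0.0,
    F_P: float = 0.0,
    tau_P: float = DEFAULT_TAU_P,
    S: float = DEFAULT_S,
    omega0: float = DEFAULT_OMEGA0,
    sigma: float = DEFAULT_SIGMA,
):
    """Ornstein–Uhlenbeck confined-diffusion ACF.

    The two short cell axes (detection waists ω₀ and Sω₀) are harmonically
    confined with width σ; the long axis is free.  With τ_D = ω₀²/(4D) and
    E(τ) = 1 − e^{−2Dτ/σ²}:

    G(τ) = G_∞ + (blink(τ)/N)
           · [1 + (2σ²/ω₀²)·E/(1 + ω₀²/(8σ²))]^(−1/2)
           · [1 + τ/τ_D]^(−1/2)
           · [1 + (2σ²/(S²ω₀²))·E/(1 + S²ω₀²/(8σ²))]^(−1/2)
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if D <= 0:
        raise ValueError("D must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    tau = np.asarray(tau, dtype=float)
    tau_D = omega0**2 / (4.0 * D)
    E = -np.expm1(-2.0 * D * tau / sigma**2)
    lat = 1.0 + (2.0 * sigma**2 / omega0**2) * E / (1.0 + omega0**2 / (8.0 * sigma**2))
    w_ax = S * omega0
    ax = 1.0 + (2.0 * sigma**2 / w_ax**2) * E / (1.0 + w_ax**2 / (8.0 * sigma**2))
    free = 1.0 + tau / tau_D
    return G_inf + blinking_term(tau, F_P, tau_P) / N / np.sqrt(lat * free * ax)


def eval_two_component_acf(
    tau,
    N: float,
    weight_fast: float,
    tau_D_fast: float,
    alpha_fast: float,
    tau_D_slow: float,
    alpha_slow: float,
    G_inf: float = 0.0,
    F_P: float = 0.0,
    tau_P: float = DEFAULT_TAU_P,
    S: float = DEFAULT_S,
):
    """Two-species anomalous-diffusion ACF with a shared blinking term:

    G = G_∞ + (blink/N)·[w·g(τ; fast) + (1−w)·g(τ; slow)].
    """
    if not 0.0 <= weight_fast <= 1.0:
        raise ValueError("weight_fast must lie in [0, 1]")
    g = weight_fast * anomalous_diffusion_factor(tau, tau_D_fast, alpha_fast, S) + (
        1.0 - weight_fast
    ) * anomalous_diffusion_factor(tau, tau_D_slow, alpha_slow, S)
    return G_inf + blinking_term(tau, F_P, tau_P) / N * g


def tau_to_D(tau_D: float, omega0: float) -> float:
    """Diffusion coefficient from residence time: D = ω₀²/(4 τ_D)."""
    if tau_D <= 0 or omega0 <= 0:
        raise ValueError("tau_D and omega0 must be positive")
    return omega0**2 / (4.0 * tau_D)


def D_to_tau(D: float, omega0: float) -> float:
    """Residence time from diffusion coefficient: τ_D = ω₀²/(4D)."""
    if D <= 0 or omega0 <= 0:
        raise ValueError("D and omega0 must be positive")
    return omega0**2 / (4.0 * D)
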