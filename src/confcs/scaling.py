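"""Mass dependence of cytoplasmic diffusion.

The per-construct diffusion coefficients are fitted with an inverse power
law D = A·MM^(−β).  For comparison, Stokes–Einstein reference curves use
the empirical radius–mass scaling R ∝ MM^β with β ≈ 0.4 for globular
proteins, and a rigid two-bead (dumbbell) hydrodynamic model captures the
shape of GFP-fusion constructs, where the tag and the target protein are
tethered by a short linker.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ConstructRecord",
    "PowerLawFit",
    "load_construct_table",
    "records_with_diffusion",
    "fit_power_law",
    "stokes_einstein_curve",
    "dumbbell_diffusion",
    "SFGFP_MASS_KDA",
    "SFGFP_D_UM2_S",
]

SFGFP_MASS_KDA = 26.9
SFGFP_D_UM2_S = 14.7  # FCS (OU-model) diffusion coefficient of free sfGFP


@dataclass(frozen=True)
class ConstructRecord:
    """One fluorescent-fusion construct: mass and mobility."""

    name: str
    mm: float  # molecular mass of the fusion (kDa)
    d_value: float  # diffusion coefficient (µm²/s) or mobility 1/τ_D (1/s)
    sem: float = 0.0
    n_cells: int = 0

    def __post_init__(self) -> None:
        if self.mm <= 0 or self.d_value <= 0 or self.sem < 0:
            raise ValueError("mm and d_value must be positive, sem nonnegative")


@dataclass(frozen=True)
class PowerLawFit:
    """Result of the inverse power-law fit D = A·MM^(−β)."""

    amplitude: float
    beta: float
    beta_se: float
    covariance: np.ndarray
    weighted: bool

    def predict(self, mm):
        return self.amplitude * np.asarray(mm, dtype=float) ** (-self.beta)


def load_construct_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the per-construct table (packaged fixture by default).

    Columns: name, mm_kda, n_cells_fcs, tau_d_us, tau_d_sem_us, alpha,
    alpha_sem, d_fcs_um2_s, d_fcs_sem_um2_s, n_cells_frap, d_frap_um2_s,
    d_frap_sem_um2_s.  Rows without an FCS diffusion coefficient have an
    empty d_fcs column.
    """
    if path is None:
        ref = resources.files("confcs") / "data" / "construct_table.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def records_with_diffusion(table: pd.DataFrame) -> list[ConstructRecord]:
    """The constructs with a measured FCS diffusion coefficient — the subset
    entering the mass-scaling fit."""
    sub = table.dropna(subset=["d_fcs_um2_s"])
    return [
        ConstructRecord(
            name=row["name"],
            mm=float(row["mm_kda"]),
            d_value=float(row["d_fcs_um2_s"]),
            sem=float(row["d_fcs_sem_um2_s"]),
            n_cells=int(row["n_cells_fcs"]),
        )
        for _, row in sub.iterrows()
    ]


def fit_power_law(records: list[ConstructRecord], weighted: bool = True) -> PowerLawFit:
    """Nonlinear least-squares fit of D = A·MM^(−β).

    With ``weighted`` (default), residuals are weighted by 1/SEM² where
    SEMs are available.  Requires at least three records with distinct
    masses.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    mm = np.array([r.mm for r in records])
    d = np.array([r.d_value for r in records])
    sem = np.array([r.sem for r in records])
    if np.allclose(mm, mm[0]):
        raise ValueError("all records share one molecular mass; fit is degenerate")
    sigma = None
    if weighted and np.all(sem > 0):
        sigma = sem
    popt, pcov = curve_fit(
        lambda m, A, beta: A * m ** (-beta), mm, d, p0=[d.max() * mm.min() ** 0.5, 0.5],
        sigma=sigma, maxfev=10000,
    )
    return PowerLawFit(
        amplitude=float(popt[0]),
        beta=float(popt[1]),
        beta_se=float(np.sqrt(pcov[1, 1])),
        covariance=pcov,
        weighted=sigma is not None,
    )


def stokes_einstein_curve(
    mm_grid,
    anchor: tuple[float, float] = (SFGFP_MASS_KDA, SFGFP_D_UM2_S),
    beta_se: float = 0.4,
):
    """Stokes–Einstein prediction D(MM) = D_ref·(MM/MM_ref)^(−β) anchored at
    a reference construct, with the radius–mass exponent β (default 0.4)."""
    mm_ref, d_ref = anchor
    if mm_ref <= 0 or d_ref <= 0:
        raise ValueError("anchor masses and D must be positive")
    return d_ref * (np.asarray(mm_grid, dtype=float) / mm_ref) ** (-beta_se)


def _bead_radius(mm: float, mm_ref: float, r_ref: float, beta_radius: float) -> float:
    return r_ref * (mm / mm_ref) ** beta_radius


def dumbbell_diffusion(
    mm_partner: float,
    mm_gfp: float = SFGFP_MASS_KDA,
    d_gfp: float = SFGFP_D_UM2_S,
    r_gfp_nm: float = 2.4,
    beta_radius: float = 0.4,
    linker_nm: float = 0.5,
) -> float:
    """Effective diffusion coefficient (µm²/s) of two tethered beads.

    The fusion is modeled as a rigid dumbbell of two hydrodynamically
    coupled spheres — the fluorescent tag (radius anchored to the measured
    single-sphere value ``d_gfp``) and the target protein, radii scaling as
    R ∝ MM^β.  At the orientationally averaged Oseen level, with bead
    mobilities μᵢ ∝ 1/aᵢ and coupling T ∝ 1/ℓ (ℓ = a₁ + a₂ + linker), the
    rigid-body mobility is

        D = kT·(μ₁μ₂ − T²)/(μ₁ + μ₂ − 2T),

    which reduces to the single-sphere value when the partner radius
    vanishes and to the Kirkwood dimer result for equal beads.
    """
    if mm_gfp <= 0:
        raise ValueError("mm_gfp must be positive")
    if mm_partner < 0:
        raise ValueError("mm_partner must be nonnegative")
    a1 = r_gfp_nm
    if a1 <= 0:
        raise ValueError("bead radii must be positive")
    if mm_partner == 0.0:
        return d_gfp
    a2 = _bead_radius(mm_partner, mm_gfp, r_gfp_nm, beta_radius)
    ell = a1 + a2 + linker_nm
    c = d_gfp * a1  # kT/(6πη) in µm²/s·nm, anchored to the tag's measured D
    mu1, mu2, t = c / a1, c / a2, c / ell
    return (mu1 * mu2 - t * t) / (mu1 + mu2 - 2.0 * t)
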