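"""Cell and confocal-volume geometry.

The bacterial cell is idealized as a spherocylinder (capsule): a cylinder of
diameter ``d`` and length ``L - d`` closed by hemispherical caps, with the
long axis along x and the cell centered at the origin.  The confocal
detection volume is a 3D Gaussian with lateral 1/e^2 waist ``omega0`` and
axial waist ``z0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellGeometry",
    "ConfocalVolume",
    "inside_spherocylinder",
    "spherocylinder_volume",
    "psf_intensity",
]


def spherocylinder_volume(length: float, diameter: float) -> float:
    """Volume (µm³) of a cylinder of length ``L - d`` closed by hemispherical
    caps of diameter ``d``: V = πd³/6 + (L − d)πd²/4."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if length < diameter:
        raise ValueError("total length L must be >= diameter d")
    d = diameter
    return np.pi * d**3 / 6.0 + (length - d) * np.pi * d**2 / 4.0


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylindrical cell of total length ``L`` and diameter ``d`` (µm)."""

    L: float = 5.0
    d: float = 0.85

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("cell diameter d must be positive")
        if self.L < self.d:
            raise ValueError("cell length L must be >= diameter d")

    @property
    def radius(self) -> float:
        return self.d / 2.0

    @property
    def half_cylinder_length(self) -> float:
        """Half-length of the cylindrical section, (L − d)/2."""
        return (self.L - self.d) / 2.0

    @property
    def volume(self) -> float:
        return spherocylinder_volume(self.L, self.d)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test; boundary points count as inside."""
        return inside_spherocylinder(points, self)


def inside_spherocylinder(p: np.ndarray, geom: CellGeometry) -> np.ndarray | bool:
    """True iff point(s) ``p`` (µm, shape (3,) or (n, 3)) lie inside the cell.

    A point is inside when its distance to the axis segment
    {(x, 0, 0) : |x| <= (L − d)/2} is at most d/2.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    half = geom.half_cylinder_length
    r2 = geom.radius**2
    dx = np.maximum(np.abs(pts[:, 0]) - half, 0.0)
    inside = dx**2 + pts[:, 1] ** 2 + pts[:, 2] ** 2 <= r2
    return bool(inside[0]) if single else inside


@dataclass(frozen=True)
class ConfocalVolume:
    """Gaussian confocal detection volume.

    omega0, z0 : lateral and axial 1/e² waists (µm)
    center     : position of the focus (µm)
    """

    omega0: float = 0.2
    z0: float = 0.8
    center: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        if not self.omega0 > 0:
            raise ValueError("omega0 must be positive")
        if self.z0 < self.omega0:
            raise ValueError("z0 must be >= omega0")

    @property
    def aspect_ratio(self) -> float:
        """S = z0/omega0."""
        return self.z0 / self.omega0


def psf_intensity(p: np.ndarray, confocal: ConfocalVolume) -> np.ndarray | float:
    """Normalized Gaussian excitation/detection profile in [0, 1].

    I(x, y, z) = exp(−2[(Δx² + Δy²)/ω₀² + Δz²/z₀²]) relative to the focus.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    c = np.asarray(confocal.center, dtype=float)
    dx, dy, dz = (pts - c).T
    val = np.exp(-2.0 * ((dx**2 + dy**2) / confocal.omega0**2 + dz**2 / confocal.z0**2))
    return float(val[0]) if single else val
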