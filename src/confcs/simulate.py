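"""Brownian-dynamics simulation of an in-silico FCS experiment.

Point emitters diffuse inside a spherocylindrical cell and are observed
through a 3D Gaussian confocal volume; the summed detection-profile
intensity of all emitters, sampled every time step, is the synthetic
fluorescence trace.  Two motion models are available:

* ``brownian`` — independent Gaussian steps of per-axis standard deviation
  sqrt(2 D Δt); steps that would leave the cell are redrawn (or specularly
  reflected), which leaves the uniform distribution stationary.
* ``fbm`` — fractional Brownian motion built from fractional Gaussian noise
  (Davies–Harte circulant embedding) with per-axis increment covariance
  (Γα/2)(|t+Δt|^α + |t−Δt|^α − 2|t|^α), so the unconfined 3D MSD is
  3 Γα t^α; confinement is imposed by specular folding at the cell wall.

Optionally each emitter can photobleach irreversibly with a rate
proportional to its instantaneous excitation intensity, to emulate the
slow intensity decay seen in live-cell acquisitions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.fft as scipy_fft
from numba import njit

from .geometry import CellGeometry, ConfocalVolume, inside_spherocylinder

__all__ = [
    "MotionModel",
    "SimulationConfig",
    "IntensityTrace",
    "SimulationReport",
    "step_brownian",
    "generate_fgn",
    "gamma_from_diffusion",
    "sample_uniform_positions",
    "simulate_trace",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class MotionModel:
    """Single-particle motion law.

    Exactly one of the two parameterizations is active:
    ``brownian`` uses the diffusion coefficient ``D`` (µm²/s, per-axis MSD
    2Dt); ``fbm`` uses the subdiffusion exponent ``alpha_ansatz`` in (0, 1]
    and generalized diffusion coefficient ``Gamma`` (µm²/s^α, per-axis MSD
    Γ t^α).
    """

    kind: Literal["brownian", "fbm"] = "brownian"
    D: float | None = 10.0
    alpha_ansatz: float | None = None
    Gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "brownian":
            if self.D is None or self.D < 0:
                raise ValueError("brownian motion requires D >= 0")
            if self.alpha_ansatz is not None or self.Gamma is not None:
                raise ValueError("brownian motion takes only D")
        elif self.kind == "fbm":
            if self.alpha_ansatz is None or self.Gamma is None:
                raise ValueError("fbm requires alpha_ansatz and Gamma")
            if not 0.0 < self.alpha_ansatz <= 1.0:
                raise ValueError("alpha_ansatz must lie in (0, 1]")
            if self.Gamma <= 0:
                raise ValueError("Gamma must be positive")
            if self.D is not None:
                raise ValueError("fbm takes (alpha_ansatz, Gamma), not D")
        else:
            raise ValueError(f"unknown motion kind {self.kind!r}")

    @staticmethod
    def brownian(D: float) -> "MotionModel":
        return MotionModel(kind="brownian", D=D)

    @staticmethod
    def fbm(alpha_ansatz: float, Gamma: float) -> "MotionModel":
        return MotionModel(kind="fbm", D=None, alpha_ansatz=alpha_ansatz, Gamma=Gamma)


def gamma_from_diffusion(D: float, alpha: float, t_match: float = 1e-3) -> float:
    """Generalized diffusion coefficient Γα such that the fBm MSD matches the
    Brownian MSD of coefficient ``D`` at time ``t_match`` (s):
    3 Γ t^α = 6 D t at t = t_match."""
    if D <= 0 or t_match <= 0:
        raise ValueError("D and t_match must be positive")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return 2.0 * D * t_match ** (1.0 - alpha)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one in-silico FCS acquisition."""

    n_particles: int = 50
    dt: float = 1e-6
    duration: float = 1.0
    geometry: CellGeometry = field(default_factory=CellGeometry)
    confocal: ConfocalVolume | None = None
    motion: MotionModel = field(default_factory=MotionModel)
    seed: int = 0
    boundary: Literal["redraw", "reflect"] = "redraw"
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError("duration must be an integer number of steps")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        if self.boundary not in ("redraw", "reflect"):
            raise ValueError("boundary must be 'redraw' or 'reflect'")
        if self.motion.kind == "fbm" and self.boundary != "reflect":
            raise ValueError("fbm supports only reflective boundaries")
        if self.confocal is None:
            # focus on the long axis, 1 µm from the cell edge
            object.__setattr__(
                self,
                "confocal",
                ConfocalVolume(center=(-self.geometry.L / 2.0 + 1.0, 0.0, 0.0)),
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def config_hash(self) -> str:
        payload = {
            "n_particles": self.n_particles,
            "dt": self.dt,
            "duration": self.duration,
            "L": self.geometry.L,
            "d": self.geometry.d,
            "omega0": self.confocal.omega0,
            "z0": self.confocal.z0,
            "center": list(self.confocal.center),
            "motion": [self.motion.kind, self.motion.D, self.motion.alpha_ansatz, self.motion.Gamma],
            "seed": self.seed,
            "boundary": self.boundary,
            "bleach_rate": self.bleach_rate,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class IntensityTrace:
    """Uniformly sampled fluorescence intensity from one acquisition."""

    dt_sample: float
    values: np.ndarray
    t_start: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a nonempty 1D array")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be nonnegative")

    @property
    def duration(self) -> float:
        return self.values.size * self.dt_sample

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt_sample * np.arange(self.values.size)


@dataclass
class SimulationReport:
    """Diagnostics from one simulated acquisition."""

    redraw_exhausted: int = 0
    n_bleached: int = 0


# --------------------------------------------------------------------------
# single-step operation (vectorized numpy; used by tests and by callers
# who want direct access to positions)

def step_brownian(
    positions: np.ndarray,
    motion: MotionModel,
    dt: float,
    geom: CellGeometry,
    rng: np.random.Generator,
    report: SimulationReport | None = None,
) -> np.ndarray:
    """Advance Brownian particles by one step with redraw confinement.

    Each coordinate receives an independent Gaussian increment of standard
    deviation sqrt(2 D Δt); any proposed position outside the cell is
    redrawn (up to a bounded retry count, after which the particle stays
    put and a diagnostic counter is incremented).
    """
    if motion.kind != "brownian":
        raise ValueError("step_brownian requires a brownian motion model")
    pos = np.array(positions, dtype=float, copy=True)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must have shape (n, 3)")
    sigma = np.sqrt(2.0 * motion.D * dt)
    if sigma == 0.0:
        return pos
    new = pos + rng.normal(0.0, sigma, size=pos.shape)
    bad = ~inside_spherocylinder(new, geom)
    tries = 0
    while np.any(bad) and tries < _MAX_REDRAWS:
        n_bad = int(bad.sum())
        new[bad] = pos[bad] + rng.normal(0.0, sigma, size=(n_bad, 3))
        bad = ~inside_spherocylinder(new, geom)
        tries += 1
    if np.any(bad):
        new[bad] = pos[bad]
        if report is not None:
            report.redraw_exhausted += int(bad.sum())
    return new


def sample_uniform_positions(
    n: int, geom: CellGeometry, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points uniformly inside the spherocylinder by rejection
    sampling from the bounding box (the stationary law of confined Brownian
    motion, so no burn-in is required)."""
    out = np.empty((n, 3))
    filled = 0
    half_box = np.array([geom.L / 2.0, geom.radius, geom.radius])
    while filled < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - filled) + 8, 3)) * half_box
        keep = cand[inside_spherocylinder(cand, geom)]
        take = min(n - filled, keep.shape[0])
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


# --------------------------------------------------------------------------
# fractional Gaussian noise (Davies–Harte circulant embedding)

def generate_fgn(
    n_steps: int,
    alpha_ansatz: float,
    Gamma: float,
    dt: float,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Sample fractional Gaussian noise increments, shape (n_series, n_steps).

    The increments have the exact stationary covariance
    ⟨η(t0+t)η(t0)⟩ = (Γ/2)(|t+Δt|^α + |t−Δt|^α − 2|t|^α), i.e. per-step
    variance Γ Δt^α, via circulant embedding of the covariance sequence.
    For α = 1 this collapses to uncorrelated Gaussian noise of variance
    Γ Δt.  Pairs of series are drawn from the real and imaginary parts of a
    single complex sample, which are independent.
    """
    if not 0.0 < alpha_ansatz <= 1.0:
        raise ValueError("alpha_ansatz must lie in (0, 1]")
    if Gamma <= 0 or dt <= 0 or n_steps < 1:
        raise ValueError("Gamma, dt and n_steps must be positive")
    n = int(n_steps)
    sq = _fgn_spectrum(n, alpha_ansatz)
    m = sq.size
    scale = Gamma * dt**alpha_ansatz
    out = np.empty((n_series, n))
    work = np.empty(m, dtype=np.complex128)
    for i in range(0, n_series, 2):
        rng.standard_normal(out=work.view(np.float64))
        work *= sq
        y = scipy_fft.fft(work, overwrite_x=True)
        out[i] = y.real[:n]
        if i + 1 < n_series:
            out[i + 1] = y.imag[:n]
    out *= np.sqrt(scale)
    return out


_FGN_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _fgn_spectrum(n: int, alpha: float) -> np.ndarray:
    """sqrt of the circulant-embedding eigenvalues, prescaled so that
    fft(sq * eps) with eps ~ complex standard normal yields two independent
    unit-variance fGn series in its real and imaginary parts."""
    key = (n, alpha)
    if key in _FGN_CACHE:
        return _FGN_CACHE[key]
    k = np.arange(n + 1, dtype=float)
    # covariance at integer lags, in units of the per-step variance
    r = 0.5 * (np.abs(k + 1) ** alpha + np.abs(k - 1) ** alpha - 2.0 * k**alpha)
    c = np.concatenate([r, r[-2:0:-1]])  # circulant first row, length 2n
    lam = scipy_fft.fft(c).real
    tol = 1e-8 * lam.max()
    if lam.min() < -tol:
        raise ValueError("circulant embedding spectrum has negative eigenvalues")
    lam = np.clip(lam, 0.0, None)
    sq = np.sqrt(lam / c.size)
    if len(_FGN_CACHE) > 8:
        _FGN_CACHE.clear()
    _FGN_CACHE[key] = sq
    return sq


# --------------------------------------------------------------------------
# numba kernels (inner loops; seeded explicitly for determinism)

@njit(cache=True)
def _inside_scalar(x, y, z, half_len, r2):
    ax = abs(x)
    dx = ax - half_len
    if dx < 0.0:
        dx = 0.0
    return dx * dx + y * y + z * z <= r2


@njit(cache=True)
def _fold_scalar(x, y, z, half_len, radius):
    """Specular fold of an outside point back through the capsule surface:
    reflect radially about the surface point nearest to the capsule axis."""
    for _ in range(_MAX_REDRAWS):
        cx = x
        if cx > half_len:
            cx = half_len
        elif cx < -half_len:
            cx = -half_len
        vx = x - cx
        vy = y
        vz = z
        vn = np.sqrt(vx * vx + vy * vy + vz * vz)
        if vn <= radius:
            return x, y, z, True
        f = (2.0 * radius - vn) / vn
        if f <= -1.0:
            return x, y, z, False
        x = cx + vx * f
        y = vy * f
        z = vz * f
        if _inside_scalar(x, y, z, half_len, radius * radius):
            return x, y, z, True
    return x, y, z, False


@njit(cache=True)
def _sim_brownian_chunk(
    normals,
    pos,
    alive,
    sigma_step,
    half_len,
    radius,
    ccx,
    ccy,
    ccz,
    inv_w2,
    inv_z2,
    reflect,
    bleach_prob_scale,
    out,
):
    """Advance all particles through one chunk of steps, accumulating the
    summed PSF intensity into ``out`` (length = chunk size).

    ``normals`` has shape (n_particles, n_chunk, 3); the bulk Gaussian
    steps are pregenerated (fast vectorized stream), while redraws after a
    boundary violation use numba's own seeded stream.  Returns
    (redraw_exhausted, n_bleached_in_chunk).
    """
    n_particles = normals.shape[0]
    n_chunk = normals.shape[1]
    r2 = radius * radius
    exhausted = 0
    bleached = 0
    for i in range(n_particles):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        for t in range(n_chunk):
            if sigma_step > 0.0:
                x1 = x + sigma_step * normals[i, t, 0]
                y1 = y + sigma_step * normals[i, t, 1]
                z1 = z + sigma_step * normals[i, t, 2]
                if _inside_scalar(x1, y1, z1, half_len, r2):
                    x, y, z = x1, y1, z1
                elif reflect:
                    x1, y1, z1, ok = _fold_scalar(x1, y1, z1, half_len, radius)
                    if ok:
                        x, y, z = x1, y1, z1
                    else:
                        exhausted += 1
                else:
                    ok = False
                    for _ in range(_MAX_REDRAWS):
                        x1 = x + sigma_step * np.random.normal()
                        y1 = y + sigma_step * np.random.normal()
                        z1 = z + sigma_step * np.random.normal()
                        if _inside_scalar(x1, y1, z1, half_len, r2):
                            ok = True
                            break
                    if ok:
                        x, y, z = x1, y1, z1
                    else:
                        exhausted += 1
            dx = x - ccx
            dy = y - ccy
            dz = z - ccz
            inten = np.exp(-2.0 * ((dx * dx + dy * dy) * inv_w2 + dz * dz * inv_z2))
            if alive[i] and bleach_prob_scale > 0.0:
                if np.random.random() < bleach_prob_scale * inten:
                    alive[i] = False
                    bleached += 1
            if alive[i]:
                out[t] += inten
        pos[i, 0] = x
        pos[i, 1] = y
        pos[i, 2] = z
    return exhausted, bleached


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def _sim_fbm_particle_kernel(
    incr,
    half_len,
    radius,
    x0,
    y0,
    z0,
    ccx,
    ccy,
    ccz,
    inv_w2,
    inv_z2,
    bleach_prob_scale,
    alive_in,
    out,
):
    """Advance one fBm particle along precomputed increments (3, n_steps)
    with reflective folding, accumulating its PSF intensity into ``out``.
    Returns (redraw_exhausted, still_alive)."""
    n_steps = incr.shape[1]
    r2 = radius * radius
    exhausted = 0
    x, y, z = x0, y0, z0
    alive = alive_in
    for t in range(n_steps):
        x1 = x + incr[0, t]
        y1 = y + incr[1, t]
        z1 = z + incr[2, t]
        if not _inside_scalar(x1, y1, z1, half_len, r2):
            x1, y1, z1, ok = _fold_scalar(x1, y1, z1, half_len, radius)
            if not ok:
                exhausted += 1
                x1, y1, z1 = x, y, z
        x, y, z = x1, y1, z1
        dx = x - ccx
        dy = y - ccy
        dz = z - ccz
        inten = np.exp(-2.0 * ((dx * dx + dy * dy) * inv_w2 + dz * dz * inv_z2))
        if alive and bleach_prob_scale > 0.0:
            if np.random.random() < bleach_prob_scale * inten:
                alive = False
        if alive:
            out[t] += inten
    return exhausted, alive


# --------------------------------------------------------------------------

def evolve_positions(
    positions: np.ndarray,
    D: float,
    dt: float,
    n_steps: int,
    geom: CellGeometry,
    boundary: str = "redraw",
    seed: int = 0,
) -> np.ndarray:
    """Advance Brownian particles ``n_steps`` steps and return the final
    positions (no intensity readout).  Exposes the confined random walk for
    occupancy and mixing diagnostics under either boundary rule."""
    pos = np.array(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must have shape (n, 3)")
    if not np.all(inside_spherocylinder(pos, geom)):
        raise ValueError("all input positions must lie inside the cell")
    ss = np.random.SeedSequence(seed)
    _seed_numba(int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF))
    rng_bulk = np.random.default_rng(ss.spawn(1)[0])
    sigma = np.sqrt(2.0 * D * dt)
    alive = np.ones(pos.shape[0], dtype=np.bool_)
    dummy = np.zeros(n_steps)
    normals = rng_bulk.standard_normal((pos.shape[0], n_steps, 3))
    _sim_brownian_chunk(
        normals, pos, alive, sigma, geom.half_cylinder_length, geom.radius,
        0.0, 0.0, 0.0, 1.0, 1.0, boundary == "reflect", 0.0, dummy,
    )
    return pos


def simulate_trace(
    config: SimulationConfig, initial_positions: np.ndarray | None = None
) -> IntensityTrace:
    """Run one in-silico FCS acquisition and return the intensity trace.

    Initial positions are uniform over the cell (the stationary law) unless
    given explicitly; the trace is the per-step sum of the Gaussian
    detection profile over all (non-bleached) emitters.  Deterministic for
    a given config + seed.
    """
    geom = config.geometry
    conf = config.confocal
    if not inside_spherocylinder(np.asarray(conf.center, dtype=float), geom):
        raise ValueError("confocal center lies outside the cell")
    ss = np.random.SeedSequence(config.seed)
    init_ss, kernel_ss = ss.spawn(2)
    if initial_positions is None:
        rng_init = np.random.default_rng(init_ss)
        x0 = sample_uniform_positions(config.n_particles, geom, rng_init)
    else:
        x0 = np.array(initial_positions, dtype=float)
        if x0.shape != (config.n_particles, 3):
            raise ValueError("initial_positions must have shape (n_particles, 3)")
        if not np.all(inside_spherocylinder(x0, geom)):
            raise ValueError("all initial positions must lie inside the cell")
    out = np.zeros(config.n_steps)
    report = SimulationReport()
    ccx, ccy, ccz = conf.center
    inv_w2 = 1.0 / conf.omega0**2
    inv_z2 = 1.0 / conf.z0**2
    bleach_scale = config.bleach_rate * config.dt
    if config.motion.kind == "brownian":
        sigma = np.sqrt(2.0 * config.motion.D * config.dt)
        seed32 = int(kernel_ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        _seed_numba(seed32)
        rng_bulk = np.random.default_rng(kernel_ss.spawn(1)[0])
        pos = np.array(x0)
        alive = np.ones(config.n_particles, dtype=np.bool_)
        chunk = min(config.n_steps, max(1, (1 << 22) // config.n_particles))
        buf = np.empty((config.n_particles, chunk, 3))
        done = 0
        while done < config.n_steps:
            n_chunk = min(chunk, config.n_steps - done)
            normals = buf[:, :n_chunk, :] if n_chunk == chunk else np.empty(
                (config.n_particles, n_chunk, 3)
            )
            rng_bulk.standard_normal(out=normals)
            exhausted, bleached = _sim_brownian_chunk(
                normals,
                pos,
                alive,
                sigma,
                geom.half_cylinder_length,
                geom.radius,
                ccx,
                ccy,
                ccz,
                inv_w2,
                inv_z2,
                config.boundary == "reflect",
                bleach_scale,
                out[done : done + n_chunk],
            )
            report.redraw_exhausted += int(exhausted)
            report.n_bleached += int(bleached)
            done += n_chunk
    else:
        rng_fgn = np.random.default_rng(kernel_ss)
        _seed_numba(int(kernel_ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF))
        alpha = config.motion.alpha_ansatz
        gamma = config.motion.Gamma
        for i in range(config.n_particles):
            incr = generate_fgn(config.n_steps, alpha, gamma, config.dt, rng_fgn, n_series=3)
            exhausted, alive = _sim_fbm_particle_kernel(
                incr,
                geom.half_cylinder_length,
                geom.radius,
                x0[i, 0],
                x0[i, 1],
                x0[i, 2],
                ccx,
                ccy,
                ccz,
                inv_w2,
                inv_z2,
                bleach_scale,
                True,
                out,
            )
            report.redraw_exhausted += int(exhausted)
            if not alive:
                report.n_bleached += 1
    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "motion": config.motion.kind,
        "redraw_exhausted": report.redraw_exhausted,
        "n_bleached": report.n_bleached,
    }
    return IntensityTrace(dt_sample=config.dt, values=out, meta=meta)
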