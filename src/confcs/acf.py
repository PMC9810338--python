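"""Autocorrelation estimation on log-spaced lag grids.

The estimator follows experimental practice for hardware correlators:
C(dt) = ⟨I(t+dt)I(t)⟩ / (⟨I(t+dt)⟩⟨I(t)⟩) − 1, with the means taken over
the overlapping segment (symmetric normalization), evaluated on a
logarithmically spaced grid of lags.  Photobleaching is corrected before
correlation by detrending the slow intensity decay with a continuous
multi-segment line and applying the variance-preserving square-root
correction.  A multiplicative blinking factor emulating chromophore
protonation–deprotonation can be applied to simulated curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .simulate import IntensityTrace

__all__ = [
    "ACFCurve",
    "DetrendSettings",
    "default_lag_grid",
    "compute_acf",
    "average_acfs",
    "apply_blinking_factor",
    "detrend_trace",
]


@dataclass
class ACFCurve:
    """Normalized intensity ACF on a strictly increasing lag grid (s)."""

    lags: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None
    min_lag: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.ndim != 1 or self.lags.size != self.values.size:
            raise ValueError("lags and values must be 1D arrays of equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not (np.all(np.isfinite(self.lags)) and np.all(np.isfinite(self.values))):
            raise ValueError("lags and values must be finite")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.lags.shape:
                raise ValueError("sem must match lags in shape")
        if self.min_lag == 0.0:
            self.min_lag = float(self.lags[0])
        elif self.min_lag > self.lags[0] + 1e-15:
            raise ValueError("min_lag must be <= smallest lag")

    def restrict(self, max_lag: float | None = None, min_lag: float | None = None) -> "ACFCurve":
        """Sub-curve on [min_lag, max_lag]; used for short-lag-window refits."""
        keep = np.ones_like(self.lags, dtype=bool)
        if max_lag is not None:
            keep &= self.lags <= max_lag
        if min_lag is not None:
            keep &= self.lags >= min_lag
        return ACFCurve(
            self.lags[keep],
            self.values[keep],
            None if self.sem is None else self.sem[keep],
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class DetrendSettings:
    """Multi-segment-line detrending settings.

    n_segments : number of linear segments of the continuous trend
    n_bins     : coarse time bins the trend is fitted to
    """

    n_segments: int = 2
    n_bins: int = 64

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.n_bins < 2 * self.n_segments:
            raise ValueError("n_bins must be >= 2 * n_segments")


def default_lag_grid(
    dt_sample: float,
    duration: float,
    min_lag: float | None = None,
    points_per_decade: int = 16,
) -> np.ndarray:
    """Log-spaced lag grid (s) from ``min_lag`` (default one sample) to one
    tenth of the trace duration, snapped to integer sample multiples."""
    if min_lag is None:
        min_lag = dt_sample
    max_lag = duration / 10.0
    if max_lag <= min_lag:
        raise ValueError("trace too short for the requested lag range")
    n_dec = np.log10(max_lag / min_lag)
    n_pts = max(2, int(np.ceil(n_dec * points_per_decade)) + 1)
    lags = np.geomspace(min_lag, max_lag, n_pts)
    k = np.unique(np.maximum(1, np.round(lags / dt_sample).astype(int)))
    return k * dt_sample


def compute_acf(
    trace: IntensityTrace,
    lag_grid: np.ndarray | None = None,
    min_lag: float | None = None,
    points_per_decade: int = 16,
) -> ACFCurve:
    """Symmetric-normalized autocorrelation of an intensity trace.

    Lags are rounded to integer multiples of the sampling interval.  The
    trace must cover at least twice the largest lag.  Constant-zero traces
    are rejected (the normalization is undefined).
    """
    I = trace.values
    n = I.size
    if not np.any(I > 0):
        raise ValueError("cannot correlate an all-zero trace")
    if lag_grid is None:
        lag_grid = default_lag_grid(trace.dt_sample, trace.duration, min_lag, points_per_decade)
    ks = np.maximum(1, np.round(np.asarray(lag_grid, dtype=float) / trace.dt_sample).astype(int))
    ks = np.unique(ks)
    if 2 * ks[-1] > n:
        raise ValueError("trace shorter than twice the maximum lag")
    vals = np.empty(ks.size)
    for j, k in enumerate(ks):
        a = I[k:]
        b = I[:-k]
        denom = a.mean() * b.mean()
        vals[j] = float(np.dot(a, b)) / a.size / denom - 1.0 if denom > 0 else 0.0
    lags = ks * trace.dt_sample
    return ACFCurve(lags, vals, meta=dict(trace.meta))


def average_acfs(curves: list[ACFCurve]) -> ACFCurve:
    """Pointwise mean of replicate ACF curves sharing one lag grid, with the
    standard error of the mean across curves as per-lag dispersion."""
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags):
            raise ValueError("curves must share the same lag grid")
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else None
    return ACFCurve(lags, mean, sem, meta={"n_curves": len(curves)})


def apply_blinking_factor(
    acf: ACFCurve, amplitude: float = 0.1, tau_h: float = 25e-6
) -> ACFCurve:
    """Multiply an ACF by the blinking decay 1 + (a/(1+a))·exp(−dt/τ_H).

    With the default a = 0.1 this equals the dark-state term
    (1 − F_P + F_P e^{−dt/τ_P})/(1 − F_P) for F_P = 1/12, τ_P = τ_H.
    """
    if amplitude < 0 or tau_h <= 0:
        raise ValueError("amplitude must be >= 0 and tau_h > 0")
    factor = 1.0 + (amplitude / (1.0 + amplitude)) * np.exp(-acf.lags / tau_h)
    return ACFCurve(acf.lags, acf.values * factor, acf.sem, meta=dict(acf.meta))


# --------------------------------------------------------------------------
# photobleaching detrend

def _fit_piecewise_linear(t: np.ndarray, y: np.ndarray, n_segments: int):
    """Continuous piecewise-linear least-squares fit with interior knots
    chosen by grid search over bin boundaries (SSE-minimizing)."""

    def design(knots):
        cols = [np.ones_like(t), t - t[0]]
        for k in knots:
            cols.append(np.maximum(t - k, 0.0))
        return np.column_stack(cols)

    def solve(knots):
        X = design(knots)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ coef - y) ** 2))
        return coef, sse

    if n_segments == 1:
        coef, _ = solve(())
        return coef, ()
    # candidate knots: interior bin positions, thinned to bound the search
    interior = t[1:-1]
    if interior.size > 24:
        interior = interior[np.linspace(0, interior.size - 1, 24).astype(int)]
    best = None
    for knots in combinations(interior, n_segments - 1):
        coef, sse = solve(knots)
        if best is None or sse < best[2]:
            best = (coef, knots, sse)
    return best[0], best[1]


def _eval_piecewise(t: np.ndarray, t0: float, coef, knots) -> np.ndarray:
    out = coef[0] + coef[1] * (t - t0)
    for c, k in zip(coef[2:], knots):
        out = out + c * np.maximum(t - k, 0.0)
    return out


def detrend_trace(
    trace: IntensityTrace, settings: DetrendSettings | None = None
) -> IntensityTrace:
    """Correct the slow photobleaching decay of an intensity trace.

    A continuous ``n_segments``-piece linear trend f(t) is least-squares
    fitted to the coarse-binned trace, and the intensity corrected with the
    variance-preserving square-root form
    I_c(t) = I(t)/sqrt(f(t)/f(0)) + f(0)·(1 − sqrt(f(t)/f(0))),
    which restores both the mean and the fluctuation amplitude of a
    stationary process.  Fails if the fitted trend is nonpositive anywhere.
    """
    if settings is None:
        settings = DetrendSettings()
    I = trace.values
    n = I.size
    if n < 4 * settings.n_bins:
        raise ValueError("trace too short for the requested number of bins")
    edges = np.linspace(0, n, settings.n_bins + 1).astype(int)
    t_bin = np.empty(settings.n_bins)
    y_bin = np.empty(settings.n_bins)
    times = trace.times
    for i in range(settings.n_bins):
        sl = slice(edges[i], edges[i + 1])
        t_bin[i] = times[sl].mean()
        y_bin[i] = I[sl].mean()
    coef, knots = _fit_piecewise_linear(t_bin, y_bin, settings.n_segments)
    f = _eval_piecewise(times, t_bin[0], coef, knots)
    if np.any(f <= 0):
        raise ValueError("fitted bleaching trend is nonpositive; cannot detrend")
    f0 = f[0]
    ratio = np.sqrt(f / f0)
    corrected = I / ratio + f0 * (1.0 - ratio)
    corrected = np.maximum(corrected, 0.0)
    meta = dict(trace.meta)
    meta["detrended"] = {
        "n_segments": settings.n_segments,
        "n_bins": settings.n_bins,
        "f0": float(f0),
        "f_end": float(f[-1]),
    }
    return IntensityTrace(trace.dt_sample, corrected, trace.t_start, meta)
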