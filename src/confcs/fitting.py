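"""Nonlinear least-squares fitting of ACF curves.

Curves are fitted with the Levenberg–Marquardt algorithm (via lmfit).
Defaults follow the experimental conventions: the blinking lifetime is
fixed to τ_P = 25 µs and the confocal aspect ratio to S = 8; for the OU
confined-diffusion model the beam waist ω₀ = 0.19 µm and the confinement
width σ = 0.42 µm (= d/2) are fixed as well, leaving {N, F_P, D, G_∞}
free — one parameter fewer than the anomalous model's
{N, F_P, τ_D, α, G_∞}.

Per-cell aggregation mirrors the acquisition protocol: six sequential
traces per cell, one fit each, arithmetic mean ± SEM over the converged
fits.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .acf import ACFCurve
from .models import (
    DEFAULT_OMEGA0,
    DEFAULT_S,
    DEFAULT_SIGMA,
    DEFAULT_TAU_P,
    MODEL_NAMES,
    eval_anomalous_acf,
    eval_ou_acf,
    eval_two_component_acf,
)

__all__ = [
    "FitResult",
    "CellMeasurement",
    "fit_acf",
    "fit_two_component",
    "aggregate_cell",
    "compare_models",
    "sigma_scan",
    "welch_t_test",
    "WelchResult",
]


@dataclass
class FitResult:
    """Outcome of one ACF model fit."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    fixed: dict[str, float]
    ssr: float
    n_points: int
    n_free: int
    converged: bool
    aic: float
    at_bounds: list[str] = field(default_factory=list)

    def predict(self, tau):
        """Evaluate the fitted model on a lag grid."""
        p = {**self.fixed, **self.params}
        if self.model == "ou":
            return eval_ou_acf(
                tau,
                N=p["N"],
                D=p["D"],
                G_inf=p["G_inf"],
                F_P=p["F_P"],
                tau_P=p["tau_P"],
                S=p["S"],
                omega0=p["omega0"],
                sigma=p["sigma"],
            )
        if self.model == "two_component":
            return eval_two_component_acf(
                tau,
                N=p["N"],
                weight_fast=p["weight_fast"],
                tau_D_fast=p["tau_D_fast"],
                alpha_fast=p["alpha_fast"],
                tau_D_slow=p["tau_D_slow"],
                alpha_slow=p["alpha_slow"],
                G_inf=p["G_inf"],
                F_P=p["F_P"],
                tau_P=p["tau_P"],
                S=p["S"],
            )
        return eval_anomalous_acf(
            tau,
            N=p["N"],
            tau_D=p["tau_D"],
            alpha=p["alpha"],
            G_inf=p["G_inf"],
            F_P=p["F_P"],
            tau_P=p["tau_P"],
            S=p["S"],
        )


def _initial_guesses(acf: ACFCurve) -> dict[str, float]:
    v = acf.values
    lags = acf.lags
    n_tail = max(3, v.size // 10)
    g_inf0 = float(np.mean(v[-n_tail:]))
    amp = float(v[0] - g_inf0)
    if amp <= 0:
        amp = max(float(np.max(v) - g_inf0), 1e-6)
    half = g_inf0 + amp / 2.0
    below = np.nonzero(v <= half)[0]
    tau_d0 = float(lags[below[0]]) if below.size else float(np.sqrt(lags[0] * lags[-1]))
    return {"amp": amp, "G_inf": g_inf0, "tau_D": tau_d0, "N": 1.0 / amp}


def _setup_params(
    model: str,
    guesses: dict[str, float],
    lags: np.ndarray,
    fixed: dict[str, float],
    init: dict[str, float],
    bounds: dict[str, tuple[float, float]],
) -> lmfit.Parameters:
    amp = guesses["amp"]
    defaults = {
        "N": (guesses["N"], 1e-4, 1e7),
        "F_P": (0.1, 0.0, 0.5),
        "G_inf": (guesses["G_inf"], -10.0 * amp, 10.0 * amp),
        "tau_P": (DEFAULT_TAU_P, 1e-7, 1e-2),
        "S": (DEFAULT_S, 1.0, 100.0),
        "tau_D": (guesses["tau_D"], lags[0] / 10.0, lags[-1] * 100.0),
        "alpha": (0.85, 0.3, 1.3),
        "omega0": (DEFAULT_OMEGA0, 1e-3, 10.0),
        "sigma": (DEFAULT_SIGMA, 1e-3, 1e3),
    }
    if model == "ou":
        w0 = fixed.get("omega0", DEFAULT_OMEGA0)
        d0 = w0**2 / (4.0 * guesses["tau_D"])
        defaults["D"] = (d0, w0**2 / (400.0 * lags[-1]), w0**2 / (0.4 * lags[0]))
        free = ["N", "F_P", "D", "G_inf"]
        always_fixed = {"tau_P", "S", "omega0", "sigma"}
    elif model == "brownian":
        free = ["N", "F_P", "tau_D", "G_inf"]
        always_fixed = {"tau_P", "S", "alpha"}
        defaults["alpha"] = (1.0, 0.3, 1.3)
    elif model == "anomalous":
        free = ["N", "F_P", "tau_D", "alpha", "G_inf"]
        always_fixed = {"tau_P", "S"}
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    params = lmfit.Parameters()
    for name in free + sorted(always_fixed):
        value, lo, hi = defaults[name]
        if name in bounds:
            lo, hi = bounds[name]
        if name in init:
            value = init[name]
        if name in fixed:
            params.add(name, value=fixed[name], vary=False)
        else:
            vary = name in free
            params.add(name, value=float(np.clip(value, lo, hi)), min=lo, max=hi, vary=vary)
    return params


def _finalize(model: str, result, params: lmfit.Parameters, n_points: int) -> FitResult:
    free_names = [k for k in result.params if result.params[k].vary]
    values = {k: float(result.params[k].value) for k in free_names}
    stderr = {k: (float(result.params[k].stderr) if result.params[k].stderr else None) for k in free_names}
    fixed = {k: float(result.params[k].value) for k in result.params if not result.params[k].vary}
    at_bounds = []
    for k in free_names:
        p = result.params[k]

        def near(bound):
            return np.isfinite(bound) and abs(p.value - bound) <= max(1e-10, 1e-4 * abs(bound))

        if near(p.min) or near(p.max):
            at_bounds.append(k)
    return FitResult(
        model=model,
        params=values,
        stderr=stderr,
        fixed=fixed,
        ssr=float(result.chisqr),
        n_points=n_points,
        n_free=len(free_names),
        converged=bool(result.success),
        aic=float(result.aic),
        at_bounds=at_bounds,
    )


def fit_acf(
    acf: ACFCurve,
    model: str = "anomalous",
    fixed: dict[str, float] | None = None,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    weighted: bool = False,
    max_lag: float | None = None,
) -> FitResult:
    """Levenberg–Marquardt fit of one ACF curve.

    ``fixed`` overrides make any parameter constant (e.g. ``{"sigma": 0.4}``);
    ``weighted`` uses 1/sem² weights when the curve carries per-lag SEMs;
    ``max_lag`` restricts the fit window (short-lag refits).
    """
    if max_lag is not None:
        acf = acf.restrict(max_lag=max_lag)
    lags, values = acf.lags, acf.values
    if lags.size < 10 or lags[-1] / lags[0] < 100.0:
        raise ValueError("ACF must have >= 10 points spanning >= 2 decades")
    fixed = dict(fixed or {})
    init = dict(init or {})
    bounds = dict(bounds or {})
    params = _setup_params(model, _initial_guesses(acf), lags, fixed, init, bounds)
    weights = None
    if weighted and acf.sem is not None:
        w = np.where(acf.sem > 0, acf.sem, np.nanmin(acf.sem[acf.sem > 0], initial=1.0))
        weights = 1.0 / w

    def residual(p):
        pv = {k: p[k].value for k in p}
        if model == "ou":
            pred = eval_ou_acf(
                lags, N=pv["N"], D=pv["D"], G_inf=pv["G_inf"], F_P=pv["F_P"],
                tau_P=pv["tau_P"], S=pv["S"], omega0=pv["omega0"], sigma=pv["sigma"],
            )
        else:
            pred = eval_anomalous_acf(
                lags, N=pv["N"], tau_D=pv["tau_D"], alpha=pv["alpha"],
                G_inf=pv["G_inf"], F_P=pv["F_P"], tau_P=pv["tau_P"], S=pv["S"],
            )
        res = pred - values
        return res * weights if weights is not None else res

    result = lmfit.minimize(residual, params, method="leastsq", xtol=1e-10, ftol=1e-10, max_nfev=50000)
    return _finalize(model, result, params, lags.size)


def fit_two_component(
    acf: ACFCurve,
    fast_fixed: dict[str, float],
    init: dict[str, float] | None = None,
    fixed: dict[str, float] | None = None,
    weighted: bool = False,
) -> FitResult:
    """Two-species anomalous fit with a fully specified fast component.

    ``fast_fixed`` must provide ``weight`` (fraction of the fast species),
    ``tau_D`` and ``alpha``; the slow component's τ_D and α are fitted
    together with N, F_P and G_∞.
    """
    for key in ("weight", "tau_D", "alpha"):
        if key not in fast_fixed:
            raise ValueError(f"fast component missing {key!r}")
    lags, values = acf.lags, acf.values
    if lags.size < 10 or lags[-1] / lags[0] < 100.0:
        raise ValueError("ACF must have >= 10 points spanning >= 2 decades")
    guesses = _initial_guesses(acf)
    fixed = dict(fixed or {})
    init = dict(init or {})
    amp = guesses["amp"]
    params = lmfit.Parameters()
    params.add("N", value=init.get("N", guesses["N"]), min=1e-4, max=1e7)
    params.add("F_P", value=init.get("F_P", 0.1), min=0.0, max=0.5)
    params.add("G_inf", value=init.get("G_inf", guesses["G_inf"]), min=-10 * amp, max=10 * amp)
    params.add("tau_D_slow", value=init.get("tau_D_slow", guesses["tau_D"]),
               min=lags[0] / 10.0, max=lags[-1] * 100.0)
    params.add("alpha_slow", value=init.get("alpha_slow", 0.85), min=0.3, max=1.3)
    params.add("tau_P", value=fixed.get("tau_P", DEFAULT_TAU_P), vary=False)
    params.add("S", value=fixed.get("S", DEFAULT_S), vary=False)
    params.add("weight_fast", value=fast_fixed["weight"], vary=False)
    params.add("tau_D_fast", value=fast_fixed["tau_D"], vary=False)
    params.add("alpha_fast", value=fast_fixed["alpha"], vary=False)
    for k, v in fixed.items():
        if k in params:
            params[k].set(value=v, vary=False)

    def residual(p):
        pv = {k: p[k].value for k in p}
        pred = eval_two_component_acf(
            lags, N=pv["N"], weight_fast=pv["weight_fast"],
            tau_D_fast=pv["tau_D_fast"], alpha_fast=pv["alpha_fast"],
            tau_D_slow=pv["tau_D_slow"], alpha_slow=pv["alpha_slow"],
            G_inf=pv["G_inf"], F_P=pv["F_P"], tau_P=pv["tau_P"], S=pv["S"],
        )
        return pred - values

    result = lmfit.minimize(residual, params, method="leastsq", xtol=1e-10, ftol=1e-10, max_nfev=50000)
    return _finalize("two_component", result, params, lags.size)


@dataclass
class CellMeasurement:
    """Per-cell aggregate over the (typically six) per-acquisition fits."""

    n_total: int
    n_converged: int
    mean_tau_D: float | None = None
    sem_tau_D: float | None = None
    mean_alpha: float | None = None
    sem_alpha: float | None = None
    mean_D: float | None = None
    sem_D: float | None = None
    fits: list[FitResult] = field(default_factory=list)


def _mean_sem(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, sem


def aggregate_cell(fits: list[FitResult]) -> CellMeasurement:
    """Mean ± SEM of the mobility parameters over the converged fits."""
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged fits to aggregate")
    out = CellMeasurement(n_total=len(fits), n_converged=len(good), fits=list(fits))
    if all("D" in f.params for f in good):
        out.mean_D, out.sem_D = _mean_sem([f.params["D"] for f in good])
    if all("tau_D" in f.params for f in good):
        out.mean_tau_D, out.sem_tau_D = _mean_sem([f.params["tau_D"] for f in good])
    if all("alpha" in f.params for f in good):
        out.mean_alpha, out.sem_alpha = _mean_sem([f.params["alpha"] for f in good])
    return out


def compare_models(
    acf: ACFCurve,
    model_names: tuple[str, ...] = MODEL_NAMES,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit several models to one curve; rank by AIC (best first).

    A model that errors out is reported with NaNs instead of aborting the
    comparison.
    """
    rows = []
    for name in model_names:
        try:
            fr = fit_acf(acf, model=name, **fit_kwargs)
            rows.append(
                {"model": name, "ssr": fr.ssr, "aic": fr.aic, "n_free": fr.n_free,
                 "converged": fr.converged}
            )
        except Exception as exc:  # noqa: BLE001 - per-model isolation is the contract
            rows.append(
                {"model": name, "ssr": np.nan, "aic": np.nan, "n_free": np.nan,
                 "converged": False, "error": str(exc)}
            )
    df = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    return df


def sigma_scan(
    acf: ACFCurve,
    sigmas: np.ndarray,
    fixed: dict[str, float] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit the OU model at each fixed confinement width σ; returns a table
    (sigma, ssr, D, converged) for locating the SSR-minimizing σ."""
    fixed = dict(fixed or {})
    rows = []
    for s in np.asarray(sigmas, dtype=float):
        fx = dict(fixed)
        fx["sigma"] = float(s)
        fr = fit_acf(acf, model="ou", fixed=fx, **fit_kwargs)
        d_val = fr.params.get("D", fr.fixed.get("D"))
        rows.append({"sigma": s, "ssr": fr.ssr, "D": d_val, "converged": fr.converged})
    return pd.DataFrame(rows)


WelchResult = namedtuple("WelchResult", ["t", "dof", "p"])


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Two-tailed heteroscedastic (Welch) t-test.

    Degrees of freedom follow Welch–Satterthwaite.  If both samples have
    zero variance and equal means, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(np.inf if a.mean() > b.mean() else -np.inf,
                           float(a.size + b.size - 2), 0.0)
    se2a, se2b = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    dof = (se2a + se2b) ** 2 / (se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return WelchResult(float(t), float(dof), float(p))
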