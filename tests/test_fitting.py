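"""Model fitting: round trips, aggregation, model comparison, statistics."""

import numpy as np
import pytest
from scipy import stats

from confcs.acf import ACFCurve
from confcs.fitting import (
    aggregate_cell,
    compare_models,
    fit_acf,
    fit_two_component,
    sigma_scan,
    welch_t_test,
)
from confcs.models import eval_anomalous_acf, eval_ou_acf, eval_two_component_acf

LAGS = np.geomspace(1e-6, 1.0, 120)


def anomalous_curve(**params):
    return ACFCurve(LAGS, eval_anomalous_acf(LAGS, **params))


class TestFitAcf:
    def test_noiseless_anomalous_round_trip(self):
        truth = dict(N=5.0, tau_D=800e-6, alpha=0.85, F_P=0.1, G_inf=0.002)
        acf = anomalous_curve(**truth)
        fr = fit_acf(acf, model="anomalous")
        assert fr.converged
        for name in ("N", "tau_D", "alpha", "F_P", "G_inf"):
            assert fr.params[name] == pytest.approx(truth[name], rel=1e-6, abs=1e-9)

    def test_noiseless_ou_round_trip(self):
        truth = dict(N=3.0, D=12.0, F_P=0.08, G_inf=0.001)
        vals = eval_ou_acf(LAGS, omega0=0.19, sigma=0.42, S=8.0, **truth)
        fr = fit_acf(ACFCurve(LAGS, vals), model="ou")
        assert fr.converged
        for name in ("N", "D", "F_P", "G_inf"):
            assert fr.params[name] == pytest.approx(truth[name], rel=1e-6, abs=1e-9)

    def test_brownian_is_anomalous_with_alpha_fixed(self):
        acf = anomalous_curve(N=2.0, tau_D=1e-3, alpha=1.0, F_P=0.05)
        fr = fit_acf(acf, model="brownian")
        assert fr.fixed["alpha"] == 1.0
        assert fr.params["tau_D"] == pytest.approx(1e-3, rel=1e-6)

    def test_fixed_overrides_and_defaults(self):
        acf = anomalous_curve(N=2.0, tau_D=1e-3, alpha=0.9)
        fr = fit_acf(acf, model="anomalous", fixed={"F_P": 0.0})
        assert fr.fixed["tau_P"] == pytest.approx(25e-6)
        assert fr.fixed["S"] == pytest.approx(8.0)
        assert fr.fixed["F_P"] == 0.0
        assert "F_P" not in fr.params

    def test_too_few_points_rejected(self):
        short = ACFCurve(LAGS[:5], np.ones(5))
        with pytest.raises(ValueError):
            fit_acf(short)

    def test_max_lag_restricts_window(self):
        acf = anomalous_curve(N=2.0, tau_D=1e-3, alpha=0.9)
        fr = fit_acf(acf, model="anomalous", max_lag=1e-1)
        assert fr.n_points == int(np.sum(LAGS <= 1e-1))

    def test_simulated_confinement_yields_apparent_anomaly(self, bd_acfs):
        # Brownian particles at d=0.85 µm: anomalous fit gives alpha < 1
        fits = [fit_acf(a, model="anomalous", fixed={"S": 4.0}) for a in bd_acfs]
        alphas = [f.params["alpha"] for f in fits]
        assert all(f.converged for f in fits)
        assert 0.75 < np.mean(alphas) < 0.95

    def test_ou_recovers_ansatz_diffusion(self, bd_acfs):
        # OU fit with sigma = d/2 at the simulation's optics (omega0=0.2, S=4)
        fits = [
            fit_acf(a, model="ou", fixed={"omega0": 0.2, "S": 4.0, "sigma": 0.425})
            for a in bd_acfs
        ]
        mean_d = np.mean([f.params["D"] for f in fits])
        assert mean_d == pytest.approx(10.0, rel=0.10)


class TestStderrCoverage:
    def test_reported_errors_cover_truth(self, rng):
        # noisy round trips: the truth lies within 2 reported standard
        # errors of the fit for >= 80% of replicates
        truth = dict(N=5.0, tau_D=800e-6, alpha=0.85, F_P=0.1, G_inf=0.0)
        clean = eval_anomalous_acf(LAGS, **truth)
        noise_sd = 0.002
        hits = {"tau_D": 0, "alpha": 0}
        n_rep = 50
        for _ in range(n_rep):
            noisy = ACFCurve(LAGS, clean + rng.normal(0.0, noise_sd, LAGS.size))
            fr = fit_acf(noisy, model="anomalous")
            for name in hits:
                se = fr.stderr[name]
                if se and abs(fr.params[name] - truth[name]) < 2.0 * se:
                    hits[name] += 1
        for name, count in hits.items():
            assert count / n_rep >= 0.8, name


class TestTwoComponentFit:
    def test_noiseless_slow_component_recovery(self):
        vals = eval_two_component_acf(
            LAGS, N=4.0, weight_fast=0.15, tau_D_fast=561e-6, alpha_fast=0.86,
            tau_D_slow=1100e-6, alpha_slow=0.88, F_P=0.1, G_inf=0.001,
        )
        fr = fit_two_component(
            ACFCurve(LAGS, vals),
            fast_fixed={"weight": 0.15, "tau_D": 561e-6, "alpha": 0.86},
        )
        assert fr.converged
        assert fr.params["tau_D_slow"] == pytest.approx(1100e-6, rel=0.02)
        assert fr.params["alpha_slow"] == pytest.approx(0.88, rel=0.02)

    def test_zero_weight_equals_single_component(self):
        truth = dict(N=3.0, tau_D=900e-6, alpha=0.84, F_P=0.1, G_inf=0.0)
        acf = anomalous_curve(**truth)
        fr = fit_two_component(
            acf, fast_fixed={"weight": 0.0, "tau_D": 561e-6, "alpha": 0.86}
        )
        assert fr.params["tau_D_slow"] == pytest.approx(900e-6, rel=1e-4)
        assert fr.params["alpha_slow"] == pytest.approx(0.84, rel=1e-4)

    def test_missing_fast_spec_rejected(self):
        acf = anomalous_curve(N=1.0, tau_D=1e-3, alpha=0.9)
        with pytest.raises(ValueError):
            fit_two_component(acf, fast_fixed={"weight": 0.15})


class TestAggregateCell:
    def _mk(self, tau_d, alpha, converged=True):
        return type(
            "F", (), {"converged": converged, "params": {"tau_D": tau_d, "alpha": alpha}}
        )()

    def test_identical_fits(self):
        cm = aggregate_cell([self._mk(5e-4, 0.85) for _ in range(6)])
        assert cm.mean_tau_D == pytest.approx(5e-4)
        assert cm.sem_tau_D == 0.0
        assert cm.n_converged == 6

    def test_textbook_mean_sem(self):
        taus = [500e-6, 520e-6, 540e-6, 560e-6, 580e-6, 600e-6]
        cm = aggregate_cell([self._mk(t, 0.85) for t in taus])
        assert cm.mean_tau_D == pytest.approx(550e-6)
        assert cm.sem_tau_D == pytest.approx(np.std(taus, ddof=1) / np.sqrt(6))
        assert cm.sem_tau_D == pytest.approx(15.28e-6, rel=1e-3)

    def test_non_converged_excluded(self):
        fits = [self._mk(5e-4, 0.85) for _ in range(5)] + [self._mk(9e-4, 0.5, False)]
        cm = aggregate_cell(fits)
        assert cm.n_converged == 5
        assert cm.mean_tau_D == pytest.approx(5e-4)

    def test_all_failed_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cell([self._mk(5e-4, 0.85, False)])


class TestCompareModels:
    def test_nested_models_ssr_ordering(self):
        acf = anomalous_curve(N=2.0, tau_D=1e-3, alpha=0.8, F_P=0.1)
        df = compare_models(acf, ("brownian", "anomalous"))
        ssr = df.set_index("model")["ssr"]
        assert ssr["anomalous"] <= ssr["brownian"] + 1e-15

    def test_ou_has_one_less_free_parameter(self):
        acf = anomalous_curve(N=2.0, tau_D=1e-3, alpha=0.9, F_P=0.1)
        df = compare_models(acf, ("anomalous", "ou")).set_index("model")
        assert df.loc["ou", "n_free"] == df.loc["anomalous", "n_free"] - 1

    def test_confined_simulation_prefers_anomalous(self, bd_acfs):
        # confinement makes the unconfined Brownian model fit worse
        wins = 0
        for acf in bd_acfs:
            df = compare_models(acf, ("brownian", "anomalous"), fixed={"S": 4.0})
            df = df.set_index("model")
            if df.loc["anomalous", "aic"] < df.loc["brownian", "aic"]:
                wins += 1
        assert wins == len(bd_acfs)


class TestSigmaScan:
    def test_ssr_minimum_near_half_diameter(self, bd_acf_mean, bd_ansatz_occupancy):
        # calibration of the harmonic width: with every other parameter held
        # at its ansatz value (D, S, omega0, N from the PSF moments,
        # F_P = 1/12, G_inf = 0), the SSR-minimizing sigma is ~ d/2
        d_cell = 0.85
        sigmas = np.linspace(0.3 * d_cell, 0.7 * d_cell, 9)
        fixed = {
            "omega0": 0.2, "S": 4.0, "D": 10.0,
            "N": bd_ansatz_occupancy, "F_P": 1.0 / 12.0, "G_inf": 0.0,
        }
        df = sigma_scan(bd_acf_mean, sigmas, fixed=fixed)
        best = df.loc[df["ssr"].idxmin(), "sigma"]
        assert 0.45 * d_cell <= best <= 0.55 * d_cell


class TestWelchTTest:
    def test_identical_samples(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_zero_variance_convention(self):
        r = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0

    def test_matches_reference_implementation(self, rng):
        a = rng.normal(14.7, 2.0, size=30)
        b = rng.normal(12.9, 3.0, size=18)
        mine = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-8)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_type_one_error_calibration(self, rng):
        # null replicates: rejection rate at p<0.05 must be ~5%
        n_rep, n = 1000, 20
        rejections = 0
        for _ in range(n_rep):
            a = rng.normal(0.0, 1.0, n)
            b = rng.normal(0.0, 1.5, n)
            if welch_t_test(a, b).p < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.015)
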