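"""MCMC sampling, convergence and fit diagnostics."""

import numpy as np
import pytest

from bayesbmc.data import DoseGroupSummary, DoseResponseDataset
from bayesbmc.inference import (
    McmcConfig,
    compute_loo,
    compute_ppp,
    compute_rhat,
    fit,
)
from bayesbmc.models import (
    ParameterVector,
    default_priors,
    evaluate,
    make_spec,
    pointwise_log_likelihood,
)
from bayesbmc.simulate import SimulationDesign, simulate_summary


def _linear_design(seed, sigma=3.0, n_reps=6, b=80.0):
    # b = 80 on the rescaled axis (0.267 %/mg/L) keeps the curve below the
    # 100% ceiling over the whole dose ladder, so no truncation bias
    spec = make_spec("linear", 300.0)
    return SimulationDesign(
        spec=spec,
        theta=ParameterVector({"a": 10.0, "b": b}, sigma=max(sigma, 0.1)),
        sigma=sigma,
        n_reps=n_reps,
        seed=seed,
    )


class TestMcmcConfig:
    def test_defaults_and_draw_count(self):
        c = McmcConfig()
        assert (c.iterations, c.n_chains, c.warmup_fraction, c.seed) == (
            30_000, 1, 0.5, 65_323
        )
        assert c.n_keep == 15_000

    def test_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=500)
        with pytest.raises(ValueError):
            McmcConfig(warmup_fraction=1.0)


class TestFit:
    def test_seed_determinism_bit_exact(self, cm1, fast_mcmc):
        spec = make_spec("exp2", cm1.max_dose)
        f1 = fit(spec, cm1, fast_mcmc)
        f2 = fit(spec, cm1, fast_mcmc)
        for k in f1.params:
            assert np.array_equal(f1.params[k], f2.params[k])
        assert np.array_equal(f1.sigma, f2.sigma)
        assert f1.ppp == f2.ppp and f1.loo_elpd == f2.loo_elpd

    def test_draw_count_matches_config(self, cm1, fast_mcmc):
        f = fit(make_spec("linear", cm1.max_dose), cm1, fast_mcmc)
        assert f.n_draws == fast_mcmc.n_keep

    def test_linear_posterior_matches_wls_oracle(self, cm1):
        """Under the flat-prior constant-variance normal likelihood, the
        marginal posterior of the linear slope is centred on the ordinary
        least-squares slope (a direct matrix solve)."""
        import arviz as az

        spec = make_spec("linear", cm1.max_dose)
        config = McmcConfig(iterations=30_000)
        pr = default_priors(spec, cm1, likelihood="normal")
        f = fit(spec, cm1, config, priors=pr, likelihood="normal")
        X = np.c_[np.ones(len(cm1.doses)), cm1.doses / cm1.max_dose]
        beta = np.linalg.lstsq(X, cm1.means, rcond=None)[0]
        b = f.params["b"]
        ess = float(az.ess(b[None, :]))
        mcse = b.std() / np.sqrt(ess)
        assert abs(b.mean() - beta[1]) < 3 * mcse

    def test_posterior_contraction_with_replication(self):
        """Posterior mean of the slope approaches the truth as replication
        grows (parameter-recovery at n_reps = 3, 30, 300)."""
        errors = []
        for n_reps in (3, 30, 300):
            ds = simulate_summary(_linear_design(seed=10 + n_reps, n_reps=n_reps))
            f = fit(
                make_spec("linear", 300.0), ds,
                McmcConfig(iterations=4_000), likelihood="normal",
            )
            errors.append(abs(float(np.mean(f.params["b"])) - 80.0))
        assert errors[-1] < errors[0]
        assert errors[-1] / 80.0 < 0.05


class TestRhat:
    def test_identical_halves_give_one(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=500)
        # B = 0, so the estimate is sqrt((n-1)/n) — 1 up to O(1/n)
        assert compute_rhat(np.concatenate([half, half])) == pytest.approx(1.0, abs=2e-3)

    def test_offset_halves_diverge(self):
        rng = np.random.default_rng(2)
        draws = np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert compute_rhat(draws) > 1.05

    def test_constant_draws_warn(self):
        with pytest.warns(UserWarning, match="zero within-segment"):
            assert compute_rhat(np.ones(100)) == 1.0

    def test_matches_textbook_formula(self):
        """Independent re-implementation of split-chain PSRF."""
        rng = np.random.default_rng(3)
        draws = np.cumsum(rng.normal(size=2_000)) * 0.05 + rng.normal(size=2_000)
        n = len(draws) // 2
        segs = [draws[:n], draws[n : 2 * n]]
        means = [s.mean() for s in segs]
        vars_ = [s.var(ddof=1) for s in segs]
        w = np.mean(vars_)
        b_over_n = np.var(means, ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert compute_rhat(draws) == pytest.approx(expected, rel=1e-12)


class TestPpp:
    def test_self_consistency_near_half(self):
        """Data simulated from the fitted model family give PPP near 0.5."""
        ppps = []
        for seed in range(20):
            ds = simulate_summary(_linear_design(seed=100 + seed))
            f = fit(
                make_spec("linear", 300.0), ds,
                McmcConfig(iterations=2_000), likelihood="normal",
            )
            ppps.append(f.ppp)
        assert abs(np.mean(ppps) - 0.5) < 0.15

    def test_flat_model_on_steep_data_fails_mean_chisq(self):
        """A forced-flat curve on strongly dosed data is flagged by the
        mean-discrepancy statistic."""
        ds = simulate_summary(_linear_design(seed=4, sigma=2.0))
        spec = make_spec("linear", 300.0)
        pr = default_priors(
            spec, ds, likelihood="normal", overrides={"b": (1e-6, 2e-6)}
        )
        f = fit(spec, ds, McmcConfig(iterations=2_000), priors=pr,
                likelihood="normal")
        assert compute_ppp(f, ds, statistic="mean_chisq") < 0.05

    def test_band_membership_on_real_data(self, cm1, fast_mcmc):
        f = fit(make_spec("exp2", cm1.max_dose), cm1, fast_mcmc)
        assert 0.05 <= f.ppp <= 0.95


class TestLoo:
    def test_identical_models_identical_elpd(self, cm1, fast_mcmc):
        f1 = fit(make_spec("linear", cm1.max_dose), cm1, fast_mcmc)
        f2 = fit(make_spec("linear", cm1.max_dose), cm1, fast_mcmc)
        assert f1.loo_elpd == f2.loo_elpd

    def test_matches_exact_refit_oracle(self):
        """PSIS/WAIC leave-one-group-out agrees with brute-force refits that
        actually exclude each (non-control) group."""
        ds = simulate_summary(_linear_design(seed=9, sigma=2.0, n_reps=4))
        # keep a 6-group ladder so every reduced dataset stays valid
        groups = tuple(g for g in ds.groups if g.dose in (0.0, 10.0, 50.0, 100.0, 200.0, 300.0))
        ds = DoseResponseDataset("x", groups)
        spec = make_spec("linear", ds.max_dose)
        config = McmcConfig(iterations=6_000)
        full = fit(spec, ds, config, likelihood="normal")
        loo = compute_loo(full, ds)

        brute = []
        for i in range(1, len(ds.groups)):  # control stays (dataset invariant)
            reduced = DoseResponseDataset(
                "x", tuple(g for j, g in enumerate(ds.groups) if j != i)
            )
            f = fit(spec, reduced, config, likelihood="normal")
            ll_held = pointwise_log_likelihood(
                spec, f.params, f.sigma, ds, likelihood="normal"
            )[:, i]
            mx = ll_held.max()
            brute.append(mx + np.log(np.mean(np.exp(ll_held - mx))))
        approx = loo.pointwise[1:].sum()
        assert abs(approx - np.sum(brute)) < 1.0

    def test_noise_parameter_does_not_raise_elpd(self):
        """A pure-noise extra parameter (power over linear truth) cannot beat
        the true model by more than small-sample noise."""
        deltas = []
        for seed in range(6):
            ds = simulate_summary(_linear_design(seed=40 + seed))
            cfg = McmcConfig(iterations=3_000)
            f_lin = fit(make_spec("linear", 300.0), ds, cfg)
            f_pow = fit(make_spec("power", 300.0), ds, cfg)
            deltas.append(f_pow.loo_elpd - f_lin.loo_elpd)
        assert np.mean(deltas) < 1.0
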