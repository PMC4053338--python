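"""Sampler correctness on known targets, diagnostics, DIC, HPD, PPC."""
import numpy as np
import pytest

from carrion import mcmc
from carrion.mcmc import Block, McmcConfig, PosteriorFit, dic, gelman_rubin, hpd_interval


def _fit_from_draws(draws, names=None):
    draws = np.asarray(draws, dtype=float)
    return PosteriorFit(
        names=names or [f"p{j}" for j in range(draws.shape[-1])],
        draws=draws,
        rhat=np.ones(draws.shape[-1]),
        acceptance={},
    )


class TestSampler:
    def test_standard_normal_moments(self):
        cfg = McmcConfig(n_chains=3, n_burnin=500, n_keep=2000, thin=1, seed=1)
        fit = mcmc.sample(lambda th: -0.5 * th[0] ** 2, np.zeros((3, 1)) + [[-2], [0], [2]], cfg)
        s = fit.flat("p0")
        assert np.mean(s) == pytest.approx(0.0, abs=0.1)
        assert np.var(s) == pytest.approx(1.0, abs=0.15)

    def test_correlated_normal_recovers_correlation(self):
        rho = 0.7
        prec = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))

        def logp(th):
            return -0.5 * th @ prec @ th

        cfg = McmcConfig(n_chains=3, n_burnin=1500, n_keep=3000, thin=1, seed=2)
        inits = np.array([[-2.0, -2.0], [0.0, 0.0], [2.0, 2.0]])
        fit = mcmc.sample(
            logp, inits, cfg, blocks=[Block("xy", [0, 1], kind="vector")]
        )
        pooled = fit.flat()
        assert np.corrcoef(pooled.T)[0, 1] == pytest.approx(rho, abs=0.05)

    def test_same_seed_bit_identical(self):
        cfg = McmcConfig(n_chains=2, n_burnin=200, n_keep=200, thin=1, seed=9)
        inits = np.array([[-1.0], [1.0]])
        f1 = mcmc.sample(lambda th: -0.5 * th[0] ** 2, inits, cfg)
        f2 = mcmc.sample(lambda th: -0.5 * th[0] ** 2, inits, cfg)
        assert np.array_equal(f1.draws, f2.draws)

    def test_nonfinite_init_rejected(self):
        cfg = McmcConfig(n_chains=1, n_burnin=10, n_keep=10, thin=1, seed=0)
        with pytest.raises(ValueError, match="not finite"):
            mcmc.sample(lambda th: -np.inf, np.zeros((1, 1)), cfg)

    def test_factorized_block_targets_independent_normals(self):
        # three independent normals with different means updated element-wise
        mu = np.array([-1.0, 0.0, 2.0])

        def logp(th):
            return -0.5 * np.sum((th - mu) ** 2)

        def comp(th, name):
            return -0.5 * (th - mu) ** 2

        cfg = McmcConfig(n_chains=3, n_burnin=500, n_keep=2000, thin=1, seed=3)
        inits = np.zeros((3, 3))
        fit = mcmc.sample(
            logp, inits, cfg,
            blocks=[Block("all", [0, 1, 2], kind="factorized")],
            component_logp=comp,
        )
        assert np.allclose(fit.flat().mean(axis=0), mu, atol=0.12)


class TestSerialisation:
    def test_draws_csv_and_diagnostics_sidecar(self, tmp_path):
        import json

        import pandas as pd

        rng = np.random.default_rng(20)
        fit = _fit_from_draws(rng.standard_normal((2, 40, 3)), ["a", "b", "c"])
        fit.acceptance = {"a": 0.4}
        fit.save(tmp_path / "draws.csv", tmp_path / "diag.json")
        df = pd.read_csv(tmp_path / "draws.csv")
        assert list(df.columns) == ["chain", "iteration", "a", "b", "c"]
        assert len(df) == 80
        assert np.allclose(df[["a", "b", "c"]].to_numpy(), fit.flat())
        diag = json.loads((tmp_path / "diag.json").read_text())
        assert diag["converged"] and diag["acceptance"] == {"a": 0.4}


class TestGelmanRubin:
    def test_duplicated_chains_exactly_one(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((1, 500, 2))
        draws = np.concatenate([one, one, one])
        assert np.allclose(gelman_rubin(draws), 1.0, atol=1e-9)

    def test_hand_formula_on_fixed_numbers(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 10.0
        draws = np.stack([a, b])[:, :, None]
        n = 10
        W = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
        B = n * np.var([a.mean(), b.mean()], ddof=1)
        expected = np.sqrt((W + B / n) / W)
        assert gelman_rubin(draws)[0] == pytest.approx(expected, rel=1e-12)

    def test_separated_chains_fail_convergence_gate(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(200)
        b = rng.standard_normal(200) + 10.0
        r = gelman_rubin(np.stack([a, b])[:, :, None])[0]
        assert r >= 1.05
        fit = _fit_from_draws(np.stack([a, b])[:, :, None])
        fit.rhat = np.array([r])
        assert not fit.converged

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 1)))


class TestDic:
    def test_constant_deviance_gives_constant(self):
        assert dic(np.full(100, 42.0), 42.0) == pytest.approx(42.0)

    def test_normal_conjugate_toy_matches_hand_computation(self):
        # y_i ~ N(mu, 1), flat prior: posterior mu ~ N(ybar, 1/n);
        # pD = n * var_post(mu) = 1, so DIC = D(ybar) + 2
        rng = np.random.default_rng(6)
        y = rng.standard_normal(25) + 3.0
        mus = rng.normal(y.mean(), 1 / np.sqrt(len(y)), size=200_000)

        def D(mu):
            return np.sum((y[None, :] - np.atleast_1d(mu)[:, None]) ** 2, axis=1)

        d_draws = D(mus)
        hand = float(D(np.array([y.mean()]))[0]) + 2.0
        assert dic(d_draws, float(D(np.array([mus.mean()]))[0])) == pytest.approx(
            hand, rel=0.02
        )

    def test_noise_parameter_never_shrinks_pd(self):
        # adding a pure-noise parameter adds posterior deviance spread
        rng = np.random.default_rng(7)
        y = rng.standard_normal(25)
        mus = rng.normal(y.mean(), 1 / 5.0, size=100_000)
        extra = rng.normal(0.0, 0.3, size=100_000)  # noise param enters mean

        def D(mu):
            return np.sum((y[None, :] - np.atleast_1d(mu)[:, None]) ** 2, axis=1)

        pd_small = np.mean(D(mus)) - float(D(np.array([np.mean(mus)]))[0])
        mu2 = mus + extra
        pd_big = np.mean(D(mu2)) - float(D(np.array([np.mean(mu2)]))[0])
        assert pd_big >= pd_small


class TestHpd:
    def test_uniform_width(self):
        rng = np.random.default_rng(8)
        s = rng.uniform(0, 1, 200_000)
        lo, hi = hpd_interval(s, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_symmetric_unimodal_close_to_central(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(100_000)
        lo, hi = hpd_interval(s, 0.95)
        assert lo == pytest.approx(np.quantile(s, 0.025), abs=0.05)
        assert hi == pytest.approx(np.quantile(s, 0.975), abs=0.05)

    def test_degenerate_zero_width(self):
        lo, hi = hpd_interval(np.full(50, 3.2), 0.9)
        assert lo == hi == 3.2

    def test_never_wider_than_equal_tailed(self):
        rng = np.random.default_rng(10)
        for dist in (rng.exponential(1, 5000), rng.standard_normal(5000),
                     rng.beta(0.5, 2, 5000)):
            lo, hi = hpd_interval(dist, 0.9)
            qlo, qhi = np.quantile(dist, [0.05, 0.95])
            assert (hi - lo) <= (qhi - qlo) + 1e-9

    def test_rhat_cross_check_against_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(11)
        draws = rng.standard_normal((3, 400, 2))
        draws[2] += 0.5
        ours = gelman_rubin(draws, split=False)
        theirs = az.rhat(az.convert_to_dataset(draws))
        vals = np.array([theirs[v].values for v in theirs.data_vars]).ravel()
        # arviz uses rank-normalised split-rhat; agreement is approximate
        assert np.allclose(ours, vals, atol=0.08)


class TestPosteriorPredictive:
    def test_constant_discrepancy_ties_count(self):
        fit = _fit_from_draws(np.zeros((2, 50, 1)))
        p = mcmc.posterior_predictive_pvalue(
            fit,
            replicate_generator=lambda th, rng: rng.standard_normal(5),
            discrepancy=lambda y, th: 1.0,
            observed_data=np.zeros(5),
            n_rep=100,
            seed=0,
        )
        assert p == 1.0

    def test_extreme_observation_flagged(self):
        # observed data far in the tail of the predictive => p near 0
        rng = np.random.default_rng(12)
        fit = _fit_from_draws(rng.normal(0, 0.05, (2, 200, 1)))
        p = mcmc.posterior_predictive_pvalue(
            fit,
            replicate_generator=lambda th, r: r.normal(th[0], 1.0, 20),
            discrepancy=lambda y, th: float(np.mean(y)),
            observed_data=np.full(20, 5.0),
            n_rep=500,
            seed=1,
        )
        assert p < 0.05
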