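"""Sampling engine validated on targets with known moments, plus
diagnostics and draw post-processing."""

import numpy as np
import pytest
from scipy import stats

from dietmix.mixing_model import Block, LogPosterior, _sb_identity, _sb_simplex
from dietmix.sampler import (
    PosteriorDraws,
    combine_sources,
    compare_spread,
    ess,
    rhat,
    run_chains,
    summarize,
)


def toy_lp(logdensity, dim, name="x", init=None):
    b = Block(name=name, kind="rwm", shape=(dim,), init=init if init is not None else np.zeros(dim))
    b.subblocks = [_sb_identity(name, slice(None), ("ll",), dim)]
    return LogPosterior([b], {"ll": lambda s: float(logdensity(s[name]))}, meta={})


def dirichlet_lp(alpha):
    n = len(alpha)
    b = Block(name="pi", kind="rwm", shape=(n,), init=np.full(n, 1.0 / n))
    b.subblocks = [_sb_simplex("pi", None, ("prior",), n)]
    return LogPosterior(
        [b],
        {"prior": lambda s: float(stats.dirichlet.logpdf(s["pi"] / s["pi"].sum(), alpha))},
        meta={"species": [f"s{i}" for i in range(n)]},
    )


class TestRunChains:
    def test_standard_normal_moments(self):
        lp = toy_lp(lambda x: -0.5 * (x**2).sum(), 2)
        d = run_chains(lp, n_chains=2, n_iter=10000, seed=1)
        flat = d.draws.reshape(-1, 2)
        mc_err = 3.0 / np.sqrt(len(flat) / 20)  # generous autocorrelation allowance
        assert np.abs(flat.mean(0)).max() < mc_err
        np.testing.assert_allclose(np.cov(flat.T), np.eye(2), atol=0.1)

    def test_dirichlet_prior_only_marginals(self):
        d = run_chains(dirichlet_lp([1.0, 1.0, 1.0]), n_chains=2, n_iter=15000, seed=2)
        flat = d.draws.reshape(-1, 3)
        np.testing.assert_allclose(flat.mean(0), 1 / 3, atol=0.02)
        np.testing.assert_allclose(flat.std(0), np.sqrt(1 / 18), atol=0.02)
        np.testing.assert_allclose(flat.sum(1), 1.0, atol=1e-9)

    def test_identical_seed_bit_identical(self):
        lp = toy_lp(lambda x: -0.5 * (x**2).sum(), 3)
        a = run_chains(lp, n_chains=2, n_iter=500, seed=7)
        b = run_chains(lp, n_chains=2, n_iter=500, seed=7)
        assert np.array_equal(a.draws, b.draws)
        c = run_chains(lp, n_chains=2, n_iter=500, seed=8)
        assert not np.array_equal(a.draws, c.draws)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            run_chains(toy_lp(lambda x: -(x**2).sum(), 1), n_chains=1, n_iter=100)

    def test_initialization_failure_reported(self):
        lp = toy_lp(lambda x: -np.inf, 2)
        with pytest.raises(Exception, match="initial"):
            run_chains(lp, n_chains=2, n_iter=100, seed=1)


class TestDiagnostics:
    def iid_draws(self, rho=0.0, n=5000, chains=2, seed=0):
        rng = np.random.default_rng(seed)
        x = np.empty((chains, n))
        for c in range(chains):
            e = rng.standard_normal(n)
            z = np.empty(n)
            z[0] = e[0]
            for t in range(1, n):
                z[t] = rho * z[t - 1] + np.sqrt(1 - rho**2) * e[t]
            x[c] = z
        return PosteriorDraws(x[..., None], ["x"], 0, {}, {})

    def test_rhat_iid_near_one(self):
        assert rhat(self.iid_draws())["x"] < 1.01

    def test_rhat_separated_constants_large(self):
        x = np.stack([np.zeros(200), np.ones(200)])[..., None]
        x += np.random.default_rng(0).normal(0, 1e-3, x.shape)
        # rank-normalization bounds the statistic, but it must clearly
        # exceed the 1.1 convergence gate
        assert rhat(PosteriorDraws(x, ["x"], 0, {}, {}))["x"] > 1.5

    def test_ess_ar1_closed_form(self):
        n, rho = 5000, 0.9
        d = self.iid_draws(rho=rho, n=n)
        expected = 2 * n * (1 - rho) / (1 + rho)
        assert ess(d)["x"] == pytest.approx(expected, rel=0.25)

    def test_constant_parameter_flagged_values(self):
        x = np.concatenate(
            [np.ones((2, 100, 1)), np.random.default_rng(1).normal(size=(2, 100, 1))],
            axis=2,
        )
        d = PosteriorDraws(x, ["const", "free"], 0, {}, {})
        assert rhat(d)["const"] == 1.0
        assert ess(d)["const"] == 200.0  # 2 chains x 100 draws


class TestSummarize:
    def test_symmetric_prior_equal_means(self):
        d = run_chains(dirichlet_lp([1.0, 1.0, 1.0]), n_chains=2, n_iter=15000, seed=3)
        s = summarize(d)
        assert s["mean"].max() - s["mean"].min() < 0.03

    def test_interval_endpoints_monotone_in_level(self):
        d = run_chains(toy_lp(lambda x: -0.5 * (x**2).sum(), 1), n_chains=2, n_iter=4000, seed=4)
        s = summarize(d, levels=(0.5, 0.9, 0.99))
        row = s.iloc[0]
        assert row["ci50_lo"] > row["ci90_lo"] > row["ci99_lo"]
        assert row["ci50_hi"] < row["ci90_hi"] < row["ci99_hi"]


class TestCombineSources:
    @pytest.fixture
    def draws(self):
        d = run_chains(dirichlet_lp([1.0, 1.0, 1.0]), n_chains=2, n_iter=2000, seed=5)
        d.names = ["pi[s0]", "pi[s1]", "pi[s2]"]
        return d

    def test_trivial_partition_identity(self, draws):
        g = combine_sources(draws, {"s0": "a", "s1": "b", "s2": "c"})
        np.testing.assert_array_equal(
            g.draws, draws.draws[:, :, [draws.index("pi[s0]"), draws.index("pi[s1]"), draws.index("pi[s2]")]]
        )

    def test_single_group_sums_to_one(self, draws):
        g = combine_sources(draws, {"s0": "all", "s1": "all", "s2": "all"})
        np.testing.assert_allclose(g.draws, 1.0, atol=1e-9)

    def test_two_groups_sum_to_one_per_draw(self, draws):
        g = combine_sources(draws, {"s0": "fish", "s1": "fish", "s2": "crust"})
        total = g.draws.sum(axis=2)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        assert g.names == ["pi[fish]", "pi[crust]"]

    def test_non_partition_rejected(self, draws):
        with pytest.raises(ValueError, match="partition"):
            combine_sources(draws, {"s0": "a", "s1": "b"})


class TestCompareSpread:
    def make(self, x):
        return PosteriorDraws(x[..., None], ["pi[a]"], 0, {}, {"species": ["a"]})

    def test_identical_draws_unit_ratio(self):
        x = np.random.default_rng(0).normal(size=(2, 500))
        out = compare_spread(self.make(x), self.make(x.copy()))
        assert out.loc["pi[a]", "sd_ratio"] == pytest.approx(1.0)

    def test_doubled_spread_gives_half_ratio(self):
        x = np.random.default_rng(1).normal(size=(2, 500))
        y = x.mean() + 2.0 * (x - x.mean())
        out = compare_spread(self.make(x), self.make(y))
        assert out.loc["pi[a]", "sd_ratio"] == pytest.approx(0.5)
        assert out.loc["pi[a]", "w95_ratio"] == pytest.approx(0.5, rel=0.05)
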