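"""Mixing-model likelihoods and priors against independent oracles.

The oracle implementations (tests/oracles.py) recompute every term with
explicit loops, scipy densities and inline transform formulas, sharing no
code with the package's vectorized likelihood paths.
"""

import numpy as np
import pytest
from scipy import stats

from oracles import (
    o_alr,
    o_alr_inv,
    o_tau,
    oracle_fa_loglik,
    oracle_si_loglik,
    random_instance,
)

from dietmix.data_io import CoefficientPriors, dataset_from_arrays
from dietmix.mixing_model import (
    DietState,
    ModelConfigError,
    ModelSpec,
    build_model,
    compute_tau,
    fa_loglik,
    log_prior,
    moment_matched_gamma,
    moment_matched_lognormal,
    si_expected,
    si_loglik,
)

# --------------------------------------------------------------------------
# compute_tau / si_expected
# --------------------------------------------------------------------------


class TestComputeTau:
    def test_single_prey_diet(self):
        phi = np.array([[0.5, 0.3, 0.2], [0.1, 0.1, 0.8]])
        tau = compute_tau([1.0, 0.0], np.ones((2, 3)), phi, [1.0, 1.0])
        np.testing.assert_allclose(tau.parts, phi[0])

    def test_two_source_mixture(self):
        phi = np.array([[0.5, 0.5], [0.9, 0.1]])
        tau = compute_tau([0.5, 0.5], np.ones((2, 2)), phi, [1.0, 1.0])
        np.testing.assert_allclose(tau.parts, [0.7, 0.3])

    def test_fat_scale_invariance(self):
        rng = np.random.default_rng(0)
        phi = rng.dirichlet(np.ones(4), size=3)
        kappa = rng.random((3, 4)) + 0.5
        pi = rng.dirichlet(np.ones(3))
        fat = np.array([1.0, 2.0, 0.5])
        a = compute_tau(pi, kappa, phi, fat).parts
        b = compute_tau(pi, kappa, phi, 2.0 * fat).parts
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_unequal_fat_content(self):
        phi = np.array([[0.5, 0.5], [0.9, 0.1]])
        tau = compute_tau([0.5, 0.5], np.ones((2, 2)), phi, [2.0, 1.0])
        np.testing.assert_allclose(tau.parts, [1.9 / 3.0, 1.1 / 3.0])

    def test_no_conversion_limit_is_plain_mixture(self):
        rng = np.random.default_rng(1)
        phi = rng.dirichlet(np.ones(5), size=3)
        pi = rng.dirichlet(np.ones(3))
        tau = compute_tau(pi, np.ones((3, 5)), phi, np.ones(3)).parts
        np.testing.assert_allclose(tau, pi @ phi, atol=1e-12)


class TestSiExpected:
    def test_mixture_with_fractionation(self):
        got = si_expected([0.5, 0.5], np.array([[-20.0], [-10.0]]), np.ones((2, 1)))
        np.testing.assert_allclose(got, [-14.0])

    def test_unit_vector_diet(self):
        prey = np.array([[-20.0, 8.0], [-15.0, 12.0]])
        g = np.array([[1.0, 3.4], [1.0, 3.4]])
        np.testing.assert_allclose(si_expected([0, 1], prey, g), [-14.0, 15.4])

    def test_zero_fractionation(self):
        prey = np.array([[-20.0], [-10.0]])
        np.testing.assert_allclose(
            si_expected([0.3, 0.7], prey, np.zeros((2, 1))), [-13.0]
        )


# --------------------------------------------------------------------------
# likelihood oracle equivalence
# --------------------------------------------------------------------------


@pytest.mark.parametrize("latent", [False, True], ids=["mean-prey", "latent"])
def test_loglik_matches_direct_summation_oracle(latent):
    rng = np.random.default_rng(42)
    for _ in range(60):
        d, state = random_instance(rng)
        spec = ModelSpec(markers="both", latent_prey=latent)
        assert fa_loglik(d, state, spec) == pytest.approx(
            oracle_fa_loglik(d, state, latent), abs=1e-10
        )
        assert si_loglik(d, state, spec) == pytest.approx(
            oracle_si_loglik(d, state, latent), abs=1e-10
        )


def test_predator_term_peaks_at_mode_and_decays_along_eigenvectors():
    rng = np.random.default_rng(3)
    d, state = random_instance(rng, n=2, p=4, J=1, n_iso=1)
    spec = ModelSpec(markers="both", latent_prey=False)
    phi = np.array([o_alr_inv(m) for m in state.mu_fa])
    tau = o_tau(state.pi, state.kappa, phi, state.fat)
    # place the predator exactly at its expected signature
    d.predators.fa[0] = tau
    base = fa_loglik(d, state, spec)
    w, V = np.linalg.eigh(state.Sigma_tau)
    prev = base
    for step in (0.5, 1.0, 2.0):
        t = o_alr(tau) + step * np.sqrt(w[0]) * V[:, 0]
        d.predators.fa[0] = o_alr_inv(t)
        cur = fa_loglik(d, state, spec)
        assert cur < prev
        prev = cur


def test_nonpd_covariance_gives_minus_inf():
    rng = np.random.default_rng(4)
    d, state = random_instance(rng, n=2, p=4, J=2, n_iso=2)
    spec = ModelSpec(markers="both", latent_prey=False)
    state.Sigma_tau = np.array(state.Sigma_tau)
    state.Sigma_tau[0, 0] = -1.0
    assert fa_loglik(d, state, spec) == -np.inf


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------


class TestPriors:
    def test_gamma_moment_matching(self):
        shape, rate = moment_matched_gamma(1.0, 0.25)
        assert (shape, rate) == (4.0, 4.0)

    def test_lognormal_moment_matching(self):
        mu, sd = moment_matched_lognormal(2.0, 0.5)
        m = np.exp(mu + sd**2 / 2)
        v = (np.exp(sd**2) - 1) * np.exp(2 * mu + sd**2)
        assert m == pytest.approx(2.0)
        assert v == pytest.approx(0.5)

    def test_flat_dirichlet_is_constant(self):
        rng = np.random.default_rng(5)
        d, state = random_instance(rng, n=3, p=4, J=1, n_iso=1)
        d.priors.kappa_var[:] = 0
        d.priors.fat_var[:] = 0
        state.kappa = d.priors.kappa_mean
        state.fat = d.priors.fat_mean
        state.mu_fa = None
        state.Sigma_tau = None
        state.mu_si = None
        state.Sigma_tau_si = None
        spec = ModelSpec(markers="fa", alpha=1.0)
        vals = []
        for _ in range(5):
            state.pi = rng.dirichlet(np.ones(3))
            vals.append(log_prior(state, spec, d))
        np.testing.assert_allclose(vals, np.log(2.0), atol=1e-12)  # log Gamma(3)

    def test_kappa_prior_matches_scipy_gamma(self):
        rng = np.random.default_rng(6)
        d, state = random_instance(rng, n=2, p=3, J=1, n_iso=1)
        d.priors.kappa_mean[:] = 1.0
        d.priors.kappa_var[:] = 0.25
        d.priors.fat_var[:] = 0
        state.fat = d.priors.fat_mean
        state.mu_fa = None
        state.Sigma_tau = None
        state.mu_si = None
        state.Sigma_tau_si = None
        state.pi = np.array([0.5, 0.5])
        spec = ModelSpec(markers="fa")
        base = log_prior(state, spec, d)
        expected = stats.gamma.logpdf(state.kappa, a=4.0, scale=0.25).sum()
        dirich = stats.dirichlet.logpdf(state.pi, [1, 1])
        assert base == pytest.approx(expected + dirich, abs=1e-10)

    def test_zero_variance_pins_coefficients(self):
        """kappa/fat with zero prior variance are fixed, not sampled."""
        rng = np.random.default_rng(7)
        d, _ = random_instance(rng, n=2, p=3, J=2, n_iso=1)
        d.priors.kappa_var[:] = 0
        d.priors.fat_var[:] = 0
        lp = build_model(d, ModelSpec(markers="fa", latent_prey=False))
        names = [b.name for b in lp.sampled_blocks]
        assert "kappa" not in names and "fat" not in names


# --------------------------------------------------------------------------
# build_model bookkeeping
# --------------------------------------------------------------------------


class TestBuildModel:
    @pytest.fixture
    def inst(self):
        rng = np.random.default_rng(8)
        return random_instance(rng, n=2, p=4, J=3, n_iso=2)

    def test_dimension_bookkeeping(self, inst):
        d, _ = inst
        d.priors.kappa_var[:] = 0
        d.priors.fat_var[:] = 0
        lp = build_model(d, ModelSpec(markers="fa", latent_prey=False))
        dims = {b.name: b.u_size for b in lp.sampled_blocks}
        # simplex block counts n-1 unconstrained coordinates
        assert sum(sb.size for sb in lp.blocks[0].subblocks) == 1
        # the predator residual covariance is integrated out analytically,
        # so only prey-distribution blocks and pi are sampled
        assert set(dims) == {"pi", "mu_fa", "Sigma_fa"}

    def test_joint_dimension_is_sum_minus_shared_pi(self, inst):
        d, _ = inst
        fa = build_model(d, ModelSpec(markers="fa", latent_prey=False))
        si = build_model(d, ModelSpec(markers="si", latent_prey=False))
        both = build_model(d, ModelSpec(markers="both", latent_prey=False))
        pi_dim = 1  # 2 species
        assert both.dim == fa.dim + si.dim - pi_dim

    def test_value_finite_at_init_and_minus_inf_off_simplex(self, inst):
        d, _ = inst
        lp = build_model(d, ModelSpec(markers="fa", latent_prey=False))
        theta = lp.pack(lp.init_state())
        assert np.isfinite(lp.value(theta))
        state = lp.init_state()
        state["pi"] = np.array([-0.2, 1.2])
        assert lp.value(lp.pack(state)) == -np.inf

    def test_si_without_fractionation_priors_rejected(self, inst):
        d, _ = inst
        d.priors.frac_mean = None
        d.priors.frac_sd = None
        with pytest.raises(ModelConfigError, match="fractionation"):
            build_model(d, ModelSpec(markers="si"))

    def test_linear_grouping_requires_design(self):
        with pytest.raises(ModelConfigError, match="design"):
            ModelSpec(markers="fa", grouping="linear")
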