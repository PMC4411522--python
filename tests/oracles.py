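"""Independent oracle implementations shared across tests.

Everything here recomputes model quantities with explicit loops, scipy
densities and inline transform formulas; no code is shared with the
package's vectorized likelihood paths.
"""

import numpy as np
from scipy import stats

from dietmix.data_io import CoefficientPriors, dataset_from_arrays
from dietmix.mixing_model import DietState


def o_alr(x):
    return np.log(np.asarray(x[:-1]) / x[-1])


def o_alr_inv(y):
    e = np.concatenate([np.exp(y), [1.0]])
    return e / e.sum()


def o_tau(pi, kappa, phi, fat):
    p = phi.shape[1]
    acc = np.zeros(p)
    for s in range(len(pi)):
        acc += (pi[s] * fat[s]) * (kappa[s] * phi[s])
    return acc / acc.sum()


def oracle_fa_loglik(d, state, latent):
    total = 0.0
    for si_, sp in enumerate(d.species):
        for row in d.prey.fa[d.prey.fa_species == sp]:
            total += stats.multivariate_normal.logpdf(
                o_alr(row), state.mu_fa[si_], state.Sigma_fa[si_]
            )
    J = d.predators.fa.shape[0]
    for j in range(J):
        if latent:
            phi_j = state.phi[j]
            for si_ in range(len(d.species)):
                total += stats.multivariate_normal.logpdf(
                    o_alr(phi_j[si_]), state.mu_fa[si_], state.Sigma_fa[si_]
                )
        else:
            phi_j = np.array([o_alr_inv(m) for m in state.mu_fa])
        pi_j = state.pi_ind[j] if state.pi_ind is not None else state.pi
        tau = o_tau(pi_j, state.kappa, phi_j, state.fat)
        total += stats.multivariate_normal.logpdf(
            o_alr(d.predators.fa[j]), o_alr(tau), state.Sigma_tau
        )
    return total


def oracle_si_loglik(d, state, latent):
    total = 0.0
    for si_, sp in enumerate(d.species):
        for row in d.prey.si[d.prey.si_species == sp]:
            total += stats.multivariate_normal.logpdf(
                row, state.mu_si[si_], state.Sigma_si[si_]
            )
    J = d.predators.si.shape[0]
    for j in range(J):
        pi_j = state.pi_ind[j] if state.pi_ind is not None else state.pi
        mean = np.zeros(d.prey.si.shape[1])
        for si_ in range(len(d.species)):
            x = state.x_si[j, si_] if latent else state.mu_si[si_]
            if latent:
                total += stats.multivariate_normal.logpdf(
                    x, state.mu_si[si_], state.Sigma_si[si_]
                )
            mean += pi_j[si_] * (x + state.gamma[si_])
        total += stats.multivariate_normal.logpdf(
            d.predators.si[j], mean, state.Sigma_tau_si
        )
    for si_ in range(len(d.species)):
        for k in range(d.prey.si.shape[1]):
            if d.priors.frac_sd[si_, k] > 0:
                total += stats.norm.logpdf(
                    state.gamma[si_, k],
                    d.priors.frac_mean[si_, k],
                    d.priors.frac_sd[si_, k],
                )
    return total


def random_instance(rng, n=None, p=None, J=None, n_iso=None):
    """A random small dataset + full parameter state for oracle checks."""
    n = n or rng.integers(2, 4)
    p = p or rng.integers(3, 5)
    J = J or rng.integers(1, 4)
    n_iso = n_iso or rng.integers(1, 4)
    m = 3
    species = [f"s{i}" for i in range(n)]

    def comps(k, q):
        x = rng.random((k, q)) + 0.1
        return x / x.sum(1, keepdims=True)

    def spd(q):
        a = rng.normal(size=(q, q)) * 0.3
        return a @ a.T + 0.3 * np.eye(q)

    priors = CoefficientPriors(
        kappa_mean=rng.random((n, p)) + 0.5,
        kappa_var=rng.random((n, p)) * 0.2,
        fat_mean=rng.random(n) + 0.5,
        fat_var=rng.random(n) * 0.2,
        frac_mean=rng.normal(2.0, 1.0, size=(n, n_iso)),
        frac_sd=rng.random((n, n_iso)) * 0.5 + 0.1,
    )
    d = dataset_from_arrays(
        species=species,
        fa_names=[f"f{i}" for i in range(p)],
        prey_fa=comps(n * m, p),
        prey_fa_species=np.repeat(species, m),
        predator_fa=comps(J, p),
        iso_names=[f"i{i}" for i in range(n_iso)],
        prey_si=rng.normal(0, 2, size=(n * m, n_iso)),
        prey_si_species=np.repeat(species, m),
        predator_si=rng.normal(0, 2, size=(J, n_iso)),
        priors=priors,
    )
    state = DietState(
        pi=rng.dirichlet(np.ones(n)),
        kappa=rng.random((n, p)) + 0.5,
        fat=rng.random(n) + 0.5,
        mu_fa=rng.normal(size=(n, p - 1)),
        Sigma_fa=np.array([spd(p - 1) for _ in range(n)]),
        Sigma_tau=spd(p - 1),
        mu_si=rng.normal(size=(n, n_iso)),
        Sigma_si=np.array([spd(n_iso) for _ in range(n)]),
        Sigma_tau_si=spd(n_iso),
        gamma=rng.normal(2, 0.5, size=(n, n_iso)),
        phi=comps(J * n, p).reshape(J, n, p),
        x_si=rng.normal(0, 2, size=(J, n, n_iso)),
    )
    return d, state
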