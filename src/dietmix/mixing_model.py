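"""Log-prior and log-likelihood assembly for the diet mixing models.

The generative model: prey fatty-acid (FA) profiles are logistic-normal
per species (``alr(y) ~ N(mu_s, Sigma_s)``); a predator's expected profile
is the closure of consumed prey profiles weighted by diet proportions
``pi``, fat content ``Phi`` and per-FA conversion coefficients ``kappa``;
observed predator profiles scatter around it with covariance ``Sigma_tau``
in alr space. Stable-isotope (SI) signatures mix linearly with additive
trophic fractionation ``gamma``. FA-only, SI-only and joint models share
the diet-proportion block; diets may be modelled at the population level
(Dirichlet prior), per individual (hierarchical logistic-normal), or as a
linear model on predator covariates.

Every model variant is compiled by :func:`build_model` into a
:class:`LogPosterior`: parameter blocks plus factorized log-density terms,
consumed by :mod:`dietmix.sampler`.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import multigammaln

from .compositions import (
    Composition,
    alr_inv_mat,
    alr_mat,
    closure,
    ilr_basis,
    ilr_inv_mat,
    ilr_log_jacobian,
    ilr_mat,
)
from .data_io import CoefficientPriors, DietDataset

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


class ModelConfigError(ValueError):
    """The requested model cannot be built from the given dataset."""


class InvalidStateError(ValueError):
    """A parameter state violates model constraints."""


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------


def mvn_logpdf_sum(x: np.ndarray, mean, cov: np.ndarray) -> float:
    """Sum of MVN log-densities over the rows of ``x``; -inf if ``cov`` is
    not symmetric positive-definite."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    resid = x - np.asarray(mean, dtype=float)
    d = x.shape[1]
    cov = np.atleast_2d(cov)
    if not np.all(np.isfinite(cov)):
        return -np.inf
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diagonal(L)).sum()
    y = np.linalg.solve(L, resid.T)
    quad = float((y * y).sum())
    return float(-0.5 * (quad + x.shape[0] * (d * LOG2PI + logdet)))


def _is_pd(cov: np.ndarray) -> bool:
    cov = np.atleast_2d(cov)
    if not np.all(np.isfinite(cov)):
        return False
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def moment_matched_gamma(mean: float, var: float) -> tuple[float, float]:
    """(shape, rate) of a gamma distribution with the given moments."""
    if mean <= 0 or var <= 0:
        raise ValueError("need mean > 0 and var > 0")
    return mean * mean / var, mean / var


def moment_matched_lognormal(mean: float, var: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and variance."""
    if mean <= 0 or var <= 0:
        raise ValueError("need mean > 0 and var > 0")
    s2 = np.log1p(var / (mean * mean))
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def _iw_logpdf(cov: np.ndarray, df: float, scale: np.ndarray) -> float:
    """Inverse-Wishart log-density (cholesky-based; -inf off the cone)."""
    cov = np.atleast_2d(cov)
    scale = np.atleast_2d(scale)
    k = scale.shape[0]
    if not np.all(np.isfinite(cov)):
        return -np.inf
    try:
        Lc = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    ld_c = 2.0 * np.log(np.diagonal(Lc)).sum()
    Ls = np.linalg.cholesky(scale)
    ld_s = 2.0 * np.log(np.diagonal(Ls)).sum()
    tr = float(np.trace(np.linalg.solve(cov, scale)))
    return float(
        0.5 * df * ld_s
        - 0.5 * df * k * np.log(2.0)
        - multigammaln(0.5 * df, k)
        - 0.5 * (df + k + 1) * ld_c
        - 0.5 * tr
    )


def _matrix_t_logpdf(R: np.ndarray, df0: float, S0: np.ndarray) -> float:
    """Marginal log-density of residual rows R (J x d) with the row
    covariance integrated out against an inverse-Wishart(df0, S0) prior:
    ``int prod_j N(r_j; 0, Sigma) IW(Sigma; df0, S0) dSigma``."""
    R = np.atleast_2d(R)
    J, d = R.shape
    S = S0 + R.T @ R
    sign, ld_S = np.linalg.slogdet(S)
    if sign <= 0:
        return -np.inf
    ld_S0 = np.linalg.slogdet(S0)[1]
    return float(
        multigammaln(0.5 * (df0 + J), d)
        - multigammaln(0.5 * df0, d)
        - 0.5 * J * d * np.log(np.pi)
        + 0.5 * df0 * ld_S0
        - 0.5 * (df0 + J) * ld_S
    )


def _invwishart_rvs(df: float, S: np.ndarray, rng) -> np.ndarray:
    """One inverse-Wishart(df, S) draw via the Bartlett decomposition."""
    S = np.atleast_2d(S)
    k = S.shape[0]
    L = np.linalg.cholesky(S)
    A = np.zeros((k, k))
    A[np.diag_indices(k)] = np.sqrt(rng.chisquare(df - np.arange(k)))
    if k > 1:
        A[np.tril_indices(k, -1)] = rng.standard_normal(k * (k - 1) // 2)
    B = np.linalg.solve(A, L.T)
    return B.T @ B


def _iw_gibbs(resid: np.ndarray, df0: float, S0: np.ndarray, rng) -> np.ndarray:
    resid = np.atleast_2d(resid)
    df = df0 + resid.shape[0]
    S = S0 + resid.T @ resid
    return _invwishart_rvs(df, 0.5 * (S + S.T), rng)


def _conjugate_mean_cov(rows: np.ndarray, cov: np.ndarray, prior_sd: float):
    """Conditional (mean, chol(cov)) of mu | rows, with rows_i ~ N(mu, cov)
    and mu ~ N(0, prior_sd^2 I)."""
    rows = np.atleast_2d(rows)
    m, d = rows.shape
    cov_inv = np.linalg.inv(np.atleast_2d(cov))
    prec = m * cov_inv + np.eye(d) / prior_sd**2
    post_cov = np.linalg.inv(prec)
    post_cov = 0.5 * (post_cov + post_cov.T)
    mean = post_cov @ (m * (cov_inv @ rows.mean(axis=0)))
    return mean, np.linalg.cholesky(post_cov)


def _mvn_conjugate_mean(rows: np.ndarray, cov: np.ndarray, prior_sd: float, rng):
    """Draw mu | rows, with rows_i ~ N(mu, cov) and mu ~ N(0, prior_sd^2 I)."""
    mean, L = _conjugate_mean_cov(rows, cov, prior_sd)
    return mean + L @ rng.standard_normal(mean.size)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PreyDistribution:
    """Species-level distribution parameters in transformed space."""

    mu_fa: np.ndarray | None = None  # (n, p-1) alr means
    Sigma_fa: np.ndarray | None = None  # (n, p-1, p-1)
    mu_si: np.ndarray | None = None  # (n, n_iso)
    Sigma_si: np.ndarray | None = None  # (n, n_iso, n_iso)

    @classmethod
    def from_library(cls, prey, alr_ref: int = -1) -> "PreyDistribution":
        """Sample moments of each species' transformed profiles (used for
        initialization and for fixed-prey model variants)."""
        out = cls()
        if prey.fa is not None:
            rows = alr_mat(prey.fa, ref=alr_ref)
            k = rows.shape[1]
            mus, sigmas = [], []
            for s in prey.species:
                r = rows[prey.fa_species == s]
                mus.append(r.mean(axis=0))
                cov = np.cov(r.T, ddof=1) if r.shape[0] > 1 else np.eye(k)
                sigmas.append(np.atleast_2d(cov) + 1e-8 * np.eye(k))
            out.mu_fa = np.asarray(mus)
            out.Sigma_fa = np.asarray(sigmas)
        if prey.si is not None:
            k = prey.si.shape[1]
            mus, sigmas = [], []
            for s in prey.species:
                r = prey.si[prey.si_species == s]
                mus.append(r.mean(axis=0))
                cov = np.cov(r.T, ddof=1) if r.shape[0] > 1 else np.eye(k)
                sigmas.append(np.atleast_2d(cov) + 1e-8 * np.eye(k))
            out.mu_si = np.asarray(mus)
            out.Sigma_si = np.asarray(sigmas)
        return out


@dataclasses.dataclass
class DietState:
    """A full parameter state for likelihood/prior evaluation.

    ``pi`` is the population diet composition; ``pi_ind`` holds one row
    per predator for individual/linear groupings. Latent consumed prey
    profiles ``phi`` (predator x species, composition space) and latent
    consumed SI values ``x_si`` are present in latent-prey mode.
    """

    pi: np.ndarray | None = None  # (n,)
    pi_ind: np.ndarray | None = None  # (J, n)
    kappa: np.ndarray | None = None  # (n, p)
    fat: np.ndarray | None = None  # (n,)
    mu_fa: np.ndarray | None = None
    Sigma_fa: np.ndarray | None = None
    Sigma_tau: np.ndarray | None = None
    mu_si: np.ndarray | None = None
    Sigma_si: np.ndarray | None = None
    Sigma_tau_si: np.ndarray | None = None
    gamma: np.ndarray | None = None  # (n, n_iso)
    phi: np.ndarray | None = None  # (J, n, p) compositions
    x_si: np.ndarray | None = None  # (J, n, n_iso)
    Pi: np.ndarray | None = None  # (n-1,) ilr coordinates
    Sigma_Pi: np.ndarray | None = None
    B: np.ndarray | None = None  # (q, n-1)


@dataclasses.dataclass
class ModelSpec:
    """Declarative model choice: markers x grouping x options."""

    markers: str = "both"  # "fa" | "si" | "both"
    grouping: str = "population"  # "population" | "individual" | "linear"
    design: np.ndarray | None = None  # (J, q), required for "linear"
    alpha: float = 1.0  # symmetric Dirichlet concentration (population)
    sigma_prey_scale: float = 0.1  # IW scale diagonal for Sigma_s
    sigma_resid_scale: float = 0.01  # IW scale diagonal for Sigma_tau
    sigma_diet_scale: float = 0.1  # IW scale diagonal for Sigma_Pi
    mu_prior_sd: float = 10.0  # vague prior SD for alr-space prey means
    mu_si_prior_sd: float = 1000.0  # vague prior SD for SI prey means (per mil)
    # consumed-prey treatment: "latent" samples per-predator consumed prey
    # items (the full model); "mean" substitutes species means (fast,
    # ignores consumed-prey variability); "linearized" integrates the
    # consumed-prey variability analytically (delta method on the FA side,
    # exact on the SI side). Booleans are accepted: True = "latent",
    # False = "mean".
    latent_prey: bool | str = True
    alr_ref: int = -1
    fix: dict = dataclasses.field(default_factory=dict)

    @property
    def prey_mode(self) -> str:
        if self.latent_prey is True:
            return "latent"
        if self.latent_prey is False:
            return "mean"
        return str(self.latent_prey)

    def __post_init__(self) -> None:
        if self.prey_mode not in ("latent", "mean", "linearized"):
            raise ModelConfigError(f"unknown prey mode {self.latent_prey!r}")
        if self.markers not in ("fa", "si", "both"):
            raise ModelConfigError(f"unknown markers {self.markers!r}")
        if self.grouping not in ("population", "individual", "linear"):
            raise ModelConfigError(f"unknown grouping {self.grouping!r}")
        if (
            self.grouping == "linear"
            and self.design is None
            and "pi_ind" not in self.fix
        ):
            raise ModelConfigError("linear grouping requires a design matrix")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def compute_tau(pi, kappa, phi, fat) -> Composition:
    """Expected predator FA profile: closure of consumed prey profiles
    weighted by diet proportion, fat content and conversion coefficients.

    ``tau = C( sum_s (pi_s * Phi_s) * (kappa_s ⊙ phi_s) )``
    """
    pi = np.asarray(pi, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    phi = np.asarray(phi, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if not (pi.shape[0] == kappa.shape[0] == phi.shape[0] == fat.shape[0]):
        raise ValueError("species dimensions disagree")
    w = ((pi * fat)[:, None] * kappa * phi).sum(axis=0)
    if not np.all(np.isfinite(w)) or w.sum() <= 0:
        raise InvalidStateError("pre-closure profile is zero or non-finite")
    return closure(w)


def _tau_matrix(pi_mat, kappa, phi, fat):
    """Row-wise tau for J predators; ``phi`` is (n, p) shared consumed
    profiles or (J, n, p) per-predator latent profiles. None on invalid."""
    w = pi_mat * fat  # (J, n)
    if phi.ndim == 2:
        pre = w @ (kappa * phi)  # (J, p)
    else:
        pre = np.einsum("jn,jnp->jp", w, kappa[None, :, :] * phi)
    s = pre.sum(axis=1, keepdims=True)
    if np.any(s <= 0) or not np.all(np.isfinite(pre)):
        return None
    return pre / s


def _linearized_fa_meanvar(mu_fa, Sigma_fa, kappa, fat, pi_vec, ref):
    """Delta-method mean and covariance of a predator's alr signature when
    consumed prey items vary around the species distributions.

    Returns (m, Omega): the alr signature at the species means and the
    propagated covariance sum_s A_s Sigma_s A_s', where A_s is the
    Jacobian of the alr signature w.r.t. species s's consumed alr profile.
    """
    n, k = mu_fa.shape
    p = k + 1
    r = ref % p
    nonref = np.asarray([f for f in range(p) if f != r])
    phi = alr_inv_mat(mu_fa, ref=ref)  # (n, p)
    w = pi_vec * fat
    kphi = kappa * phi
    v = (w[:, None] * kphi).sum(axis=0)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        return None, None
    m = np.log(v[nonref]) - np.log(v[r])
    E = np.zeros((p, k))
    E[nonref, np.arange(k)] = 1.0
    # B[s,f,m] = w_s kappa_sf phi_sf dphi/dy; A[s] maps species-s alr
    # perturbations to alr-signature perturbations
    B = (
        w[:, None, None]
        * kphi[:, :, None]
        * (E[None, :, :] - phi[:, nonref][:, None, :])
    )
    A = B[:, nonref, :] / v[nonref][None, :, None] - B[:, r, :][:, None, :] / v[r]
    AS = np.matmul(A, Sigma_fa)  # (n, k, k) batched
    Omega = np.tensordot(AS, A, axes=([0, 2], [0, 2]))
    return m, Omega


def si_expected(pi, prey_si_values, gamma) -> np.ndarray:
    """Expected predator SI signature: ``sum_s pi_s (x_s + gamma_s)``."""
    pi = np.asarray(pi, dtype=float)
    x = np.asarray(prey_si_values, dtype=float)
    g = np.asarray(gamma, dtype=float)
    if x.shape != g.shape or x.shape[0] != pi.shape[0]:
        raise ValueError("species x isotope dimensions disagree")
    return pi @ (x + g)


def _pi_matrix(state: DietState, n_pred: int) -> np.ndarray:
    if state.pi_ind is not None:
        return np.asarray(state.pi_ind, dtype=float)
    return np.tile(np.asarray(state.pi, dtype=float), (n_pred, 1))


def fa_loglik(d: DietDataset, state: DietState, spec: ModelSpec) -> float:
    """FA-profile log-likelihood: prey-sample terms, latent consumed-prey
    terms (latent mode), and predator observation terms."""
    if d.prey.fa is None or d.predators.fa is None:
        raise ModelConfigError("dataset has no FA tables")
    ref = spec.alr_ref
    prey_rows = alr_mat(d.prey.fa, ref=ref)
    total = 0.0
    for si_, s in enumerate(d.species):
        r = prey_rows[d.prey.fa_species == s]
        total += mvn_logpdf_sum(r, state.mu_fa[si_], state.Sigma_fa[si_])
        if not np.isfinite(total):
            return -np.inf
    J = d.predators.fa.shape[0]
    if spec.prey_mode == "latent" and state.phi is not None:
        phi = np.asarray(state.phi, dtype=float)
        phi_alr = alr_mat(phi, ref=ref)  # (J, n, p-1)
        for si_ in range(len(d.species)):
            total += mvn_logpdf_sum(
                phi_alr[:, si_, :], state.mu_fa[si_], state.Sigma_fa[si_]
            )
            if not np.isfinite(total):
                return -np.inf
    else:
        phi = alr_inv_mat(state.mu_fa, ref=ref)  # mean-prey mode
    pi_mat = _pi_matrix(state, J)
    tau = _tau_matrix(pi_mat, state.kappa, phi, state.fat)
    if tau is None:
        return -np.inf
    t_obs = alr_mat(d.predators.fa, ref=ref)
    total += mvn_logpdf_sum(t_obs - alr_mat(tau, ref=ref), 0.0, state.Sigma_tau)
    return float(total)


def si_loglik(d: DietDataset, state: DietState, spec: ModelSpec) -> float:
    """SI log-likelihood: prey-sample terms, latent consumed-SI terms
    (latent mode), predator observation terms, and the fractionation
    coefficients' normal terms around their feeding-trial priors."""
    if d.prey.si is None or d.predators.si is None:
        raise ModelConfigError("dataset has no SI tables")
    if d.priors.frac_mean is None:
        raise ModelConfigError("SI model requires fractionation priors")
    n = len(d.species)
    total = 0.0
    for si_, s in enumerate(d.species):
        r = d.prey.si[d.prey.si_species == s]
        total += mvn_logpdf_sum(r, state.mu_si[si_], state.Sigma_si[si_])
        if not np.isfinite(total):
            return -np.inf
    J = d.predators.si.shape[0]
    if spec.prey_mode == "latent" and state.x_si is not None:
        x = np.asarray(state.x_si, dtype=float)  # (J, n, n_iso)
        for si_ in range(n):
            total += mvn_logpdf_sum(
                x[:, si_, :], state.mu_si[si_], state.Sigma_si[si_]
            )
            if not np.isfinite(total):
                return -np.inf
    else:
        x = np.broadcast_to(state.mu_si, (J,) + state.mu_si.shape)
    pi_mat = _pi_matrix(state, J)
    mean = np.einsum("jn,jni->ji", pi_mat, x + state.gamma[None, :, :])
    total += mvn_logpdf_sum(d.predators.si - mean, 0.0, state.Sigma_tau_si)
    # fractionation around its prior moments: travels with the SI model
    sd = np.asarray(d.priors.frac_sd, dtype=float)
    free = sd > 0
    if free.any():
        z = (state.gamma[free] - d.priors.frac_mean[free]) / sd[free]
        total += float(-0.5 * (z * z + LOG2PI).sum() - np.log(sd[free]).sum())
    return float(total)


def log_prior(state: DietState, spec: ModelSpec, d: DietDataset) -> float:
    """Joint log-prior over the sampled blocks (excluding gamma, whose
    normal term lives in :func:`si_loglik`)."""
    total = 0.0
    n = len(d.species)
    if spec.grouping == "population":
        if state.pi is None:
            raise InvalidStateError("population grouping needs state.pi")
        pi = np.asarray(state.pi, dtype=float)
        if np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-6:
            return -np.inf
        total += stats.dirichlet.logpdf(pi / pi.sum(), np.full(n, spec.alpha))
    elif "pi_ind" not in spec.fix:
        if state.pi_ind is None:
            raise InvalidStateError(f"{spec.grouping} grouping needs state.pi_ind")
        U = ilr_mat(state.pi_ind)
        if spec.grouping == "individual":
            mean = state.Pi[None, :]
        else:
            mean = spec.design @ state.B
        total += mvn_logpdf_sum(U - mean, 0.0, state.Sigma_Pi)
        if not np.isfinite(total):
            return -np.inf
        for row in state.pi_ind:
            total -= ilr_log_jacobian(row)  # density stated over proportions
        if spec.grouping == "individual":
            total += float(
                -0.5 * ((state.Pi / spec.mu_prior_sd) ** 2 + LOG2PI).sum()
                - state.Pi.size * np.log(spec.mu_prior_sd)
            )
        else:
            b = state.B.ravel()
            total += float(
                -0.5 * ((b / spec.mu_prior_sd) ** 2 + LOG2PI).sum()
                - b.size * np.log(spec.mu_prior_sd)
            )
        k = n - 1
        total += _iw_logpdf(state.Sigma_Pi, k + 2, spec.sigma_diet_scale * np.eye(k))
    if state.kappa is not None:
        km, kv = d.priors.kappa_mean, d.priors.kappa_var
        free = kv > 0
        if free.any():
            val = state.kappa[free]
            if np.any(val <= 0):
                return -np.inf
            shape = km[free] ** 2 / kv[free]
            rate = km[free] / kv[free]
            total += float(stats.gamma.logpdf(val, a=shape, scale=1.0 / rate).sum())
    if state.fat is not None:
        fm, fv = d.priors.fat_mean, d.priors.fat_var
        for s_idx in np.flatnonzero(fv > 0):
            x = state.fat[s_idx]
            if x <= 0:
                return -np.inf
            mu, sd = moment_matched_lognormal(fm[s_idx], fv[s_idx])
            total += float(stats.lognorm.logpdf(x, s=sd, scale=np.exp(mu)))
    if state.mu_fa is not None:
        total += float(
            -0.5 * ((state.mu_fa / spec.mu_prior_sd) ** 2 + LOG2PI).sum()
            - state.mu_fa.size * np.log(spec.mu_prior_sd)
        )
        k = state.Sigma_fa.shape[-1]
        S0 = spec.sigma_prey_scale * np.eye(k)
        for cov in state.Sigma_fa:
            total += _iw_logpdf(cov, k + 2, S0)
            if not np.isfinite(total):
                return -np.inf
    if state.Sigma_tau is not None:
        k = np.atleast_2d(state.Sigma_tau).shape[0]
        total += _iw_logpdf(state.Sigma_tau, k + 2, spec.sigma_resid_scale * np.eye(k))
    if state.mu_si is not None:
        total += float(
            -0.5 * ((state.mu_si / spec.mu_si_prior_sd) ** 2 + LOG2PI).sum()
            - state.mu_si.size * np.log(spec.mu_si_prior_sd)
        )
        k = state.Sigma_si.shape[-1]
        S0 = spec.sigma_prey_scale * np.eye(k)
        for cov in state.Sigma_si:
            total += _iw_logpdf(cov, k + 2, S0)
            if not np.isfinite(total):
                return -np.inf
    if state.Sigma_tau_si is not None:
        k = np.atleast_2d(state.Sigma_tau_si).shape[0]
        total += _iw_logpdf(
            state.Sigma_tau_si, k + 2, spec.sigma_resid_scale * np.eye(k)
        )
    return float(total)


# ---------------------------------------------------------------------------
# LogPosterior: blocks, sub-block updates, factors
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SubBlock:
    """One random-walk update unit inside a block.

    ``get_u`` extracts the unconstrained coordinates from the block value;
    ``set_u`` returns a new block value with those coordinates replaced;
    ``log_jac`` is the log-Jacobian of the unconstrained->constrained map,
    evaluated at a block value.
    """

    key: str
    size: int
    get_u: Callable[[np.ndarray], np.ndarray]
    set_u: Callable[[np.ndarray, np.ndarray], np.ndarray]
    log_jac: Callable[[np.ndarray], float]
    factor_names: tuple[str, ...]
    # optional state-dependent proposal preconditioner: state -> lower
    # Cholesky factor of the proposal covariance (replaces the adapted
    # per-coordinate scaling)
    precond: Callable | None = None


@dataclasses.dataclass
class CustomOp:
    """A self-contained update step with its own adapted proposal scale.

    ``update(state, cache, rng, scale)`` mutates the state in place,
    keeps the factor cache consistent, and returns its mean acceptance
    probability (used by the sampler's warmup scale adaptation). Used for
    the sequential per-predator latent-prey updates, whose acceptance
    deltas are computed incrementally and do not fit the factor-subset
    pattern of plain random-walk sub-blocks.
    """

    key: str
    update: Callable
    target: float = 0.25
    init_log_scale: float = 0.0


@dataclasses.dataclass
class Block:
    """One parameter block of a LogPosterior.

    ``kind`` is "rwm" (adaptive random-walk Metropolis over sub-blocks in
    unconstrained space, plus optional independence-MH updates), "custom"
    (self-managed updates, see :class:`CustomOp`), "gibbs"
    (full-conditional draw), or "fixed".
    """

    name: str
    kind: str
    shape: tuple
    init: np.ndarray
    factor_names: tuple[str, ...] = ()
    subblocks: list[SubBlock] = dataclasses.field(default_factory=list)
    gibbs_fn: Callable | None = None
    # independence-MH updates: (key, proposal_fn(state, rng) -> block value,
    # correction factor names, factor names to refresh on acceptance); the
    # proposal must be the full conditional of the non-correction factors,
    # so the MH ratio reduces to the correction factors alone
    mh_updates: list = dataclasses.field(default_factory=list)
    custom_ops: list = dataclasses.field(default_factory=list)
    store: bool = True
    report_fn: Callable | None = None  # state -> values (flat)
    flat_names: list[str] | None = None
    check_fn: Callable | None = None  # value -> bool, for the flat contract

    @property
    def flat_size(self) -> int:
        return int(np.prod(self.shape))

    @property
    def u_size(self) -> int:
        if self.subblocks:
            return sum(sb.size for sb in self.subblocks)
        return self.flat_size


def _sb_simplex(key: str, row: int | None, factors: tuple[str, ...], n: int) -> SubBlock:
    V = ilr_basis(n)

    def get_u(v):
        x = v if row is None else v[row]
        return ilr_mat(x[None, :], V)[0]

    def set_u(v, u):
        x = ilr_inv_mat(u[None, :], V)[0]
        if row is None:
            return x
        out = v.copy()
        out[row] = x
        return out

    def log_jac(v):
        x = v if row is None else v[row]
        return ilr_log_jacobian(x)

    return SubBlock(key, n - 1, get_u, set_u, log_jac, factors)


def _sb_identity(key: str, idx, factors: tuple[str, ...], size: int) -> SubBlock:
    """idx: tuple index or boolean mask selecting the updated entries."""

    def get_u(v):
        return np.asarray(v[idx], dtype=float).ravel().copy()

    def set_u(v, u):
        out = v.copy()
        out[idx] = u.reshape(np.shape(v[idx]))
        return out

    def log_jac(v):
        return 0.0

    return SubBlock(key, size, get_u, set_u, log_jac, factors)


def _sb_log(key: str, idx, factors: tuple[str, ...], size: int) -> SubBlock:
    def get_u(v):
        return np.log(np.asarray(v[idx], dtype=float).ravel())

    def set_u(v, u):
        out = v.copy()
        out[idx] = np.exp(u).reshape(np.shape(v[idx]))
        return out

    def log_jac(v):
        return float(np.log(v[idx]).sum())

    return SubBlock(key, size, get_u, set_u, log_jac, factors)


class LogPosterior:
    """A model compiled to parameter blocks and factorized log-density.

    ``value(theta)`` evaluates the joint log-density at a flat
    constrained-space parameter vector (concatenated block values, with
    2-D covariance blocks passed as lower-triangular entries), returning
    -inf exactly on constraint violations.
    """

    def __init__(
        self,
        blocks: Sequence[Block],
        factors: Mapping[str, Callable],
        meta: dict | None = None,
    ):
        self.blocks = list(blocks)
        self.factors = dict(factors)
        self.meta = meta or {}
        self._cov_blocks = {
            b.name
            for b in self.blocks
            if b.kind != "fixed"
            and len(b.shape) == 2
            and b.shape[0] == b.shape[1]
            and b.name.startswith("Sigma")
        }

    @property
    def sampled_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.kind != "fixed"]

    @property
    def dim(self) -> int:
        """Total unconstrained dimension of the sampled blocks."""
        total = 0
        for b in self.sampled_blocks:
            if b.name in self._cov_blocks:
                k = b.shape[0]
                total += k * (k + 1) // 2
            else:
                total += b.u_size
        return total

    def parameter_names(self) -> dict[str, list[str]]:
        out = {}
        for b in self.sampled_blocks:
            if b.flat_names is not None:
                out[b.name] = list(b.flat_names)
            elif b.name in self._cov_blocks:
                k = b.shape[0]
                out[b.name] = [
                    f"{b.name}[{i},{j}]" for i in range(k) for j in range(i + 1)
                ]
            else:
                out[b.name] = [f"{b.name}[{i}]" for i in range(b.flat_size)]
        return out

    def init_state(self) -> dict:
        return {b.name: np.array(b.init, dtype=float, copy=True) for b in self.blocks}

    def block_factors(self, names: tuple[str, ...]) -> list[str]:
        """Subset of declared factor names that exist in this model."""
        return [f for f in names if f in self.factors]

    # -- flat-vector contract ---------------------------------------------
    def _flat_sizes(self) -> list[tuple[Block, int]]:
        out = []
        for b in self.sampled_blocks:
            if b.name in self._cov_blocks:
                k = b.shape[0]
                out.append((b, k * (k + 1) // 2))
            else:
                out.append((b, b.flat_size))
        return out

    @property
    def flat_dim(self) -> int:
        return sum(s for _, s in self._flat_sizes())

    def pack(self, state: Mapping[str, np.ndarray]) -> np.ndarray:
        parts = []
        for b, _ in self._flat_sizes():
            v = np.asarray(state[b.name], dtype=float)
            if b.name in self._cov_blocks:
                k = b.shape[0]
                parts.append(v[np.tril_indices(k)])
            else:
                parts.append(v.ravel())
        return np.concatenate(parts) if parts else np.empty(0)

    def unpack(self, theta: np.ndarray) -> dict:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.flat_dim,):
            raise ValueError(f"theta must have shape ({self.flat_dim},)")
        state = self.init_state()
        pos = 0
        for b, size in self._flat_sizes():
            chunk = theta[pos : pos + size]
            pos += size
            if b.name in self._cov_blocks:
                k = b.shape[0]
                m = np.zeros((k, k))
                m[np.tril_indices(k)] = chunk
                state[b.name] = m + np.tril(m, -1).T
            else:
                state[b.name] = chunk.reshape(b.shape)
        return state

    def value(self, theta: np.ndarray) -> float:
        """Joint log-density at a flat constrained parameter vector."""
        state = self.unpack(theta)
        for b in self.sampled_blocks:
            v = state[b.name]
            if not np.all(np.isfinite(v)):
                return -np.inf
            if b.check_fn is not None and not b.check_fn(v):
                return -np.inf
        return self.value_at_state(state)

    def value_at_state(self, state: Mapping[str, np.ndarray]) -> float:
        total = 0.0
        for fn in self.factors.values():
            total += fn(state)
            if not np.isfinite(total):
                return -np.inf
        return float(total)


def _check_simplex_rows(v: np.ndarray) -> bool:
    v = np.atleast_2d(v)
    return bool(np.all(v > 0) and np.allclose(v.sum(axis=-1), 1.0, atol=1e-6))


def _check_positive(v: np.ndarray) -> bool:
    return bool(np.all(v > 0))


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


def build_model(d: DietDataset, spec: ModelSpec) -> LogPosterior:
    """Compile a dataset + model spec into a LogPosterior.

    Joint (FA + SI) models share the diet-proportion block across markers;
    the FA and SI predator tables may describe different individuals, as
    long as prey samples and predator diets come from the same populations.
    """
    use_fa = spec.markers in ("fa", "both")
    use_si = spec.markers in ("si", "both")
    if use_fa and (d.prey.fa is None or d.predators.fa is None):
        raise ModelConfigError("FA model requested but FA tables are missing")
    if use_si and (d.prey.si is None or d.predators.si is None):
        raise ModelConfigError("SI model requested but SI tables are missing")
    if use_si and d.priors.frac_mean is None:
        raise ModelConfigError(
            "SI model requested without fractionation priors; supply a "
            "fractionation table (there is no safe default)"
        )

    n = len(d.species)
    species = list(d.species)
    ref = spec.alr_ref
    fix = dict(spec.fix)
    moments = PreyDistribution.from_library(d.prey, alr_ref=ref)

    J_fa = d.predators.fa.shape[0] if use_fa else 0
    J_si = d.predators.si.shape[0] if use_si else 0

    # unified predator index for individual/linear groupings
    pred_ids: list[str] = []
    fa_map = si_map = None
    if spec.grouping != "population":
        if use_fa:
            for i in d.predators.fa_ids:
                if i not in pred_ids:
                    pred_ids.append(i)
        if use_si:
            for i in d.predators.si_ids:
                if i not in pred_ids:
                    pred_ids.append(i)
        if use_fa:
            fa_map = np.array([pred_ids.index(i) for i in d.predators.fa_ids])
        if use_si:
            si_map = np.array([pred_ids.index(i) for i in d.predators.si_ids])
    Ju = len(pred_ids)

    design = None
    if spec.grouping == "linear" and spec.design is not None:
        design = np.asarray(spec.design, dtype=float)
        if design.shape[0] != Ju:
            raise ModelConfigError(
                f"design matrix has {design.shape[0]} rows for {Ju} predators"
            )

    blocks: list[Block] = []
    factors: dict[str, Callable] = {}

    def fixed_or(name, default_init):
        if name in fix:
            return np.asarray(fix[name], dtype=float), True
        return np.asarray(default_init, dtype=float), False

    pred_factors = tuple(
        x for x in ("pred_fa", "pred_si")
        if (x == "pred_fa" and use_fa) or (x == "pred_si" and use_si)
    )

    # ---- diet proportions -------------------------------------------------
    if spec.grouping == "population":
        init_pi, pi_fixed = fixed_or("pi", np.full(n, 1.0 / n))
        b = Block(
            name="pi",
            kind="fixed" if pi_fixed else "rwm",
            shape=(n,),
            init=init_pi,
            factor_names=pred_factors + ("prior_pi",),
            flat_names=[f"pi[{s}]" for s in species],
            check_fn=_check_simplex_rows,
        )
        if not pi_fixed:
            b.subblocks = [_sb_simplex("pi", None, b.factor_names, n)]
            alpha = np.full(n, spec.alpha)

            def prior_pi(state, alpha=alpha):
                pi = state["pi"]
                if np.any(pi <= 0):
                    return -np.inf
                return float(stats.dirichlet.logpdf(pi / pi.sum(), alpha))

            factors["prior_pi"] = prior_pi
        blocks.append(b)
    else:
        init_pi_ind, pi_ind_fixed = fixed_or("pi_ind", np.full((Ju, n), 1.0 / n))
        b = Block(
            name="pi_ind",
            kind="fixed" if pi_ind_fixed else "rwm",
            shape=(Ju, n),
            init=init_pi_ind,
            factor_names=pred_factors + ("prior_pi",),
            flat_names=[f"pi[{pid}|{s}]" for pid in pred_ids for s in species],
            check_fn=_check_simplex_rows,
        )
        if not pi_ind_fixed:
            b.subblocks = [
                _sb_simplex(f"pi_ind[{j}]", j, b.factor_names, n) for j in range(Ju)
            ]
        blocks.append(b)
        if not pi_ind_fixed:
            V = ilr_basis(n)
            if spec.grouping == "individual":
                blocks.append(
                    Block(
                        name="Pi",
                        kind="gibbs",
                        shape=(n - 1,),
                        init=np.zeros(n - 1),
                        gibbs_fn=lambda state, rng: _mvn_conjugate_mean(
                            ilr_mat(state["pi_ind"], V),
                            state["Sigma_Pi"],
                            spec.mu_prior_sd,
                            rng,
                        ),
                        factor_names=("prior_pi",),
                        report_fn=lambda state: ilr_inv_mat(state["Pi"][None, :], V)[0],
                        flat_names=[f"Pi[{s}]" for s in species],
                    )
                )
            else:
                q = design.shape[1]
                bB = Block(
                    name="B",
                    kind="rwm",
                    shape=(q, n - 1),
                    init=np.zeros((q, n - 1)),
                    factor_names=("prior_pi",),
                    flat_names=[f"B[{i},{j}]" for i in range(q) for j in range(n - 1)],
                )
                bB.subblocks = [
                    _sb_identity("B", (slice(None), slice(None)), bB.factor_names, q * (n - 1))
                ]
                blocks.append(bB)

            def gibbs_sigma_pi(state, rng):
                U = ilr_mat(state["pi_ind"], V)
                mean = (
                    state["Pi"][None, :]
                    if spec.grouping == "individual"
                    else design @ state["B"]
                )
                return _iw_gibbs(
                    U - mean, n + 1, spec.sigma_diet_scale * np.eye(n - 1), rng
                )

            blocks.append(
                Block(
                    name="Sigma_Pi",
                    kind="gibbs",
                    shape=(n - 1, n - 1),
                    init=0.5 * np.eye(n - 1),
                    gibbs_fn=gibbs_sigma_pi,
                    factor_names=("prior_pi",),
                    store=False,
                )
            )

            def prior_pi(state):
                U = ilr_mat(state["pi_ind"], V)
                mean = (
                    state["Pi"][None, :]
                    if spec.grouping == "individual"
                    else design @ state["B"]
                )
                total = mvn_logpdf_sum(U - mean, 0.0, state["Sigma_Pi"])
                if not np.isfinite(total):
                    return -np.inf
                for row in state["pi_ind"]:
                    total -= ilr_log_jacobian(row)
                if spec.grouping == "individual":
                    total += float(
                        -0.5 * ((state["Pi"] / spec.mu_prior_sd) ** 2 + LOG2PI).sum()
                        - state["Pi"].size * np.log(spec.mu_prior_sd)
                    )
                else:
                    bb = state["B"].ravel()
                    total += float(
                        -0.5 * ((bb / spec.mu_prior_sd) ** 2 + LOG2PI).sum()
                        - bb.size * np.log(spec.mu_prior_sd)
                    )
                total += _iw_logpdf(
                    state["Sigma_Pi"], (n - 1) + 2, spec.sigma_diet_scale * np.eye(n - 1)
                )
                return total

            factors["prior_pi"] = prior_pi

    # ---- conversion coefficients and fat content ---------------------------
    if use_fa:
        p = len(d.fa_names)
        km, kv = d.priors.kappa_mean, d.priors.kappa_var
        kappa_init, kappa_fixed = fixed_or("kappa", km)
        kappa_free = np.zeros_like(kv, dtype=bool) if kappa_fixed else (kv > 0)
        b = Block(
            name="kappa",
            kind="rwm" if kappa_free.any() else "fixed",
            shape=(n, p),
            init=kappa_init,
            factor_names=("pred_fa", "prior_kappa"),
            store=bool(kappa_free.any()),
            report_fn=lambda state: (
                state["kappa"] / state["kappa"].sum(axis=1, keepdims=True)
            ).ravel(),
            flat_names=[f"kappa[{s}|{f}]" for s in species for f in d.fa_names],
            check_fn=_check_positive,
        )
        if kappa_free.any():
            for s_idx in range(n):
                mask = np.zeros((n, p), dtype=bool)
                mask[s_idx] = kappa_free[s_idx]
                if mask.any():
                    b.subblocks.append(
                        _sb_log(
                            f"kappa[{s_idx}]", mask, b.factor_names, int(mask.sum())
                        )
                    )

            def prior_kappa(state, km=km, kv=kv, free=kappa_free):
                val = state["kappa"][free]
                if np.any(val <= 0):
                    return -np.inf
                shape = km[free] ** 2 / kv[free]
                rate = km[free] / kv[free]
                return float(stats.gamma.logpdf(val, a=shape, scale=1.0 / rate).sum())

            factors["prior_kappa"] = prior_kappa
        blocks.append(b)

        fm, fv = d.priors.fat_mean, d.priors.fat_var
        fat_init, fat_fixed = fixed_or("fat", fm)
        fat_free = np.zeros_like(fv, dtype=bool) if fat_fixed else (fv > 0)
        b = Block(
            name="fat",
            kind="rwm" if fat_free.any() else "fixed",
            shape=(n,),
            init=fat_init,
            factor_names=("pred_fa", "prior_fat"),
            store=bool(fat_free.any()),
            flat_names=[f"fat[{s}]" for s in species],
            check_fn=_check_positive,
        )
        if fat_free.any():
            b.subblocks = [_sb_log("fat", fat_free, b.factor_names, int(fat_free.sum()))]

            def prior_fat(state, fm=fm, fv=fv, free=fat_free):
                total = 0.0
                for s_idx in np.flatnonzero(free):
                    x = state["fat"][s_idx]
                    if x <= 0:
                        return -np.inf
                    mu, sd = moment_matched_lognormal(fm[s_idx], fv[s_idx])
                    lx = np.log(x)
                    total += (
                        -lx - np.log(sd) - 0.5 * LOG2PI - 0.5 * ((lx - mu) / sd) ** 2
                    )
                return float(total)

            factors["prior_fat"] = prior_fat
        blocks.append(b)

    # ---- FA marker ---------------------------------------------------------
    if use_fa:
        p = len(d.fa_names)
        prey_alr = alr_mat(d.prey.fa, ref=ref)
        prey_rows_by_s = [prey_alr[d.prey.fa_species == s] for s in species]
        t_obs = alr_mat(d.predators.fa, ref=ref)
        k_fa = p - 1
        S0_prey = spec.sigma_prey_scale * np.eye(k_fa)
        S0_tau = spec.sigma_resid_scale * np.eye(k_fa)
        df0 = k_fa + 2
        mode = spec.prey_mode
        latent = mode == "latent"

        mu_fa_init, mu_fa_fixed = fixed_or("mu_fa", moments.mu_fa)
        Sigma_fa_init, Sigma_fa_fixed = fixed_or("Sigma_fa", moments.Sigma_fa)

        for s_idx, s in enumerate(species):
            factors[f"prey_fa::{s}"] = (
                lambda state, s_idx=s_idx: mvn_logpdf_sum(
                    prey_rows_by_s[s_idx],
                    state["mu_fa"][s_idx],
                    state["Sigma_fa"][s_idx],
                )
            )
            if not mu_fa_fixed:
                factors[f"prior_mu_fa::{s}"] = lambda state, s_idx=s_idx: float(
                    -0.5 * ((state["mu_fa"][s_idx] / spec.mu_prior_sd) ** 2 + LOG2PI).sum()
                    - k_fa * np.log(spec.mu_prior_sd)
                )
            if not Sigma_fa_fixed:
                factors[f"prior_Sigma_fa::{s}"] = lambda state, s_idx=s_idx: _iw_logpdf(
                    state["Sigma_fa"][s_idx], df0, S0_prey
                )
            if latent:
                factors[f"lat_fa::{s}"] = lambda state, s_idx=s_idx: mvn_logpdf_sum(
                    state["phi_alr"][:, s_idx, :],
                    state["mu_fa"][s_idx],
                    state["Sigma_fa"][s_idx],
                )

        if mu_fa_fixed:
            blocks.append(
                Block(name="mu_fa", kind="fixed", shape=(n, k_fa), init=mu_fa_init)
            )
        elif latent:

            def gibbs_mu_fa(state, rng):
                out = np.empty((n, k_fa))
                for s_idx in range(n):
                    rows = np.vstack(
                        [prey_rows_by_s[s_idx], state["phi_alr"][:, s_idx, :]]
                    )
                    out[s_idx] = _mvn_conjugate_mean(
                        rows, state["Sigma_fa"][s_idx], spec.mu_prior_sd, rng
                    )
                return out

            blocks.append(
                Block(
                    name="mu_fa",
                    kind="gibbs",
                    shape=(n, k_fa),
                    init=mu_fa_init,
                    gibbs_fn=gibbs_mu_fa,
                    factor_names=tuple(
                        [f"prey_fa::{s}" for s in species]
                        + [f"lat_fa::{s}" for s in species]
                        + [f"prior_mu_fa::{s}" for s in species]
                    ),
                    store=False,
                )
            )
        else:
            # mean-prey mode: the prey-sample conditional of mu_s is exactly
            # conjugate; propose from it and Metropolis-correct with the
            # predator factor (which depends on mu through the consumed
            # species-mean profiles)
            def make_mu_fa_prop(s_idx):
                def prop(state, rng):
                    out = state["mu_fa"].copy()
                    out[s_idx] = _mvn_conjugate_mean(
                        prey_rows_by_s[s_idx],
                        state["Sigma_fa"][s_idx],
                        spec.mu_prior_sd,
                        rng,
                    )
                    return out

                return prop

            b = Block(
                name="mu_fa",
                kind="mh",
                shape=(n, k_fa),
                init=mu_fa_init,
                factor_names=tuple(
                    [f"prey_fa::{s}" for s in species]
                    + [f"prior_mu_fa::{s}" for s in species]
                    + ["pred_fa"]
                ),
                store=False,
            )
            b.mh_updates = [
                (
                    f"mu_fa[{s_idx}]",
                    make_mu_fa_prop(s_idx),
                    ("pred_fa",),
                    (f"prey_fa::{species[s_idx]}", f"prior_mu_fa::{species[s_idx]}"),
                )
                for s_idx in range(n)
            ]

            # local moves preconditioned by the prey-data conditional
            # covariance, mixed with the independence jumps above
            def make_mu_fa_precond(s_idx):
                def pre(state):
                    _, L = _conjugate_mean_cov(
                        prey_rows_by_s[s_idx],
                        state["Sigma_fa"][s_idx],
                        spec.mu_prior_sd,
                    )
                    return L

                return pre

            for s_idx in range(n):
                sb = _sb_identity(
                    f"mu_fa[{s_idx}]",
                    (s_idx, slice(None)),
                    (
                        f"prey_fa::{species[s_idx]}",
                        f"prior_mu_fa::{species[s_idx]}",
                        "pred_fa",
                    ),
                    k_fa,
                )
                sb.precond = make_mu_fa_precond(s_idx)
                b.subblocks.append(sb)
            blocks.append(b)

        if Sigma_fa_fixed:
            blocks.append(
                Block(
                    name="Sigma_fa", kind="fixed", shape=(n, k_fa, k_fa), init=Sigma_fa_init
                )
            )
        elif mode == "linearized":
            # the propagated predator covariance depends on Sigma_s, so the
            # prey-conditional inverse-Wishart draw is an independence-MH
            # proposal corrected by the predator factor
            def make_sigma_fa_prop(s_idx):
                def prop(state, rng):
                    out = state["Sigma_fa"].copy()
                    rows = prey_rows_by_s[s_idx] - state["mu_fa"][s_idx]
                    out[s_idx] = _iw_gibbs(rows, df0, S0_prey, rng)
                    return out

                return prop

            b = Block(
                name="Sigma_fa",
                kind="mh",
                shape=(n, k_fa, k_fa),
                init=Sigma_fa_init,
                factor_names=tuple(
                    [f"prey_fa::{s}" for s in species]
                    + [f"prior_Sigma_fa::{s}" for s in species]
                    + ["pred_fa"]
                ),
                store=False,
            )
            b.mh_updates = [
                (
                    f"Sigma_fa[{s_idx}]",
                    make_sigma_fa_prop(s_idx),
                    ("pred_fa",),
                    (
                        f"prey_fa::{species[s_idx]}",
                        f"prior_Sigma_fa::{species[s_idx]}",
                    ),
                )
                for s_idx in range(n)
            ]
            blocks.append(b)
        else:

            def gibbs_sigma_fa(state, rng):
                out = np.empty((n, k_fa, k_fa))
                for s_idx in range(n):
                    rows = prey_rows_by_s[s_idx] - state["mu_fa"][s_idx]
                    if latent:
                        rows = np.vstack(
                            [
                                rows,
                                state["phi_alr"][:, s_idx, :] - state["mu_fa"][s_idx],
                            ]
                        )
                    out[s_idx] = _iw_gibbs(rows, df0, S0_prey, rng)
                return out

            blocks.append(
                Block(
                    name="Sigma_fa",
                    kind="gibbs",
                    shape=(n, k_fa, k_fa),
                    init=Sigma_fa_init,
                    gibbs_fn=gibbs_sigma_fa,
                    factor_names=tuple(
                        [f"prey_fa::{s}" for s in species]
                        + ([f"lat_fa::{s}" for s in species] if latent else [])
                        + [f"prior_Sigma_fa::{s}" for s in species]
                    ),
                    store=False,
                )
            )

        if latent:
            # sequential per-predator updates: proposals preconditioned by
            # chol(Sigma_s); acceptance deltas use rank-1 updates of the
            # residual Gram matrix under the marginalized (matrix-t)
            # predator factor, or plain Gaussian terms if Sigma_tau fixed
            def make_phi_op(s_idx):
                def update(state, cache, rng, scale):
                    phi = state["phi_alr"]
                    J = phi.shape[0]
                    mu = state["mu_fa"][s_idx]
                    Sig = state["Sigma_fa"][s_idx]
                    try:
                        Ls = np.linalg.cholesky(Sig)
                    except np.linalg.LinAlgError:
                        return 0.0
                    if spec.grouping == "population":
                        pi_mat = np.tile(state["pi"], (J, 1))
                    elif fa_map is not None:
                        pi_mat = state["pi_ind"][fa_map]
                    else:
                        pi_mat = state["pi_ind"]
                    w = pi_mat * state["fat"]
                    kap = state["kappa"]
                    phi_comp = alr_inv_mat(phi, ref=ref)
                    contrib = w[:, :, None] * (kap[None] * phi_comp)
                    pre = contrib.sum(axis=1)
                    base = pre - contrib[:, s_idx, :]
                    tau = pre / pre.sum(1, keepdims=True)
                    R = t_obs - alr_mat(tau, ref=ref)
                    gauss = "Sigma_tau" in state
                    if gauss:
                        Lt = np.linalg.cholesky(np.atleast_2d(state["Sigma_tau"]))
                    else:
                        G = S0_tau + R.T @ R
                        _, ldG = np.linalg.slogdet(G)
                        const = df0 + J

                    def lat_q(row):
                        y = np.linalg.solve(Ls, row - mu)
                        return -0.5 * float(y @ y)

                    def pred_q(r):
                        y = np.linalg.solve(Lt, r)
                        return -0.5 * float(y @ y)

                    phi_s = phi[:, s_idx, :]
                    asum = 0.0
                    for j in range(J):
                        new_row = phi_s[j] + scale * (
                            Ls @ rng.standard_normal(k_fa)
                        )
                        new_comp = alr_inv_mat(new_row[None, :], ref=ref)[0]
                        pre_new = base[j] + w[j, s_idx] * (kap[s_idx] * new_comp)
                        ssum = pre_new.sum()
                        if ssum <= 0 or not np.isfinite(ssum):
                            continue
                        r_new = t_obs[j] - alr_mat(
                            (pre_new / ssum)[None, :], ref=ref
                        )[0]
                        delta = lat_q(new_row) - lat_q(phi_s[j])
                        if gauss:
                            delta += pred_q(r_new) - pred_q(R[j])
                        else:
                            G_new = (
                                G - np.outer(R[j], R[j]) + np.outer(r_new, r_new)
                            )
                            sgn, ld_new = np.linalg.slogdet(G_new)
                            if sgn <= 0:
                                continue
                            delta += -0.5 * const * (ld_new - ldG)
                        if not np.isfinite(delta):
                            continue
                        asum += np.exp(min(delta, 0.0))
                        if np.log(rng.random()) < delta:
                            phi_s[j] = new_row
                            R[j] = r_new
                            if not gauss:
                                G, ldG = G_new, ld_new
                    cache[f"lat_fa::{species[s_idx]}"] = mvn_logpdf_sum(
                        phi_s, mu, Sig
                    )
                    cache["pred_fa"] = factors["pred_fa"](state)
                    return asum / max(J, 1)

                return update

            b = Block(
                name="phi_alr",
                kind="custom",
                shape=(J_fa, n, k_fa),
                init=np.tile(mu_fa_init[None, :, :], (J_fa, 1, 1)),
                factor_names=tuple([f"lat_fa::{s}" for s in species] + ["pred_fa"]),
                store=False,
            )
            b.custom_ops = [
                CustomOp(f"phi[{s_idx}]", make_phi_op(s_idx), init_log_scale=np.log(0.5))
                for s_idx in range(n)
            ]
            blocks.append(b)

        Sigma_tau_init, Sigma_tau_fixed = fixed_or("Sigma_tau", 0.1 * np.eye(k_fa))

        def fa_resid(state):
            if spec.grouping == "population":
                pi_mat = np.tile(state["pi"], (J_fa, 1))
            elif fa_map is not None:
                pi_mat = state["pi_ind"][fa_map]
            else:
                pi_mat = state["pi_ind"]
            phi = (
                alr_inv_mat(state["phi_alr"], ref=ref)
                if latent
                else alr_inv_mat(state["mu_fa"], ref=ref)
            )
            tau = _tau_matrix(pi_mat, state["kappa"], phi, state["fat"])
            if tau is None:
                return None
            return t_obs - alr_mat(tau, ref=ref)

        if mode == "linearized":

            def pred_fa(state):
                floor = (
                    np.atleast_2d(state["Sigma_tau"])
                    if "Sigma_tau" in state
                    else state["resid_scale"][0] * np.eye(k_fa)
                )
                if spec.grouping == "population":
                    m, Om = _linearized_fa_meanvar(
                        state["mu_fa"],
                        state["Sigma_fa"],
                        state["kappa"],
                        state["fat"],
                        state["pi"],
                        ref,
                    )
                    if m is None:
                        return -np.inf
                    return mvn_logpdf_sum(t_obs - m, 0.0, Om + floor)
                pi_rows = (
                    state["pi_ind"][fa_map]
                    if fa_map is not None
                    else state["pi_ind"]
                )
                total = 0.0
                for j in range(t_obs.shape[0]):
                    m, Om = _linearized_fa_meanvar(
                        state["mu_fa"],
                        state["Sigma_fa"],
                        state["kappa"],
                        state["fat"],
                        pi_rows[j],
                        ref,
                    )
                    if m is None:
                        return -np.inf
                    total += mvn_logpdf_sum(t_obs[[j]] - m, 0.0, Om + floor)
                    if not np.isfinite(total):
                        return -np.inf
                return total

            factors["pred_fa"] = pred_fa
            if Sigma_tau_fixed:
                blocks.append(
                    Block(
                        name="Sigma_tau",
                        kind="fixed",
                        shape=(k_fa, k_fa),
                        init=Sigma_tau_init,
                    )
                )
            else:
                b = Block(
                    name="resid_scale",
                    kind="rwm",
                    shape=(1,),
                    init=np.array([spec.sigma_resid_scale]),
                    factor_names=("pred_fa", "prior_resid_scale"),
                    flat_names=["resid_scale"],
                    check_fn=_check_positive,
                )
                b.subblocks = [
                    _sb_log("resid_scale", slice(None), b.factor_names, 1)
                ]
                blocks.append(b)
                ln_mu = np.log(spec.sigma_resid_scale)

                def prior_resid_scale(state, ln_mu=ln_mu):
                    c = state["resid_scale"][0]
                    if c <= 0:
                        return -np.inf
                    lc = np.log(c)
                    return float(
                        -lc - np.log(2.0) - 0.5 * LOG2PI
                        - 0.5 * ((lc - ln_mu) / 2.0) ** 2
                    )

                factors["prior_resid_scale"] = prior_resid_scale
        elif Sigma_tau_fixed:

            def pred_fa(state):
                r = fa_resid(state)
                if r is None:
                    return -np.inf
                return mvn_logpdf_sum(r, 0.0, state["Sigma_tau"])

            factors["pred_fa"] = pred_fa
            blocks.append(
                Block(
                    name="Sigma_tau", kind="fixed", shape=(k_fa, k_fa), init=Sigma_tau_init
                )
            )
        else:
            # Sigma_tau is weakly identified (few predators vs many FA
            # dimensions) and its Gibbs coupling mixes poorly; integrate
            # it out analytically against its inverse-Wishart prior,
            # giving a matrix-t predator factor
            def pred_fa(state):
                r = fa_resid(state)
                if r is None:
                    return -np.inf
                return _matrix_t_logpdf(r, df0, S0_tau)

            factors["pred_fa"] = pred_fa

    # ---- SI marker ---------------------------------------------------------
    if use_si:
        n_iso = len(d.prey.iso_names)
        si_obs = d.predators.si
        S0_prey_si = spec.sigma_prey_scale * np.eye(n_iso)
        S0_tau_si = spec.sigma_resid_scale * np.eye(n_iso)
        df0_si = n_iso + 2
        prey_si_by_s = [d.prey.si[d.prey.si_species == s] for s in species]
        mode = spec.prey_mode
        latent = mode == "latent"

        mu_si_init, mu_si_fixed = fixed_or("mu_si", moments.mu_si)
        Sigma_si_init, Sigma_si_fixed = fixed_or("Sigma_si", moments.Sigma_si)

        for s_idx, s in enumerate(species):
            factors[f"prey_si::{s}"] = lambda state, s_idx=s_idx: mvn_logpdf_sum(
                prey_si_by_s[s_idx], state["mu_si"][s_idx], state["Sigma_si"][s_idx]
            )
            if not mu_si_fixed:
                factors[f"prior_mu_si::{s}"] = lambda state, s_idx=s_idx: float(
                    -0.5
                    * ((state["mu_si"][s_idx] / spec.mu_si_prior_sd) ** 2 + LOG2PI).sum()
                    - n_iso * np.log(spec.mu_si_prior_sd)
                )
            if not Sigma_si_fixed:
                factors[f"prior_Sigma_si::{s}"] = lambda state, s_idx=s_idx: _iw_logpdf(
                    state["Sigma_si"][s_idx], df0_si, S0_prey_si
                )
            if latent:
                factors[f"lat_si::{s}"] = lambda state, s_idx=s_idx: mvn_logpdf_sum(
                    state["x_si"][:, s_idx, :],
                    state["mu_si"][s_idx],
                    state["Sigma_si"][s_idx],
                )

        if mu_si_fixed:
            blocks.append(
                Block(name="mu_si", kind="fixed", shape=(n, n_iso), init=mu_si_init)
            )
        elif latent:

            def gibbs_mu_si(state, rng):
                out = np.empty((n, n_iso))
                for s_idx in range(n):
                    rows = np.vstack([prey_si_by_s[s_idx], state["x_si"][:, s_idx, :]])
                    out[s_idx] = _mvn_conjugate_mean(
                        rows, state["Sigma_si"][s_idx], spec.mu_si_prior_sd, rng
                    )
                return out

            blocks.append(
                Block(
                    name="mu_si",
                    kind="gibbs",
                    shape=(n, n_iso),
                    init=mu_si_init,
                    gibbs_fn=gibbs_mu_si,
                    factor_names=tuple(
                        [f"prey_si::{s}" for s in species]
                        + [f"lat_si::{s}" for s in species]
                        + [f"prior_mu_si::{s}" for s in species]
                    ),
                    store=False,
                )
            )
        else:

            def make_mu_si_prop(s_idx):
                def prop(state, rng):
                    out = state["mu_si"].copy()
                    out[s_idx] = _mvn_conjugate_mean(
                        prey_si_by_s[s_idx],
                        state["Sigma_si"][s_idx],
                        spec.mu_si_prior_sd,
                        rng,
                    )
                    return out

                return prop

            b = Block(
                name="mu_si",
                kind="mh",
                shape=(n, n_iso),
                init=mu_si_init,
                factor_names=tuple(
                    [f"prey_si::{s}" for s in species]
                    + [f"prior_mu_si::{s}" for s in species]
                    + ["pred_si"]
                ),
                store=False,
            )
            b.mh_updates = [
                (
                    f"mu_si[{s_idx}]",
                    make_mu_si_prop(s_idx),
                    ("pred_si",),
                    (f"prey_si::{species[s_idx]}", f"prior_mu_si::{species[s_idx]}"),
                )
                for s_idx in range(n)
            ]
            blocks.append(b)

        if Sigma_si_fixed:
            blocks.append(
                Block(
                    name="Sigma_si", kind="fixed", shape=(n, n_iso, n_iso), init=Sigma_si_init
                )
            )
        elif mode == "linearized":

            def make_sigma_si_prop(s_idx):
                def prop(state, rng):
                    out = state["Sigma_si"].copy()
                    rows = prey_si_by_s[s_idx] - state["mu_si"][s_idx]
                    out[s_idx] = _iw_gibbs(rows, df0_si, S0_prey_si, rng)
                    return out

                return prop

            b = Block(
                name="Sigma_si",
                kind="mh",
                shape=(n, n_iso, n_iso),
                init=Sigma_si_init,
                factor_names=tuple(
                    [f"prey_si::{s}" for s in species]
                    + [f"prior_Sigma_si::{s}" for s in species]
                    + ["pred_si"]
                ),
                store=False,
            )
            b.mh_updates = [
                (
                    f"Sigma_si[{s_idx}]",
                    make_sigma_si_prop(s_idx),
                    ("pred_si",),
                    (
                        f"prey_si::{species[s_idx]}",
                        f"prior_Sigma_si::{species[s_idx]}",
                    ),
                )
                for s_idx in range(n)
            ]
            blocks.append(b)
        else:

            def gibbs_sigma_si(state, rng):
                out = np.empty((n, n_iso, n_iso))
                for s_idx in range(n):
                    rows = prey_si_by_s[s_idx] - state["mu_si"][s_idx]
                    if latent:
                        rows = np.vstack(
                            [rows, state["x_si"][:, s_idx, :] - state["mu_si"][s_idx]]
                        )
                    out[s_idx] = _iw_gibbs(rows, df0_si, S0_prey_si, rng)
                return out

            blocks.append(
                Block(
                    name="Sigma_si",
                    kind="gibbs",
                    shape=(n, n_iso, n_iso),
                    init=Sigma_si_init,
                    gibbs_fn=gibbs_sigma_si,
                    factor_names=tuple(
                        [f"prey_si::{s}" for s in species]
                        + ([f"lat_si::{s}" for s in species] if latent else [])
                        + [f"prior_Sigma_si::{s}" for s in species]
                    ),
                    store=False,
                )
            )

        if latent:

            def make_xsi_op(s_idx):
                def update(state, cache, rng, scale):
                    x = state["x_si"]
                    J = x.shape[0]
                    mu = state["mu_si"][s_idx]
                    Sig = state["Sigma_si"][s_idx]
                    try:
                        Ls = np.linalg.cholesky(np.atleast_2d(Sig))
                    except np.linalg.LinAlgError:
                        return 0.0
                    if spec.grouping == "population":
                        pi_mat = np.tile(state["pi"], (J, 1))
                    elif si_map is not None:
                        pi_mat = state["pi_ind"][si_map]
                    else:
                        pi_mat = state["pi_ind"]
                    mean = np.einsum(
                        "jn,jni->ji", pi_mat, x + state["gamma"][None, :, :]
                    )
                    R = si_obs - mean
                    gauss = "Sigma_tau_si" in state
                    if gauss:
                        Lt = np.linalg.cholesky(np.atleast_2d(state["Sigma_tau_si"]))
                    else:
                        G = S0_tau_si + R.T @ R
                        _, ldG = np.linalg.slogdet(G)
                        const = df0_si + J

                    def lat_q(row):
                        y = np.linalg.solve(Ls, row - mu)
                        return -0.5 * float(y @ y)

                    def pred_q(r):
                        y = np.linalg.solve(Lt, r)
                        return -0.5 * float(y @ y)

                    x_s = x[:, s_idx, :]
                    asum = 0.0
                    for j in range(J):
                        new_row = x_s[j] + scale * (
                            Ls @ rng.standard_normal(n_iso)
                        )
                        r_new = R[j] - pi_mat[j, s_idx] * (new_row - x_s[j])
                        delta = lat_q(new_row) - lat_q(x_s[j])
                        if gauss:
                            delta += pred_q(r_new) - pred_q(R[j])
                        else:
                            G_new = (
                                G - np.outer(R[j], R[j]) + np.outer(r_new, r_new)
                            )
                            sgn, ld_new = np.linalg.slogdet(G_new)
                            if sgn <= 0:
                                continue
                            delta += -0.5 * const * (ld_new - ldG)
                        if not np.isfinite(delta):
                            continue
                        asum += np.exp(min(delta, 0.0))
                        if np.log(rng.random()) < delta:
                            x_s[j] = new_row
                            R[j] = r_new
                            if not gauss:
                                G, ldG = G_new, ld_new
                    cache[f"lat_si::{species[s_idx]}"] = mvn_logpdf_sum(
                        x_s, mu, Sig
                    )
                    cache["pred_si"] = factors["pred_si"](state)
                    return asum / max(J, 1)

                return update

            b = Block(
                name="x_si",
                kind="custom",
                shape=(J_si, n, n_iso),
                init=np.tile(mu_si_init[None, :, :], (J_si, 1, 1)),
                factor_names=tuple([f"lat_si::{s}" for s in species] + ["pred_si"]),
                store=False,
            )
            b.custom_ops = [
                CustomOp(f"x_si[{s_idx}]", make_xsi_op(s_idx), init_log_scale=np.log(0.5))
                for s_idx in range(n)
            ]
            blocks.append(b)

        gamma_init, gamma_fixed = fixed_or("gamma", d.priors.frac_mean)
        gamma_free = (
            np.zeros_like(gamma_init, dtype=bool)
            if gamma_fixed
            else (d.priors.frac_sd > 0)
        )
        b = Block(
            name="gamma",
            kind="rwm" if gamma_free.any() else "fixed",
            shape=(n, n_iso),
            init=gamma_init,
            factor_names=("pred_si", "gamma_prior"),
            store=bool(gamma_free.any()),
            flat_names=[
                f"gamma[{s}|{iso}]" for s in species for iso in d.prey.iso_names
            ],
        )
        if gamma_free.any():
            b.subblocks = [
                _sb_identity("gamma", gamma_free, b.factor_names, int(gamma_free.sum()))
            ]
            gm, gsd = d.priors.frac_mean, d.priors.frac_sd

            def gamma_prior(state, gm=gm, gsd=gsd, free=gamma_free):
                z = (state["gamma"][free] - gm[free]) / gsd[free]
                return float(-0.5 * (z * z + LOG2PI).sum() - np.log(gsd[free]).sum())

            factors["gamma_prior"] = gamma_prior

            if latent:
                # compensated move: shifting gamma_s while translating every
                # latent consumed-SI row by -(gamma*_s - gamma_s) leaves the
                # predator means exactly invariant, so only the latent and
                # gamma terms enter the acceptance (involution, Jacobian 1)
                gj_factors = ["gamma_prior"] + [f"lat_si::{s}" for s in species]

                def gamma_joint_update(state, cache, rng, scale, free=gamma_free):
                    g_cur = state["gamma"]
                    g_new = g_cur.copy()
                    g_new[free] = g_cur[free] + scale * rng.standard_normal(
                        int(free.sum())
                    )
                    x_cur = state["x_si"]
                    state["gamma"] = g_new
                    state["x_si"] = x_cur - (g_new - g_cur)[None, :, :]
                    new_vals = {f: factors[f](state) for f in gj_factors}
                    delta = sum(new_vals.values()) - sum(
                        cache[f] for f in gj_factors
                    )
                    if np.isfinite(delta) and np.log(rng.random()) < delta:
                        cache.update(new_vals)
                        return float(np.exp(min(delta, 0.0)))
                    state["gamma"] = g_cur
                    state["x_si"] = x_cur
                    return (
                        float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
                    )

                b.custom_ops.append(
                    CustomOp(
                        "gamma_joint",
                        gamma_joint_update,
                        target=0.3,
                        init_log_scale=np.log(0.2),
                    )
                )
        blocks.append(b)

        def si_mean(state):
            if spec.grouping == "population":
                pi_mat = np.tile(state["pi"], (J_si, 1))
            elif si_map is not None:
                pi_mat = state["pi_ind"][si_map]
            else:
                pi_mat = state["pi_ind"]
            x = (
                state["x_si"]
                if latent
                else np.broadcast_to(state["mu_si"], (J_si, n, n_iso))
            )
            return np.einsum("jn,jni->ji", pi_mat, x + state["gamma"][None, :, :])

        Sigma_tau_si_init, Sigma_tau_si_fixed = fixed_or(
            "Sigma_tau_si", 0.25 * np.eye(n_iso)
        )
        if mode == "linearized":
            # the SI mixture is linear in the consumed values, so the
            # consumed-prey marginalization is exact here:
            # Var = sum_s pi_s^2 Sigma_s^SI + residual floor
            def pred_si(state):
                floor = (
                    np.atleast_2d(state["Sigma_tau_si"])
                    if "Sigma_tau_si" in state
                    else state["resid_scale_si"][0] * np.eye(n_iso)
                )
                mean = si_mean(state)
                if spec.grouping == "population":
                    Om = np.einsum(
                        "s,sij->ij", state["pi"] ** 2, state["Sigma_si"]
                    )
                    return mvn_logpdf_sum(si_obs - mean, 0.0, Om + floor)
                pi_rows = (
                    state["pi_ind"][si_map]
                    if si_map is not None
                    else state["pi_ind"]
                )
                total = 0.0
                for j in range(si_obs.shape[0]):
                    Om = np.einsum("s,sij->ij", pi_rows[j] ** 2, state["Sigma_si"])
                    total += mvn_logpdf_sum(
                        si_obs[[j]] - mean[j], 0.0, Om + floor
                    )
                    if not np.isfinite(total):
                        return -np.inf
                return total

            factors["pred_si"] = pred_si
            if Sigma_tau_si_fixed:
                blocks.append(
                    Block(
                        name="Sigma_tau_si",
                        kind="fixed",
                        shape=(n_iso, n_iso),
                        init=Sigma_tau_si_init,
                    )
                )
            else:
                b = Block(
                    name="resid_scale_si",
                    kind="rwm",
                    shape=(1,),
                    init=np.array([0.25]),
                    factor_names=("pred_si", "prior_resid_scale_si"),
                    flat_names=["resid_scale_si"],
                    check_fn=_check_positive,
                )
                b.subblocks = [
                    _sb_log("resid_scale_si", slice(None), b.factor_names, 1)
                ]
                blocks.append(b)

                def prior_resid_scale_si(state):
                    c = state["resid_scale_si"][0]
                    if c <= 0:
                        return -np.inf
                    lc = np.log(c)
                    return float(
                        -lc - np.log(2.0) - 0.5 * LOG2PI
                        - 0.5 * ((lc - np.log(0.25)) / 2.0) ** 2
                    )

                factors["prior_resid_scale_si"] = prior_resid_scale_si
        elif Sigma_tau_si_fixed:
            factors["pred_si"] = lambda state: mvn_logpdf_sum(
                si_obs - si_mean(state), 0.0, state["Sigma_tau_si"]
            )
            blocks.append(
                Block(
                    name="Sigma_tau_si",
                    kind="fixed",
                    shape=(n_iso, n_iso),
                    init=Sigma_tau_si_init,
                )
            )
        else:
            # marginalized, as for the FA residual covariance
            factors["pred_si"] = lambda state: _matrix_t_logpdf(
                si_obs - si_mean(state), df0_si, S0_tau_si
            )

    # ---- joint diet/latent move (population + latent mode) -----------------
    # The diet proportions and the latent consumed prey form a narrow ridge:
    # given the latents, the predator factor pins pi tightly, so plain
    # random-walk pi updates crawl. This move proposes pi in ilr space and
    # translates every latent row (alr/SI coordinates) by the shift in the
    # anchor-predicted predator signature, keeping residuals nearly fixed.
    # The map is an involution with unit Jacobian (translations), so plain
    # Metropolis acceptance over the affected factors is exact.
    pi_block = blocks[0]
    if (
        spec.grouping == "population"
        and pi_block.kind == "rwm"
        and spec.prey_mode == "latent"
    ):
        V_pi = ilr_basis(n)
        joint_factors = ["prior_pi"]
        if use_fa:
            joint_factors += [f"lat_fa::{s}" for s in species] + ["pred_fa"]
        if use_si:
            joint_factors += [f"lat_si::{s}" for s in species] + ["pred_si"]

        def anchor_signature(pi_vec, state):
            m = state["kappa"] * alr_inv_mat(state["mu_fa"], ref=ref)
            pre = (pi_vec * state["fat"]) @ m
            return alr_mat((pre / pre.sum())[None, :], ref=ref)[0]

        def pi_joint_update(state, cache, rng, scale):
            pi_cur = state["pi"]
            u1 = ilr_mat(pi_cur[None, :], V_pi)[0] + scale * rng.standard_normal(n - 1)
            pi_new = ilr_inv_mat(u1[None, :], V_pi)[0]
            saved = {"pi": pi_cur}
            state["pi"] = pi_new
            if use_fa:
                saved["phi_alr"] = state["phi_alr"]
                D = anchor_signature(pi_new, state) - anchor_signature(pi_cur, state)
                state["phi_alr"] = saved["phi_alr"] - D[None, None, :]
            if use_si:
                saved["x_si"] = state["x_si"]
                Dsi = (pi_new - pi_cur) @ (state["mu_si"] + state["gamma"])
                state["x_si"] = saved["x_si"] - Dsi[None, None, :]
            new_vals = {f: factors[f](state) for f in joint_factors}
            delta = (
                sum(new_vals.values())
                - sum(cache[f] for f in joint_factors)
                + ilr_log_jacobian(pi_new)
                - ilr_log_jacobian(pi_cur)
            )
            if np.isfinite(delta) and np.log(rng.random()) < delta:
                cache.update(new_vals)
                return float(np.exp(min(delta, 0.0)))
            for k, v in saved.items():
                state[k] = v
            return float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0

        for rep in range(2):  # two kernels per sweep: pi is the focal block
            pi_block.custom_ops.append(
                CustomOp(
                    f"pi_joint{rep}",
                    pi_joint_update,
                    target=0.3,
                    init_log_scale=np.log(0.2),
                )
            )

    meta = {
        "species": species,
        "fa_names": list(d.fa_names),
        "iso_names": list(d.prey.iso_names),
        "markers": spec.markers,
        "grouping": spec.grouping,
        "latent_prey": spec.latent_prey,
        "alr_ref": spec.alr_ref,
        "pred_ids": pred_ids if spec.grouping != "population" else list(d.predators.ids),
        "diet_param_pattern": "pi",
    }
    lp = LogPosterior(blocks, factors, meta=meta)
    logger.info(
        "built %s/%s model: %d blocks (%d sampled), unconstrained dim %d",
        spec.markers,
        spec.grouping,
        len(blocks),
        len(lp.sampled_blocks),
        lp.dim,
    )
    return lp


# ---------------------------------------------------------------------------
# conversion-coefficient estimation from feeding trials
# ---------------------------------------------------------------------------


def estimate_conversion_coefficients(
    trial: DietDataset,
    known_pi,
    latent_prey: bool = False,
    kappa_prior_var: float = 1.0,
    alr_ref: int = -1,
) -> LogPosterior:
    """Model for conversion coefficients from a feeding trial with known
    diet proportions.

    Diet proportions are fixed at the known trial values; kappa is free
    for every species x FA under vague gamma priors (mean 1, variance
    ``kappa_prior_var``). Because the closure in the predator model makes
    kappa identifiable only up to a per-species multiplicative constant,
    draws are reported closure-normalized; feed the posterior moments to
    :func:`conversion_priors_from_draws`.
    """
    known_pi = np.asarray([np.asarray(r, dtype=float) for r in known_pi], dtype=float)
    J = trial.predators.fa.shape[0]
    if known_pi.shape != (J, len(trial.species)):
        raise ModelConfigError(
            f"known_pi must be ({J}, {len(trial.species)}); got {known_pi.shape}"
        )
    if J < 2:
        warnings.warn("fewer than 2 trial predators: kappa is weakly identified")
    priors = dataclasses.replace(
        trial.priors,
        kappa_mean=np.ones_like(trial.priors.kappa_mean),
        kappa_var=np.full_like(trial.priors.kappa_var, float(kappa_prior_var)),
    )
    trial = dataclasses.replace(trial, priors=priors)
    spec = ModelSpec(
        markers="fa",
        grouping="individual",
        latent_prey=latent_prey,
        alr_ref=alr_ref,
        fix={"pi_ind": known_pi},
    )
    return build_model(trial, spec)


def conversion_priors_from_draws(draws, species, fa_names) -> CoefficientPriors:
    """Posterior moments of closure-normalized kappa draws, packaged as
    conversion-coefficient priors for downstream diet models."""
    n, p = len(species), len(fa_names)
    km = np.ones((n, p))
    kv = np.zeros((n, p))
    for i, s in enumerate(species):
        for j, f in enumerate(fa_names):
            x = draws.param(f"kappa[{s}|{f}]")
            km[i, j] = x.mean()
            kv[i, j] = x.var(ddof=1)
    return CoefficientPriors(
        kappa_mean=km,
        kappa_var=kv,
        fat_mean=np.ones(n),
        fat_var=np.zeros(n),
    )
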