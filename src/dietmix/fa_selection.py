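"""Ordination-based selection of fatty acids for diet analysis.

Gas chromatography yields many more fatty acids than a Bayesian mixing
model can comfortably carry; the common habit of keeping the most
abundant FAs can discard exactly the FAs that separate prey species. The
procedure here ranks FAs by their contribution to among-species
separation on constrained ordination axes, and greedily retains the top
contributors until a target fraction of among-source variance is reached,
subject to a cap on the condition number of the species-mean signature
matrix (a collinearity guard: near-collinear prey signatures make the
mixing system ill-conditioned regardless of how much variance they span).

The constrained ordination is CAP (constrained analysis of principal
coordinates) realized as principal coordinates of Euclidean distances on
clr-transformed profiles, followed by redundancy analysis on species
indicators; since the distance is Euclidean in clr space, this reduces to
an SVD of the species-fitted clr matrix. Per-FA contributions are
eigenvalue-weighted squared loadings summed over the constrained axes.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .compositions import clr_mat, closure_mat, replace_zeros_mat
from .data_io import DietDataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class OrdinationResult:
    """Constrained ordination of prey FA profiles by species membership."""

    axes: np.ndarray  # (N, k) constrained sample scores
    eigenvalues: np.ndarray  # (k,) nonnegative, non-increasing
    loadings: np.ndarray  # (p, k) per-FA loadings on constrained axes
    axis_variance_fraction: np.ndarray  # per-axis share of total variance
    contributions: np.ndarray  # (p,) per-FA share of constrained variance, sums to 1
    among_variance_fraction: float  # total among-species share of variance
    fa_names: list[str]


@dataclasses.dataclass
class SelectionReport:
    """Greedy FA-selection trajectory and the chosen subset."""

    order: list[str]  # FAs sorted by decreasing contribution
    contributions: np.ndarray  # aligned with ``order``
    cumulative_variance: np.ndarray  # share of among-source variance at each prefix
    condition_numbers: np.ndarray  # species-mean matrix condition at each prefix
    selected: list[str]
    cum_var_target: float
    cond_cap: float
    fallback: bool = False  # True when no prefix satisfied cond_cap


def _species_indicators(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    species = list(dict.fromkeys(labels))
    X = np.zeros((labels.size, len(species)))
    for i, s in enumerate(species):
        X[labels == s, i] = 1.0
    return X, species


def cap_ordination(
    prey_fa: np.ndarray, species_labels, fa_names=None
) -> OrdinationResult:
    """Constrained ordination of clr-transformed prey profiles on species
    membership.

    Rows with zeros must be replaced first (this function does it with the
    default multiplicative rule if needed). A species with fewer samples
    than constrained axes triggers a rank-deficiency warning; the fit uses
    a pseudo-inverse throughout.
    """
    prey_fa = np.asarray(prey_fa, dtype=float)
    labels = np.asarray(species_labels)
    if prey_fa.ndim != 2 or prey_fa.shape[0] != labels.size:
        raise ValueError("profile matrix and labels disagree")
    if fa_names is None:
        fa_names = [f"fa{i}" for i in range(prey_fa.shape[1])]
    X_ind, species = _species_indicators(labels)
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    counts = X_ind.sum(axis=0)
    if np.any(counts < 2):
        raise ValueError("every species needs >= 2 samples")
    k_max = len(species) - 1
    if np.any(counts < k_max):
        warnings.warn(
            "a species has fewer samples than constrained axes; "
            "using pseudo-inverse projection"
        )

    if np.any(prey_fa == 0):
        prey_fa = replace_zeros_mat(prey_fa)
    Z = clr_mat(closure_mat(prey_fa))
    Z = Z - Z.mean(axis=0)  # PCoA on Euclidean clr distances == PCA on Z
    Xc = X_ind - X_ind.mean(axis=0)
    # projection onto the species subspace (hat matrix via pseudo-inverse)
    H = Xc @ np.linalg.pinv(Xc)
    Zhat = H @ Z

    N = Z.shape[0]
    U, D, Vt = np.linalg.svd(Zhat, full_matrices=False)
    eig = D**2 / (N - 1)
    keep = min(k_max, int(np.sum(eig > max(eig.max(), 1e-300) * 1e-12)))
    keep = max(keep, 1)
    eig = eig[:keep]
    V = Vt[:keep].T  # (p, k) unit loadings
    scores = U[:, :keep] * D[:keep]

    total_var = (Z**2).sum() / (N - 1)
    among = float(eig.sum() / total_var) if total_var > 0 else 0.0
    contrib = (V**2) @ eig
    csum = contrib.sum()
    contributions = contrib / csum if csum > 0 else np.full(len(fa_names), np.nan)
    return OrdinationResult(
        axes=scores,
        eigenvalues=eig,
        loadings=V,
        axis_variance_fraction=eig / total_var if total_var > 0 else eig * 0,
        contributions=contributions,
        among_variance_fraction=among,
        fa_names=list(fa_names),
    )


def condition_number(matrix: np.ndarray) -> float:
    """Ratio of the largest to the smallest singular value.

    Returns +inf (with a warning) when the smallest singular value
    underflows to zero, i.e. the matrix is numerically rank-deficient.
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    sv = np.linalg.svd(m, compute_uv=False)
    if sv[-1] <= 0 or sv[-1] < sv[0] * 1e-12:  # numerically rank-deficient
        warnings.warn("rank-deficient matrix: condition number is infinite")
        return float("inf")
    return float(sv[0] / sv[-1])


def species_mean_matrix(
    prey_fa: np.ndarray, species_labels, fa_idx=None
) -> np.ndarray:
    """n_species x |subset| matrix of species-mean proportions, each row
    re-closed on the subset."""
    prey_fa = np.asarray(prey_fa, dtype=float)
    labels = np.asarray(species_labels)
    species = list(dict.fromkeys(labels))
    M = np.asarray([prey_fa[labels == s].mean(axis=0) for s in species])
    if fa_idx is not None:
        M = M[:, list(fa_idx)]
    return closure_mat(M)


def prey_condition_number(prey_fa, species_labels, fa_names, subset) -> float:
    """Condition number of the species-mean proportion matrix restricted
    to (and re-closed on) an FA subset — the collinearity diagnostic."""
    fa_names = list(fa_names)
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("subset needs >= 2 FAs")
    unknown = [f for f in subset if f not in fa_names]
    if unknown:
        raise ValueError(f"unknown FA names {unknown}")
    idx = [fa_names.index(f) for f in subset]
    return condition_number(species_mean_matrix(prey_fa, species_labels, idx))


def select_fas(
    d: DietDataset, cum_var_target: float = 0.75, cond_cap: float = 20.0
) -> SelectionReport:
    """Greedy FA selection by ordination contribution under a condition-
    number cap.

    FAs are added in decreasing contribution order while the cumulative
    share of among-source variance is below ``cum_var_target`` and the
    species-mean matrix condition number of the prefix stays within
    ``cond_cap``. If not even two FAs satisfy the cap, the best-2 subset
    is returned with a warning. The full trajectory (both diagnostics at
    every prefix) is reported.
    """
    if d.prey.fa is None:
        raise ValueError("dataset has no prey FA table")
    if len(d.fa_names) < 3:
        raise ValueError("need >= 3 FAs to select from")
    ord_res = cap_ordination(d.prey.fa, d.prey.fa_species, d.fa_names)
    order_idx = np.argsort(-ord_res.contributions, kind="stable")
    order = [d.fa_names[i] for i in order_idx]
    contributions = ord_res.contributions[order_idx]
    cumvar = np.cumsum(contributions)

    conds = np.empty(len(order))
    for k in range(1, len(order) + 1):
        conds[k - 1] = condition_number(
            species_mean_matrix(d.prey.fa, d.prey.fa_species, order_idx[:k])
        )

    selected: list[str] = []
    fallback = False
    for k, fa in enumerate(order):
        if selected and cumvar[len(selected) - 1] >= cum_var_target:
            break
        if conds[k] > cond_cap:
            break
        selected.append(fa)
    if len(selected) < 2:
        warnings.warn(
            f"no >=2-FA prefix satisfies cond_cap={cond_cap}; "
            "returning the best-2 subset"
        )
        selected = order[:2]
        fallback = True
    logger.info(
        "selected %d/%d FAs (cumulative among-source variance %.2f, "
        "condition number %.2f)",
        len(selected),
        len(order),
        cumvar[len(selected) - 1],
        conds[len(selected) - 1],
    )
    return SelectionReport(
        order=order,
        contributions=contributions,
        cumulative_variance=cumvar,
        condition_numbers=conds,
        selected=selected,
        cum_var_target=cum_var_target,
        cond_cap=cond_cap,
        fallback=fallback,
    )
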