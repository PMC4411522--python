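"""Posterior sampling engine, convergence diagnostics and draw handling.

The kernel is adaptive random-walk Metropolis-within-Gibbs: each model is
a list of parameter blocks (see :mod:`dietmix.mixing_model`); blocks with
tractable full conditionals (covariances, conditionally Gaussian means)
are updated by Gibbs draws, the rest by random-walk Metropolis proposals
in unconstrained coordinates, one sub-block at a time, with proposal
scales adapted during warmup and frozen afterwards. Only the factors of
the joint density that depend on the updated sub-block are re-evaluated.

Diagnostics (split-chain potential scale reduction and effective sample
size) are computed with ArviZ.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RHAT_GATE = 1.1  # convergence gate logged prominently after every run


class SamplerError(RuntimeError):
    pass


@dataclasses.dataclass
class PosteriorDraws:
    """Labelled MCMC draws with chain structure.

    ``draws`` has shape (chain, iteration, parameter); simplex blocks are
    re-closed on recording, so diet-proportion draws sum to one exactly.
    """

    draws: np.ndarray
    names: list[str]
    seed: int | None
    acceptance: dict
    meta: dict

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 and self.draws.ndim != 3:
            raise ValueError("draws must be (chain, iteration, parameter)")
        if self.draws.ndim == 2:
            self.draws = self.draws[None, ...]

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no parameter named {name!r}") from None

    def param(self, name: str) -> np.ndarray:
        """(chain, iteration) array for one parameter."""
        return self.draws[:, :, self.index(name)]

    def flat(self, name: str) -> np.ndarray:
        """All post-warmup draws of one parameter, chains concatenated."""
        return self.param(name).reshape(-1)

    def select(self, prefix: str) -> list[str]:
        return [n for n in self.names if n.startswith(prefix)]


def _jitter_init(lp, rng, scale: float):
    """Overdispersed initial state: jitter every RWM sub-block in
    unconstrained coordinates; retry with smaller jitter if the density
    is not finite at the proposal."""
    for attempt in range(25):
        state = lp.init_state()
        s = scale * 0.7**attempt
        for b in lp.sampled_blocks:
            if b.kind == "custom":
                state[b.name] = state[b.name] + 0.5 * s * rng.standard_normal(
                    state[b.name].shape
                )
            if b.kind not in ("rwm", "mh"):
                continue
            for sb in b.subblocks:
                u = sb.get_u(state[b.name]) + s * rng.standard_normal(sb.size)
                state[b.name] = sb.set_u(state[b.name], u)
        if np.isfinite(lp.value_at_state(state)):
            return state
    raise SamplerError(
        "could not find a finite-density initial state after 25 attempts; "
        "check the model/priors against the data"
    )


def run_chains(
    lp,
    n_chains: int = 3,
    n_iter: int = 20000,
    n_warmup: int | None = None,
    seed: int = 0,
    thin: int = 1,
    init_jitter: float = 0.5,
    target_accept: float | None = None,
) -> PosteriorDraws:
    """Sample a LogPosterior; fully reproducible given ``seed``.

    ``n_warmup`` defaults to half of ``n_iter``; adaptation of proposal
    scales stops at the end of warmup and warmup draws are discarded.
    """
    if n_chains < 2:
        raise ValueError("need >= 2 chains for diagnostics")
    if n_warmup is None:
        n_warmup = n_iter // 2
    if not 0 <= n_warmup < n_iter:
        raise ValueError("need 0 <= n_warmup < n_iter")

    stored_blocks = [b for b in lp.sampled_blocks if b.store]
    name_map = lp.parameter_names()
    names: list[str] = []
    for b in stored_blocks:
        names.extend(name_map[b.name])
    cov_blocks = getattr(lp, "_cov_blocks", set())

    def record(state):
        out = []
        for b in stored_blocks:
            if b.report_fn is not None:
                out.append(np.asarray(b.report_fn(state), dtype=float).ravel())
            elif b.name in cov_blocks:
                k = b.shape[0]
                out.append(np.asarray(state[b.name])[np.tril_indices(k)])
            else:
                out.append(np.asarray(state[b.name], dtype=float).ravel())
        return np.concatenate(out) if out else np.empty(0)

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    kept = (n_iter - n_warmup + thin - 1) // thin
    all_draws = np.empty((n_chains, kept, len(names)))
    acc_counts: dict[str, list[float]] = {}

    ops: list[tuple] = []
    for b in lp.sampled_blocks:
        if b.kind == "gibbs":
            ops.append(("gibbs", b, tuple(lp.block_factors(b.factor_names))))
        elif b.kind in ("rwm", "mh"):
            for sb in b.subblocks:
                ops.append(("rwm", b, sb, tuple(lp.block_factors(sb.factor_names))))
            for co in b.custom_ops:
                ops.append(("custom", b, co))
            for key, prop_fn, mh_f, refresh_f in b.mh_updates:
                ops.append(
                    (
                        "mh",
                        b,
                        key,
                        prop_fn,
                        tuple(lp.block_factors(mh_f)),
                        tuple(lp.block_factors(refresh_f)),
                    )
                )
        elif b.kind == "custom":
            for co in b.custom_ops:
                ops.append(("custom", b, co))
        else:
            raise SamplerError(f"unknown block kind {b.kind!r}")

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        state = _jitter_init(lp, rng, init_jitter)
        cache = {fname: fn(state) for fname, fn in lp.factors.items()}
        if not np.all(np.isfinite(list(cache.values()))):
            raise SamplerError("non-finite factor at initial state")

        # per-subblock proposal state
        prop = {}
        mh_acc: dict[str, list[int]] = {}
        for op in ops:
            if op[0] == "rwm":
                _, b, sb, _ = op
                tgt = target_accept or (0.44 if sb.size == 1 else 0.25)
                prop[(b.name, sb.key)] = {
                    "log_scale": np.log(2.38 / np.sqrt(sb.size)),
                    "diag": np.ones(sb.size),
                    "target": tgt,
                    "acc": 0,
                    "n": 0,
                    "hist": [],
                }
            elif op[0] == "custom":
                _, b, co = op
                prop[(b.name, co.key)] = {
                    "log_scale": co.init_log_scale,
                    "target": target_accept or co.target,
                    "acc": 0.0,
                    "n": 0,
                }

        half_warm = n_warmup // 2
        k_out = 0
        for it in range(n_iter):
            adapting = it < n_warmup
            for op in ops:
                kind = op[0]
                if kind == "rwm":
                    _, b, sb, fnames = op
                    ps = prop[(b.name, sb.key)]
                    cur_val = state[b.name]
                    u = sb.get_u(cur_val)
                    if sb.precond is not None:
                        L = sb.precond(state)
                        u_new = u + np.exp(ps["log_scale"]) * (
                            L @ rng.standard_normal(sb.size)
                        )
                    else:
                        step = np.exp(ps["log_scale"]) * ps["diag"]
                        u_new = u + step * rng.standard_normal(sb.size)
                    new_val = sb.set_u(cur_val, u_new)
                    state[b.name] = new_val
                    new_terms = {f: lp.factors[f](state) for f in fnames}
                    delta = (
                        sum(new_terms.values())
                        - sum(cache[f] for f in fnames)
                        + sb.log_jac(new_val)
                        - sb.log_jac(cur_val)
                    )
                    if np.isfinite(delta) and np.log(rng.random()) < delta:
                        cache.update(new_terms)
                        accepted = True
                    else:
                        state[b.name] = cur_val
                        accepted = False
                    ps["n"] += 1
                    ps["acc"] += accepted
                    if adapting:
                        gamma = (it + 1) ** -0.6
                        a_prob = min(1.0, np.exp(delta)) if np.isfinite(delta) else 0.0
                        ps["log_scale"] += gamma * (a_prob - ps["target"])
                        if it < half_warm:
                            ps["hist"].append(sb.get_u(state[b.name]))
                        elif it == half_warm and len(ps["hist"]) >= 20:
                            sd = np.std(np.asarray(ps["hist"]), axis=0)
                            ps["diag"] = np.where(sd > 1e-12, sd, 1.0)
                            ps["hist"] = []
                elif kind == "custom":
                    _, b, co = op
                    ps = prop[(b.name, co.key)]
                    a = co.update(state, cache, rng, np.exp(ps["log_scale"]))
                    ps["n"] += 1
                    ps["acc"] += float(a)
                    if adapting:
                        gamma = (it + 1) ** -0.6
                        ps["log_scale"] += gamma * (float(a) - ps["target"])
                elif kind == "gibbs":
                    _, b, fnames = op
                    state[b.name] = np.asarray(
                        b.gibbs_fn(state, rng), dtype=float
                    ).reshape(b.shape)
                    for f in fnames:
                        cache[f] = lp.factors[f](state)
                else:  # independence MH with conjugate proposal
                    _, b, key, prop_fn, mh_f, refresh_f = op
                    cur_val = state[b.name]
                    state[b.name] = np.asarray(prop_fn(state, rng), dtype=float)
                    new_terms = {f: lp.factors[f](state) for f in mh_f}
                    delta = sum(new_terms.values()) - sum(cache[f] for f in mh_f)
                    if np.isfinite(delta) and np.log(rng.random()) < delta:
                        cache.update(new_terms)
                        for f in refresh_f:
                            cache[f] = lp.factors[f](state)
                        mh_acc.setdefault(key, []).append(1)
                    else:
                        state[b.name] = cur_val
                        mh_acc.setdefault(key, []).append(0)

            if it >= n_warmup and (it - n_warmup) % thin == 0:
                all_draws[c, k_out] = record(state)
                k_out += 1

        for (bname, key), ps in prop.items():
            acc_counts.setdefault(f"{bname}::{key}", []).append(
                ps["acc"] / max(ps["n"], 1)
            )
        for key, hits in mh_acc.items():
            acc_counts.setdefault(f"mh::{key}", []).append(float(np.mean(hits)))

    acceptance = {k: float(np.mean(v)) for k, v in acc_counts.items()}
    draws = PosteriorDraws(
        draws=all_draws,
        names=names,
        seed=seed,
        acceptance=acceptance,
        meta=dict(lp.meta),
    )
    bad = {}
    try:
        r = rhat(draws)
        bad = {k: v for k, v in r.items() if np.isfinite(v) and v > RHAT_GATE}
    except Exception:  # diagnostics must never kill a run
        pass
    if bad:
        logger.warning(
            "CONVERGENCE GATE: %d parameter(s) with rhat > %.2f (worst: %s)",
            len(bad),
            RHAT_GATE,
            max(bad, key=bad.get),
        )
    else:
        logger.info("convergence gate passed: all rhat <= %.2f", RHAT_GATE)
    return draws


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _per_param(draws: PosteriorDraws, fn) -> dict[str, float]:
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(draws.names):
            x = draws.draws[:, :, i]
            out[name] = fn(x)
    return out


def rhat(draws: PosteriorDraws) -> dict[str, float]:
    """Split-chain potential scale reduction factor per parameter.

    Parameters that are exactly constant across all draws are reported as
    1.0 (and logged), since a pinned coordinate has trivially converged.
    """
    import arviz as az

    if draws.n_chains < 2 or draws.n_draws < 10:
        raise ValueError("rhat needs >= 2 chains and >= 10 iterations")

    def one(x):
        if np.ptp(x) == 0:
            logger.info("rhat: constant parameter flagged")
            return 1.0
        return float(az.rhat(x))

    return _per_param(draws, one)


def ess(draws: PosteriorDraws) -> dict[str, float]:
    """Effective sample size per parameter (autocorrelation-based).

    Constant parameters report the total number of draws, flagged in the
    log.
    """
    import arviz as az

    if draws.n_chains < 2 or draws.n_draws < 10:
        raise ValueError("ess needs >= 2 chains and >= 10 iterations")
    total = draws.n_chains * draws.n_draws

    def one(x):
        if np.ptp(x) == 0:
            logger.info("ess: constant parameter flagged")
            return float(total)
        return float(az.ess(x))

    return _per_param(draws, one)


def summarize(
    draws: PosteriorDraws, levels: Sequence[float] = (0.9, 0.95)
) -> pd.DataFrame:
    """Posterior summary table: one row per parameter with mean, median,
    SD, central credible intervals at the requested levels, rhat and ESS."""
    flat = draws.draws.reshape(-1, len(draws.names))
    out = pd.DataFrame(index=pd.Index(draws.names, name="parameter"))
    out["mean"] = flat.mean(axis=0)
    out["median"] = np.median(flat, axis=0)
    out["sd"] = flat.std(axis=0, ddof=1)
    for lev in sorted(levels):
        lo, hi = 50 * (1 - lev), 50 * (1 + lev)
        pct = int(round(100 * lev))
        out[f"ci{pct}_lo"] = np.percentile(flat, lo, axis=0)
        out[f"ci{pct}_hi"] = np.percentile(flat, hi, axis=0)
    try:
        r = rhat(draws)
        e = ess(draws)
        out["rhat"] = [r[n] for n in draws.names]
        out["ess"] = [e[n] for n in draws.names]
    except ValueError:
        out["rhat"] = np.nan
        out["ess"] = np.nan
    return out


# ---------------------------------------------------------------------------
# draw post-processing
# ---------------------------------------------------------------------------


def _diet_units(draws: PosteriorDraws) -> dict[str, dict[str, str]]:
    """Map unit -> {species: parameter name} for diet-proportion draws.

    Units are "population" (``pi[sp]`` or ``Pi[sp]``) and individual
    predator ids (``pi[id|sp]``).
    """
    species = draws.meta.get("species")
    if not species:
        raise ValueError("draws carry no species metadata")
    units: dict[str, dict[str, str]] = {}
    for prefix, unit in (("pi[", None), ("Pi[", "population")):
        for name in draws.names:
            if not name.startswith(prefix):
                continue
            inner = name[len(prefix) : -1]
            if "|" in inner:
                pid, sp = inner.split("|", 1)
                if sp in species:
                    units.setdefault(pid, {})[sp] = name
            elif inner in species:
                units.setdefault(unit or "population", {})[inner] = name
    return units


def combine_sources(
    draws: PosteriorDraws, groups: Mapping[str, str]
) -> PosteriorDraws:
    """Post-hoc source grouping: per draw, a group's proportion is the sum
    of its member species' proportions.

    ``groups`` maps every species to a group name and must partition the
    species list.
    """
    species = draws.meta.get("species")
    if not species:
        raise ValueError("draws carry no species metadata")
    missing = [s for s in species if s not in groups]
    extra = [s for s in groups if s not in species]
    if missing or extra:
        raise ValueError(
            f"groups must partition the species: missing {missing}, unknown {extra}"
        )
    group_names = list(dict.fromkeys(groups.values()))
    units = _diet_units(draws)
    if not units:
        raise ValueError("no diet-proportion parameters in draws")
    new_names: list[str] = []
    cols: list[np.ndarray] = []
    for unit, members in units.items():
        if set(members) != set(species):
            continue  # incomplete unit (should not happen)
        for g in group_names:
            idx = [draws.index(members[s]) for s in species if groups[s] == g]
            summed = draws.draws[:, :, idx].sum(axis=2)
            label = f"pi[{g}]" if unit == "population" else f"pi[{unit}|{g}]"
            new_names.append(label)
            cols.append(summed)
    arr = np.stack(cols, axis=2)
    meta = dict(draws.meta)
    meta["species"] = group_names
    meta["grouped_from"] = dict(groups)
    return PosteriorDraws(
        draws=arr, names=new_names, seed=draws.seed, acceptance={}, meta=meta
    )


def compare_spread(draws_a: PosteriorDraws, draws_b: PosteriorDraws) -> pd.DataFrame:
    """Spread ratios (a relative to b) for parameters present in both runs.

    ``sd_ratio`` < 1 means run *a* has the tighter posterior; ``w95_ratio``
    compares 95% central interval widths the same way.
    """
    common = [n for n in draws_a.names if n in set(draws_b.names)]
    if not common:
        raise ValueError("no common parameters to compare")
    rows = []
    for n in common:
        xa, xb = draws_a.flat(n), draws_b.flat(n)
        qa = np.percentile(xa, [2.5, 97.5])
        qb = np.percentile(xb, [2.5, 97.5])
        wa, wb = qa[1] - qa[0], qb[1] - qb[0]
        rows.append(
            {
                "parameter": n,
                "sd_a": xa.std(ddof=1),
                "sd_b": xb.std(ddof=1),
                "sd_ratio": xa.std(ddof=1) / xb.std(ddof=1) if xb.std(ddof=1) > 0 else np.nan,
                "w95_ratio": wa / wb if wb > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
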