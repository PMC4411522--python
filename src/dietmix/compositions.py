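"""Compositional-geometry primitives.

Fatty-acid profiles and diet proportions are *compositions*: nonnegative
vectors carrying only relative information, constrained to sum to one.
Standard multivariate machinery does not apply directly on the simplex, so
every model in this package works in log-ratio coordinates:

* the additive log-ratio (alr) transform divides each part by a reference
  part and takes logs, giving an unconstrained (p-1)-vector;
* the centred log-ratio (clr) transform divides by the geometric mean,
  giving a p-vector constrained to sum to zero;
* an orthonormal isometric log-ratio (ilr) basis is used internally where a
  non-degenerate density over the simplex is needed (hierarchical diet
  models, samplers); it is not part of the public surface.

All transforms guard against overflow by subtracting the maximum before
exponentiation, and refuse zero parts (use :func:`replace_zeros` first).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: tolerance for accepting a vector as already closed
SUM_TOL = 1e-9
#: vectors off by up to this much are re-closed with a warning (instrument
#: exports frequently mis-sum at the third decimal)
RECLOSE_TOL = 1e-3


class CompositionError(ValueError):
    """Input is not a valid composition."""


class ZeroPartError(CompositionError):
    """A log-ratio transform met a zero part; call replace_zeros first."""


@dataclasses.dataclass(frozen=True)
class Composition:
    """A p-part vector of proportions summing to one.

    Parameters
    ----------
    parts
        Nonnegative proportions. Vectors summing to 1 within ``1e-9`` are
        accepted as-is; sums off by at most ``1e-3`` are re-closed with a
        logged warning; anything else raises :class:`CompositionError`.
    labels
        Optional part names, same length as ``parts``.
    """

    parts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        parts = np.asarray(self.parts, dtype=float)
        if parts.ndim != 1 or parts.size < 2:
            raise CompositionError("a composition needs >= 2 parts in a 1-D vector")
        if not np.all(np.isfinite(parts)):
            raise CompositionError("composition parts must be finite")
        if np.any(parts < 0):
            raise CompositionError("composition parts must be nonnegative")
        total = parts.sum()
        if abs(total - 1.0) > SUM_TOL:
            if abs(total - 1.0) <= RECLOSE_TOL:
                logger.warning("re-closing composition with sum %.6f", total)
                parts = parts / total
            else:
                raise CompositionError(
                    f"composition parts sum to {total:.6f}, not 1"
                )
        parts.flags.writeable = False
        object.__setattr__(self, "parts", parts)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != parts.size:
                raise CompositionError("labels length does not match parts")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.parts.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.parts, dtype=dtype)

    def __getitem__(self, idx):
        return self.parts[idx]


@dataclasses.dataclass(frozen=True)
class LogRatioVector:
    """A log-ratio image of a composition.

    ``basis`` is ``("alr", ref_index)`` (length p-1, reference part dropped)
    or ``("clr", None)`` (length p, values sum to zero).
    """

    values: np.ndarray
    basis: tuple[str, int | None]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        kind = self.basis[0]
        if kind not in ("alr", "clr"):
            raise ValueError(f"unknown log-ratio basis {kind!r}")
        if kind == "clr" and abs(values.sum()) > 1e-9:
            raise ValueError("clr values must sum to 0")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return self.values.size


def _parts(c) -> np.ndarray:
    if isinstance(c, Composition):
        return c.parts
    return Composition(np.asarray(c, dtype=float)).parts


def closure(v, labels: Sequence[str] | None = None) -> Composition:
    """Normalize a nonnegative vector to unit sum (the C operator)."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise CompositionError("closure needs a 1-D vector with >= 2 entries")
    if np.any(v < 0):
        raise CompositionError("closure input must be nonnegative")
    total = v.sum()
    if not np.isfinite(total) or total <= 0:
        raise CompositionError("closure input must have a positive sum")
    return Composition(v / total, labels=tuple(labels) if labels is not None else None)


def closure_mat(x: np.ndarray) -> np.ndarray:
    """Row-wise closure of a matrix of nonnegative vectors."""
    x = np.asarray(x, dtype=float)
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise CompositionError("closure input rows must have positive sums")
    return x / s


def _resolve_ref(ref: int, p: int) -> int:
    if not -p <= ref < p:
        raise IndexError(f"reference index {ref} out of range for {p} parts")
    return ref % p


def alr(c, ref: int = -1) -> LogRatioVector:
    """Additive log-ratio transform, reference part dropped.

    ``values[k] = log(c[k] / c[ref])`` for the p-1 non-reference parts, in
    original order with the reference removed.
    """
    parts = _parts(c)
    r = _resolve_ref(ref, parts.size)
    if np.any(parts == 0):
        raise ZeroPartError("alr undefined for zero parts; apply replace_zeros first")
    keep = np.arange(parts.size) != r
    return LogRatioVector(np.log(parts[keep]) - np.log(parts[r]), basis=("alr", r))


def alr_mat(x: np.ndarray, ref: int = -1) -> np.ndarray:
    """Row-wise alr of a matrix of compositions (no per-row validation)."""
    x = np.asarray(x, dtype=float)
    r = _resolve_ref(ref, x.shape[-1])
    if np.any(x <= 0):
        raise ZeroPartError("alr undefined for zero parts; apply replace_zeros first")
    keep = np.arange(x.shape[-1]) != r
    return np.log(x[..., keep]) - np.log(x[..., [r]])


def alr_inv(y, ref: int = -1) -> Composition:
    """Inverse alr: insert the reference part and close exp(values)."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("alr_inv expects a 1-D vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("alr_inv values must be finite")
    p = y.size + 1
    r = _resolve_ref(ref, p)
    z = np.insert(y, r, 0.0)
    z -= z.max()  # overflow guard
    e = np.exp(z)
    return Composition(e / e.sum())


def alr_inv_mat(y: np.ndarray, ref: int = -1) -> np.ndarray:
    """Row-wise inverse alr (overflow-guarded)."""
    y = np.asarray(y, dtype=float)
    p = y.shape[-1] + 1
    r = _resolve_ref(ref, p)
    z = np.insert(y, r, 0.0, axis=-1)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def clr(c) -> LogRatioVector:
    """Centred log-ratio transform: log parts minus their mean."""
    parts = _parts(c)
    if np.any(parts == 0):
        raise ZeroPartError("clr undefined for zero parts; apply replace_zeros first")
    lp = np.log(parts)
    return LogRatioVector(lp - lp.mean(), basis=("clr", None))


def clr_mat(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ZeroPartError("clr undefined for zero parts; apply replace_zeros first")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def clr_inv(z) -> Composition:
    """Inverse clr: closure of exp(z); invariant to adding a constant to z."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError("clr_inv expects a 1-D vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("clr_inv values must be finite")
    z = z - z.max()
    e = np.exp(z)
    return Composition(e / e.sum())


def replace_zeros(c, delta: float | None = None) -> Composition:
    """Multiplicative zero replacement.

    Zeros become ``delta`` and the nonzero parts are scaled by
    ``1 - n_zeros * delta`` so the vector still sums to one; ratios among
    nonzero parts are preserved. Idempotent on zero-free input. By default
    ``delta`` is half the smallest positive part.
    """
    parts = _parts(c)
    zero = parts == 0
    pos_min = parts[~zero].min()
    if delta is None:
        delta = 0.5 * pos_min
    if not 0 < delta < pos_min:
        raise ValueError(
            f"delta must lie in (0, {pos_min:.3g}), the smallest positive part"
        )
    if not zero.any():
        labels = c.labels if isinstance(c, Composition) else None
        return Composition(parts, labels=labels)
    out = parts * (1.0 - zero.sum() * delta)
    out[zero] = delta
    labels = c.labels if isinstance(c, Composition) else None
    return Composition(out, labels=labels)


def replace_zeros_mat(x: np.ndarray, delta: float | None = None) -> np.ndarray:
    """Row-wise multiplicative zero replacement on a closed matrix."""
    x = closure_mat(np.asarray(x, dtype=float))
    if delta is None:
        pos = x[x > 0]
        delta = 0.5 * pos.min()
    out = x.copy()
    for i in range(out.shape[0]):
        zero = out[i] == 0
        if zero.any():
            out[i] = out[i] * (1.0 - zero.sum() * delta)
            out[i, zero] = delta
    return out


def geometric_mean_profile(rows) -> Composition:
    """Closure of column-wise geometric means of a stack of compositions."""
    if isinstance(rows, np.ndarray):
        mat = rows.astype(float)
    else:
        mat = np.asarray([_parts(r) for r in rows], dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise CompositionError("need at least one profile row")
    if np.any(mat <= 0):
        raise ZeroPartError("geometric mean undefined for zero parts")
    gm = np.exp(np.log(mat).mean(axis=0))
    return closure(gm)


# ---------------------------------------------------------------------------
# internal ilr machinery (not part of the public surface)
# ---------------------------------------------------------------------------


def ilr_basis(p: int) -> np.ndarray:
    """Fixed orthonormal Helmert-style contrast matrix, shape (p, p-1).

    Columns are orthonormal and orthogonal to the all-ones vector, so clr
    vectors map bijectively to (p-1)-dim ilr coordinates.
    """
    if p < 2:
        raise ValueError("need p >= 2")
    V = np.zeros((p, p - 1))
    for k in range(1, p):
        V[:k, k - 1] = 1.0 / np.sqrt(k * (k + 1))
        V[k, k - 1] = -k / np.sqrt(k * (k + 1))
    return V


def ilr_mat(x: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Row-wise ilr coordinates of compositions."""
    x = np.asarray(x, dtype=float)
    V = ilr_basis(x.shape[-1]) if basis is None else basis
    return clr_mat(x) @ V


def ilr_inv_mat(u: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Row-wise inverse ilr (overflow-guarded closure of exp)."""
    u = np.asarray(u, dtype=float)
    V = ilr_basis(u.shape[-1] + 1) if basis is None else basis
    z = u @ V.T
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def ilr_log_jacobian(pi: np.ndarray) -> float:
    """log |det d(pi)/du| for the map u -> closure(exp(V u)).

    Equals ``0.5*log(p) + sum(log(pi))``; used when a density stated over
    the simplex is sampled in ilr coordinates.
    """
    pi = np.asarray(pi, dtype=float)
    p = pi.size
    return 0.5 * np.log(p) + np.log(pi).sum()
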