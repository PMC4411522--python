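"""Compositional-geometry primitives: exact examples, round trips and
cross-checks against scikit-bio's independent implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dietmix.compositions import (
    Composition,
    CompositionError,
    ZeroPartError,
    alr,
    alr_inv,
    alr_inv_mat,
    alr_mat,
    closure,
    closure_mat,
    clr,
    clr_inv,
    geometric_mean_profile,
    ilr_basis,
    ilr_inv_mat,
    ilr_log_jacobian,
    ilr_mat,
    replace_zeros,
)


def random_compositions(draw_dims=st.integers(3, 25)):
    return draw_dims.flatmap(
        lambda p: st.lists(
            st.floats(0.05, 10.0), min_size=p, max_size=p
        ).map(lambda v: np.asarray(v) / np.sum(v))
    )


class TestClosure:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ([1, 1, 2], [0.25, 0.25, 0.5]),
            ([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]),
            ([3, 0, 1], [0.75, 0, 0.25]),
        ],
    )
    def test_examples(self, v, expected):
        np.testing.assert_allclose(closure(v).parts, expected)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.random(7)
        once = closure(v).parts
        np.testing.assert_allclose(closure(once).parts, once)

    @pytest.mark.parametrize("bad", [[0, 0, 0], [1, -1, 2], [1.0]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(CompositionError):
            closure(bad)

    def test_near_one_reclosed_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="dietmix.compositions"):
            c = Composition(np.array([0.2, 0.3, 0.5004]))
        assert abs(c.parts.sum() - 1) < 1e-12
        assert any("re-closing" in r.message for r in caplog.records)

    def test_far_from_one_rejected(self):
        with pytest.raises(CompositionError):
            Composition(np.array([0.2, 0.3, 0.6]))


class TestAlr:
    def test_formula(self):
        got = np.asarray(alr([0.2, 0.3, 0.5], ref=-1))
        np.testing.assert_allclose(got, np.log([0.4, 0.6]))

    def test_uniform_maps_to_zero(self):
        np.testing.assert_allclose(np.asarray(alr([1 / 3] * 3)), [0, 0], atol=1e-12)

    def test_zero_part_raises_pointer_to_replace_zeros(self):
        with pytest.raises(ZeroPartError, match="replace_zeros"):
            alr([0.75, 0.0, 0.25])

    def test_inverse_examples(self):
        np.testing.assert_allclose(alr_inv(np.zeros(2)).parts, [1 / 3] * 3)
        np.testing.assert_allclose(
            alr_inv(np.log([0.4, 0.6]), ref=-1).parts, [0.2, 0.3, 0.5]
        )

    def test_inverse_overflow_guard(self):
        c = alr_inv(np.array([700.0, 0.0])).parts
        assert np.isfinite(c).all()
        assert c[0] == pytest.approx(1.0)

    def test_nonstandard_reference(self):
        c = [0.2, 0.3, 0.5]
        got = np.asarray(alr(c, ref=0))
        np.testing.assert_allclose(got, np.log([0.3 / 0.2, 0.5 / 0.2]))
        np.testing.assert_allclose(alr_inv(got, ref=0).parts, c)


class TestClr:
    def test_uniform(self):
        np.testing.assert_allclose(np.asarray(clr([0.25] * 4)), np.zeros(4), atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=6)
        np.testing.assert_allclose(
            clr_inv(z + 5.0).parts, clr_inv(z).parts, atol=1e-10
        )

    def test_zero_part_raises(self):
        with pytest.raises(ZeroPartError):
            clr([0.5, 0.5, 0.0])


@settings(max_examples=200, deadline=None)
@given(random_compositions())
def test_round_trips(c):
    """alr/clr round trips recover the composition to 1e-10."""
    np.testing.assert_allclose(alr_inv(np.asarray(alr(c))).parts, c, atol=1e-10)
    np.testing.assert_allclose(clr_inv(np.asarray(clr(c))).parts, c, atol=1e-10)
    assert abs(np.asarray(clr(c)).sum()) < 1e-10


class TestReplaceZeros:
    def test_multiplicative_rule(self):
        got = replace_zeros([0.75, 0, 0.25], delta=0.01).parts
        np.testing.assert_allclose(got, [0.7425, 0.01, 0.2475])

    def test_all_but_one_zero(self):
        got = replace_zeros([1.0, 0.0, 0.0], delta=0.01).parts
        np.testing.assert_allclose(got, [0.98, 0.01, 0.01])

    def test_idempotent_on_zero_free(self):
        c = closure([1, 2, 3]).parts
        np.testing.assert_allclose(replace_zeros(c, delta=1e-3).parts, c)

    def test_preserves_ratios_and_sum(self):
        got = replace_zeros([0.6, 0.2, 0.0, 0.2], delta=0.005).parts
        assert got.sum() == pytest.approx(1.0)
        assert got[0] / got[1] == pytest.approx(3.0)

    @pytest.mark.parametrize("delta", [0.0, -0.1, 0.9])
    def test_bad_delta(self, delta):
        with pytest.raises(ValueError):
            replace_zeros([0.75, 0, 0.25], delta=delta)


class TestGeometricMeanProfile:
    def test_single_row_identity(self):
        c = closure([1, 2, 3]).parts
        np.testing.assert_allclose(geometric_mean_profile(c[None, :]).parts, c)

    def test_symmetry(self):
        got = geometric_mean_profile(np.array([[0.2, 0.8], [0.8, 0.2]])).parts
        np.testing.assert_allclose(got, [0.5, 0.5])

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        rows = closure_mat(rng.random((5, 4)))
        a = geometric_mean_profile(rows).parts
        b = geometric_mean_profile(rows[::-1]).parts
        np.testing.assert_allclose(a, b)

    def test_zero_rejected(self):
        with pytest.raises(ZeroPartError):
            geometric_mean_profile(np.array([[0.5, 0.5, 0.0], [0.2, 0.3, 0.5]]))


class TestAgainstScikitBio:
    """scikit-bio implements the same transforms independently."""

    def test_transforms_match(self):
        from skbio.stats import composition as skb

        rng = np.random.default_rng(3)
        x = closure_mat(rng.random((20, 6)) + 0.05)
        np.testing.assert_allclose(clr_inv(np.asarray(clr(x[0]))).parts, x[0], atol=1e-10)
        np.testing.assert_allclose(
            np.asarray(clr(x[0])), skb.clr(x[0]), atol=1e-10
        )
        np.testing.assert_allclose(closure_mat(x * 7.0), skb.closure(x * 7.0))

    def test_zero_replacement_matches(self):
        from skbio.stats import composition as skb

        x = np.array([[0.75, 0.0, 0.25], [0.1, 0.4, 0.5]])
        ours = replace_zeros(x[0], delta=0.01).parts
        theirs = skb.multi_replace(x, delta=0.01)[0]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestIlrInternals:
    def test_basis_orthonormal_and_contrast(self):
        for p in (2, 5, 9):
            V = ilr_basis(p)
            np.testing.assert_allclose(V.T @ V, np.eye(p - 1), atol=1e-12)
            np.testing.assert_allclose(V.sum(axis=0), 0.0, atol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(4)
        x = closure_mat(rng.random((10, 5)) + 0.05)
        np.testing.assert_allclose(ilr_inv_mat(ilr_mat(x)), x, atol=1e-10)

    def test_log_jacobian_matches_finite_differences(self):
        p = 4
        V = ilr_basis(p)
        u = np.array([0.3, -0.2, 0.5])

        def f(u):
            return ilr_inv_mat(u[None, :], V)[0][: p - 1]

        eps = 1e-6
        J = np.empty((p - 1, p - 1))
        for i in range(p - 1):
            du = np.zeros(p - 1)
            du[i] = eps
            J[:, i] = (f(u + du) - f(u - du)) / (2 * eps)
        pi = ilr_inv_mat(u[None, :], V)[0]
        np.testing.assert_allclose(
            np.log(abs(np.linalg.det(J))), ilr_log_jacobian(pi), atol=1e-6
        )


def test_alr_mat_consistent_with_scalar():
    rng = np.random.default_rng(5)
    x = closure_mat(rng.random((8, 5)) + 0.01)
    m = alr_mat(x, ref=2)
    for i in range(8):
        np.testing.assert_allclose(m[i], np.asarray(alr(x[i], ref=2)), atol=1e-12)
    np.testing.assert_allclose(alr_inv_mat(m, ref=2), x, atol=1e-10)
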