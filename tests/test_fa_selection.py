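"""Ordination-based FA ranking and the greedy selection procedure."""

import numpy as np
import pytest

from dietmix.compositions import alr_inv_mat, closure_mat
from dietmix.data_io import dataset_from_arrays
from dietmix.fa_selection import (
    cap_ordination,
    condition_number,
    prey_condition_number,
    select_fas,
    species_mean_matrix,
)


def two_species_one_informative_fa(rng, m=15, p=6, shift=2.0):
    """Two species identical except in FA 0 (alr space)."""
    base = rng.normal(0, 0.1, size=(2 * m, p - 1))
    base[m:, 0] += shift
    labels = np.array(["a"] * m + ["b"] * m)
    return alr_inv_mat(base), labels


class TestCapOrdination:
    def test_single_discriminative_fa_dominates(self):
        rng = np.random.default_rng(0)
        fa, labels = two_species_one_informative_fa(rng)
        res = cap_ordination(fa, labels)
        assert res.contributions.sum() == pytest.approx(1.0)
        # fa0 carries the separation (the reference part also responds,
        # since alr shift moves both ends of the log ratio)
        assert np.argsort(-res.contributions)[0] in (0, 5)
        assert res.contributions.max() > 0.4
        assert res.among_variance_fraction > 0.5

    def test_permuted_labels_collapse_among_variance(self):
        rng = np.random.default_rng(1)
        fa, labels = two_species_one_informative_fa(rng)
        base = cap_ordination(fa, labels).among_variance_fraction
        permuted = []
        for _ in range(20):
            permuted.append(
                cap_ordination(fa, rng.permutation(labels)).among_variance_fraction
            )
        assert np.mean(permuted) < base / 4

    def test_sample_duplication_invariance(self):
        rng = np.random.default_rng(2)
        fa, labels = two_species_one_informative_fa(rng)
        a = cap_ordination(fa, labels).contributions
        b = cap_ordination(np.vstack([fa, fa]), np.concatenate([labels, labels])).contributions
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_eigenvalues_nonincreasing_and_axis_cap(self):
        rng = np.random.default_rng(3)
        x = closure_mat(rng.random((30, 8)) + 0.1)
        labels = np.repeat(["a", "b", "c"], 10)
        res = cap_ordination(x, labels)
        assert res.eigenvalues.shape[0] <= 2
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)

    def test_few_samples_warns_rank_deficiency(self):
        rng = np.random.default_rng(4)
        x = closure_mat(rng.random((2 * 2 + 2 * 2, 5)) + 0.1)
        labels = np.repeat(["a", "b", "c", "d"], 2)
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            cap_ordination(x, labels)


class TestConditionNumber:
    def test_orthonormal_rows_give_exactly_one(self):
        assert condition_number(np.eye(3)) == 1.0
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(4, 4)))
        assert condition_number(q[:3]) == pytest.approx(1.0)

    def test_identical_subcompositions_blow_up(self):
        fa = np.array(
            [[0.4, 0.4, 0.1, 0.1], [0.4, 0.4, 0.12, 0.08],
             [0.2, 0.2, 0.25, 0.35], [0.2, 0.2, 0.3, 0.3]]
        )
        labels = np.array(["a", "a", "b", "b"])
        # species means share the (fa1, fa2) subcomposition exactly
        c = prey_condition_number(fa, labels, ["f1", "f2", "f3", "f4"], ["f1", "f2"])
        assert c > 1e6

    def test_duplicated_collinear_column_increases_condition(self):
        """Appending a perfectly collinear column that pushes the column
        count past the row count makes the matrix rank-deficient, so the
        condition number strictly increases (to infinity)."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = closure_mat(rng.random((3, 2)) + 0.1)
            base = condition_number(m)
            with pytest.warns(UserWarning, match="rank-deficient"):
                dup = condition_number(np.hstack([m, m[:, [0]]]))
            assert np.isfinite(base) and dup == np.inf

    def test_species_mean_matrix_recloses_subset(self):
        fa = np.array([[0.1, 0.2, 0.3, 0.4]] * 2 + [[0.4, 0.3, 0.2, 0.1]] * 2)
        labels = np.array(["a", "a", "b", "b"])
        m = species_mean_matrix(fa, labels, [0, 1])
        np.testing.assert_allclose(m.sum(axis=1), 1.0)
        np.testing.assert_allclose(m[0], [1 / 3, 2 / 3])


def make_dataset(fa, labels, fa_names):
    return dataset_from_arrays(
        species=list(dict.fromkeys(labels)),
        fa_names=fa_names,
        prey_fa=fa,
        prey_fa_species=labels,
        predator_fa=fa[:1],
    )


class TestSelectFas:
    def test_no_constraints_selects_all_in_contribution_order(self):
        rng = np.random.default_rng(6)
        fa, labels = two_species_one_informative_fa(rng)
        ds = make_dataset(fa, labels, [f"f{i}" for i in range(6)])
        rep = select_fas(ds, cum_var_target=1.0, cond_cap=np.inf)
        assert rep.selected == rep.order
        assert np.all(np.diff(rep.contributions) <= 1e-12)
        assert np.all(np.diff(rep.cumulative_variance) >= -1e-12)

    def test_variance_target_truncates(self):
        rng = np.random.default_rng(7)
        fa, labels = two_species_one_informative_fa(rng)
        ds = make_dataset(fa, labels, [f"f{i}" for i in range(6)])
        rep = select_fas(ds, cum_var_target=0.6, cond_cap=np.inf)
        assert len(rep.selected) < 6
        k = len(rep.selected)
        assert rep.cumulative_variance[k - 1] >= 0.6

    def test_cond_cap_fallback_returns_best_two(self):
        rng = np.random.default_rng(8)
        fa, labels = two_species_one_informative_fa(rng)
        ds = make_dataset(fa, labels, [f"f{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="best-2"):
            rep = select_fas(ds, cum_var_target=0.95, cond_cap=1.0 + 1e-9)
        assert rep.fallback
        assert rep.selected == rep.order[:2]

    def test_trajectory_deterministic(self):
        rng = np.random.default_rng(9)
        fa, labels = two_species_one_informative_fa(rng)
        ds = make_dataset(fa, labels, [f"f{i}" for i in range(6)])
        a = select_fas(ds)
        b = select_fas(ds)
        assert a.order == b.order
        np.testing.assert_array_equal(a.condition_numbers, b.condition_numbers)
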