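import numpy as np
import pytest

from hospeval.indicator_system import comprehensive_weights
from hospeval.weighting import (
    EntropyState,
    PairwiseMatrix,
    ahp_weights,
    assemble_weights,
    entropy_pipeline_weights,
    entropy_weights,
    geometric_mean_weights,
)

from conftest import make_random_hierarchy


def consistent_matrix(w):
    w = np.asarray(w, dtype=float)
    return np.outer(w, 1.0 / w)


def eig_oracle(a):
    """Independent principal-eigenvector oracle via dense eigensolver."""
    vals, vecs = np.linalg.eig(a)
    i = np.argmax(vals.real)
    v = np.abs(vecs[:, i].real)
    return v / v.sum(), float(vals[i].real)


class TestPairwiseMatrix:
    def test_rejects_non_reciprocal(self):
        a = np.array([[1.0, 2.0], [0.4, 1.0]])
        with pytest.raises(ValueError, match="reciprocal"):
            PairwiseMatrix(values=a)

    def test_rejects_non_positive(self):
        a = np.array([[1.0, -2.0], [-0.5, 1.0]])
        with pytest.raises(ValueError, match="positive"):
            PairwiseMatrix(values=a)

    def test_rejects_bad_diagonal(self):
        a = np.array([[2.0, 1.0], [1.0, 0.5]])
        with pytest.raises(ValueError):
            PairwiseMatrix(values=a)

    def test_csv_round_trip(self, tmp_path):
        p = PairwiseMatrix(values=consistent_matrix([0.3, 0.7]), labels=("a", "b"))
        path = tmp_path / "pm.csv"
        p.to_csv(path)
        again = PairwiseMatrix.from_csv(path)
        np.testing.assert_allclose(again.values, p.values)
        assert again.labels == ("a", "b")


class TestAhpWeights:
    def test_recovers_level1_weights_from_consistent_matrix(self):
        w = np.array([0.2, 0.15, 0.45, 0.2])
        res = ahp_weights(consistent_matrix(w))
        np.testing.assert_allclose(res.weights, w, atol=1e-8)
        assert res.consistency_ratio == pytest.approx(0.0, abs=1e-8)
        assert res.consistent

    def test_identity_judgments_uniform(self):
        res = ahp_weights(np.ones((3, 3)))
        np.testing.assert_allclose(res.weights, np.full(3, 1 / 3), atol=1e-10)
        assert res.consistency_ratio == pytest.approx(0.0, abs=1e-10)

    def test_3x3_matches_dense_eigensolver_oracle(self):
        a = np.array([[1, 2, 4], [1 / 2, 1, 3], [1 / 4, 1 / 3, 1]], dtype=float)
        res = ahp_weights(a)
        w_oracle, lmax_oracle = eig_oracle(a)
        np.testing.assert_allclose(res.weights, w_oracle, atol=1e-8)
        assert res.lambda_max == pytest.approx(lmax_oracle, abs=1e-8)
        cr_oracle = ((lmax_oracle - 3) / 2) / 0.58
        assert res.consistency_ratio == pytest.approx(cr_oracle, abs=1e-8)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(25):
            k = int(rng.integers(3, 8))
            w = rng.dirichlet(np.ones(k))
            a = consistent_matrix(w) * np.exp(rng.normal(0, 0.1, (k, k)))
            a = np.triu(a, 1)
            a = a + a.T + np.eye(k)
            a[np.tril_indices(k, -1)] = 1.0 / a.T[np.tril_indices(k, -1)]
            res = ahp_weights(a)
            w_oracle, _ = eig_oracle(a)
            np.testing.assert_allclose(res.weights, w_oracle, atol=1e-7)

    def test_scale_invariance(self):
        w = np.array([1.0, 2.0, 3.0])
        res1 = ahp_weights(consistent_matrix(w))
        res2 = ahp_weights(consistent_matrix(w * 17.3))
        np.testing.assert_allclose(res1.weights, res2.weights, atol=1e-10)

    def test_inconsistent_matrix_flagged_not_raised(self):
        a = np.array([[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]], dtype=float)
        res = ahp_weights(a)
        assert res.consistency_ratio > 0.1
        assert not res.consistent

    def test_cr_zero_for_order_two(self):
        res = ahp_weights(np.array([[1.0, 5.0], [0.2, 1.0]]))
        assert res.consistency_ratio == 0.0

    def test_order_outside_range_rejected(self):
        with pytest.raises(ValueError, match="order"):
            ahp_weights(np.ones((16, 16)))

    def test_geometric_mean_agrees_on_consistent(self):
        w = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(
            geometric_mean_weights(consistent_matrix(w)), w, atol=1e-12
        )


def entropy_oracle(x):
    """Direct brute-force reimplementation of the entropy weight formula."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    h = np.empty(k)
    for j in range(k):
        s = x[:, j].sum()
        if s == 0:
            h[j] = 1.0
            continue
        acc = 0.0
        for i in range(n):
            p = x[i, j] / s
            if p > 0:
                acc += p * np.log(p)
        h[j] = min(max(-acc / np.log(n), 0.0), 1.0)
    d = 1.0 - h
    if d.sum() <= 0:
        return h, np.full(k, 1.0 / k)
    return h, d / d.sum()


class TestEntropyWeights:
    def test_hand_example(self):
        x = np.array([[1.0, 0.5], [0.0, 0.5]])
        state = entropy_weights(x)
        np.testing.assert_allclose(state.entropy, [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(state.weights, [1.0, 0.0], atol=1e-12)

    def test_single_indicator_weight_one(self, rng):
        state = entropy_weights(rng.uniform(0, 1, size=(6, 1)))
        np.testing.assert_allclose(state.weights, [1.0])

    def test_all_constant_uniform_fallback(self):
        state = entropy_weights(np.full((5, 3), 0.4))
        assert state.uniform_fallback
        np.testing.assert_allclose(state.weights, np.full(3, 1 / 3))

    def test_zero_column_degenerate(self):
        x = np.array([[0.0, 1.0], [0.0, 0.2]])
        state = entropy_weights(x)
        assert state.degenerate_columns == (0,)
        assert state.entropy[0] == 1.0
        assert state.weights[0] == 0.0

    def test_brute_force_oracle_100_random(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            k = int(rng.integers(1, 8))
            x = rng.uniform(0, 1, size=(n, k))
            x[rng.uniform(size=x.shape) < 0.15] = 0.0
            state = entropy_weights(x)
            h_oracle, w_oracle = entropy_oracle(x)
            np.testing.assert_allclose(state.entropy, h_oracle, atol=1e-12)
            np.testing.assert_allclose(state.weights, w_oracle, atol=1e-12)

    def test_hospital_permutation_invariance(self, rng):
        x = rng.uniform(0, 1, size=(9, 5))
        perm = rng.permutation(9)
        np.testing.assert_allclose(
            entropy_weights(x).weights, entropy_weights(x[perm]).weights, atol=1e-12
        )

    def test_duplicate_column_splits_weight(self, rng):
        x = rng.uniform(0.1, 1, size=(8, 3))
        base = entropy_weights(x).weights
        dup = entropy_weights(np.column_stack([x, x[:, 0]])).weights
        assert dup[0] == pytest.approx(dup[3], abs=1e-12)
        # relative weights of the untouched columns are preserved
        assert dup[1] / dup[2] == pytest.approx(base[1] / base[2], abs=1e-9)

    def test_weights_sum_to_one(self, rng):
        state = entropy_weights(rng.uniform(0, 1, size=(7, 6)))
        assert state.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            entropy_weights(np.array([[1.0, -0.1], [0.5, 0.2]]))


class TestAssembleWeights:
    def test_uniform_inputs_on_packaged_shape(self, hierarchy):
        l1 = np.full(4, 0.25)
        l2 = {
            n.name: np.full(len(n.children), 1.0 / len(n.children))
            for n in hierarchy.level1
        }
        l3 = {
            (n1.name, n2.name): np.full(len(n2.leaves), 1.0 / len(n2.leaves))
            for n1 in hierarchy.level1
            for n2 in n1.children
        }
        ws = assemble_weights(hierarchy, l1, l2, l3)
        for n1 in hierarchy.level1:
            for n2 in n1.children:
                for leaf in n2.leaves:
                    expect = 0.25 / len(n1.children) / len(n2.leaves)
                    assert ws[leaf.id] == pytest.approx(expect, abs=1e-15)
        assert ws.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_printed_weights_reproduce_patient_satisfaction(self, hierarchy):
        l1 = np.array([n.weight for n in hierarchy.level1])
        l2 = {n.name: np.array([c.weight for c in n.children]) for n in hierarchy.level1}
        l3 = {
            (n1.name, n2.name): np.array([leaf.weight for leaf in n2.leaves])
            for n1 in hierarchy.level1
            for n2 in n1.children
        }
        ws = assemble_weights(hierarchy, l1, l2, l3)
        assert ws["patient_satisfaction"] == pytest.approx(0.07, abs=1e-12)
        np.testing.assert_allclose(
            ws.weights, comprehensive_weights(hierarchy).weights, atol=1e-15
        )

    def test_random_full_precision_sums_to_one(self, rng):
        for _ in range(10):
            h = make_random_hierarchy(rng)
            l1 = np.array([n.weight for n in h.level1])
            l2 = {n.name: np.array([c.weight for c in n.children]) for n in h.level1}
            l3 = {
                (n1.name, n2.name): np.array([leaf.weight for leaf in n2.leaves])
                for n1 in h.level1
                for n2 in n1.children
            }
            ws = assemble_weights(h, l1, l2, l3)
            assert ws.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch_names_branch(self, hierarchy):
        l1 = np.full(4, 0.25)
        l2 = {n.name: np.full(len(n.children), 1.0 / len(n.children))
              for n in hierarchy.level1}
        l2["Input"] = np.array([1.0])  # wrong length
        with pytest.raises(ValueError, match="Input"):
            assemble_weights(hierarchy, l1, l2, {})

    def test_missing_branch_named(self, hierarchy):
        l1 = np.full(4, 0.25)
        with pytest.raises(ValueError, match="missing level-2"):
            assemble_weights(hierarchy, l1, {}, {})

    def test_entropy_pipeline_weights(self, hierarchy, norm_default):
        ws = entropy_pipeline_weights(hierarchy, norm_default)
        assert len(ws) == 41
        assert ws.weights.sum() == pytest.approx(1.0, abs=1e-9)
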