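import numpy as np
import pytest

from lmdlink.exceptions import ContractError
from lmdlink.io_data import make_table
from lmdlink.linear_features import (
    build_association_matrix,
    epsilon_fill,
    extract_linear_features,
    read_features_tsv,
    select_rank,
    svd_decompose,
    write_features_tsv,
)


class TestBuildAssociationMatrix:
    def test_diagonal_pairs(self):
        table = make_table("lncRNA", "disease", [("L1", "D1"), ("L2", "D2")])
        m = build_association_matrix(table)
        assert np.array_equal(m.values, np.eye(2))

    def test_single_row(self):
        table = make_table("lncRNA", "disease", [("L1", "D1"), ("L1", "D2")])
        m = build_association_matrix(table)
        assert m.values.shape == (1, 2)
        assert np.array_equal(m.values, [[1, 1]])

    def test_entry_sum_equals_pair_count(self):
        table = make_table(
            "lncRNA", "disease", [("L1", "D1"), ("L2", "D1"), ("L2", "D2")]
        )
        m = build_association_matrix(table)
        assert m.values.sum() == len(table)
        assert m.entry("L2", "D2") == 1 and m.entry("L1", "D2") == 0

    def test_empty_table_rejected(self):
        table = make_table("lncRNA", "disease", [])
        with pytest.raises(ContractError):
            build_association_matrix(table)


class TestEpsilonFill:
    def test_zeros_become_epsilon_ones_unchanged(self):
        table = make_table("lncRNA", "disease", [("L1", "D1"), ("L2", "D2")])
        m = build_association_matrix(table)
        filled = epsilon_fill(m, 1e-6)
        assert np.array_equal(filled, [[1, 1e-6], [1e-6, 1]])
        assert np.array_equal(m.values, np.eye(2))  # original not mutated

    def test_all_ones_unchanged(self):
        table = make_table("lncRNA", "disease", [("L1", "D1"), ("L1", "D2")])
        filled = epsilon_fill(build_association_matrix(table), 1e-6)
        assert np.array_equal(filled, [[1, 1]])

    def test_custom_epsilon(self):
        table = make_table("lncRNA", "disease", [("L1", "D1"), ("L2", "D1")])
        m = build_association_matrix(table)
        filled = epsilon_fill(m, 0.5)
        assert filled[0, 0] == 1 and filled.min() == 0.5 or filled.min() == 1

    @pytest.mark.parametrize("eps", [0.0, -1e-6])
    def test_nonpositive_epsilon_rejected(self, eps):
        table = make_table("lncRNA", "disease", [("L1", "D1"), ("L2", "D2")])
        with pytest.raises(ContractError):
            epsilon_fill(build_association_matrix(table), eps)


class TestSvdDecompose:
    def test_identity_spectrum(self):
        fact = svd_decompose(np.eye(2))
        assert np.allclose(fact.sigma, [1, 1])

    def test_diagonal_spectrum_sorted(self):
        fact = svd_decompose(np.array([[3.0, 0.0], [0.0, 4.0]]))
        assert np.allclose(fact.sigma, [4, 3])

    def test_reconstruction_and_orthonormality(self, rng):
        A = rng.normal(size=(5, 4))
        fact = svd_decompose(A)
        recon = fact.U @ np.diag(fact.sigma) @ fact.Vt
        assert np.linalg.norm(recon - A) < 1e-8 * np.linalg.norm(A)
        assert np.allclose(fact.U.T @ fact.U, np.eye(4), atol=1e-8)
        assert np.allclose(fact.Vt @ fact.Vt.T, np.eye(4), atol=1e-8)

    def test_sign_convention_is_deterministic(self, rng):
        A = rng.normal(size=(6, 5))
        f1, f2 = svd_decompose(A), svd_decompose(A.copy())
        assert np.array_equal(f1.U, f2.U) and np.array_equal(f1.Vt, f2.Vt)
        dominant = np.argmax(np.abs(f1.U), axis=0)
        assert (f1.U[dominant, np.arange(f1.U.shape[1])] > 0).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ContractError):
            svd_decompose(np.array([[1.0, np.inf]]))


class TestSelectRank:
    def test_huge_gap_detected(self):
        assert select_rank(np.array([5.0, 3.0, 1e-13, 1e-14]), gap_floor=1e3) == 2

    def test_no_qualifying_gap_keeps_full_spectrum(self):
        assert select_rank(np.array([2.0, 1.0]), gap_floor=1e3) == 2

    def test_exact_zero_tail_wins(self):
        assert select_rank(np.array([2.0, 1.0, 0.0, 0.0]), gap_floor=1e3) == 2

    def test_fixed_method_clamps(self):
        sigma = np.array([3.0, 2.0, 1.0])
        assert select_rank(sigma, method="fixed", fixed_k=2) == 2
        assert select_rank(sigma, method="fixed", fixed_k=10) == 3

    def test_fixed_without_k_rejected(self):
        with pytest.raises(ContractError):
            select_rank(np.array([1.0]), method="fixed")

    def test_increasing_sigma_rejected(self):
        with pytest.raises(ContractError):
            select_rank(np.array([1.0, 2.0]))

    def test_planted_rank_recovered(self, rng):
        # low-rank product plus tiny noise: the spectral gap sits at the rank
        for r in (2, 3, 5):
            m, n = 40, 30
            U, _ = np.linalg.qr(rng.normal(size=(m, r)))
            V, _ = np.linalg.qr(rng.normal(size=(n, r)))
            s = rng.uniform(0.5, 5.0, size=r)
            A = U @ np.diag(s) @ V.T + 1e-8 * rng.normal(size=(m, n))
            sigma = svd_decompose(A).sigma
            assert select_rank(sigma) == r


class TestExtractLinearFeatures:
    def test_identity_gives_unit_basis_rows(self):
        fact = svd_decompose(np.eye(2))
        feats = extract_linear_features(fact, 2, ("L1", "L2"), ("D1", "D2"))
        for v in feats.lnc_vectors.values():
            assert np.isclose(np.abs(v).max(), 1) and np.isclose(
                np.linalg.norm(v), 1
            )

    def test_k_one_vectors(self, rng):
        A = rng.random((3, 3)) + 0.1
        fact = svd_decompose(A)
        feats = extract_linear_features(
            fact, 1, ("a", "b", "c"), ("x", "y", "z")
        )
        assert all(v.shape == (1,) for v in feats.lnc_vectors.values())
        assert all(v.shape == (1,) for v in feats.dis_vectors.values())

    def test_full_rank_factor_product_identity(self, rng):
        # dot(LL_i * sigma[:k], LD_j) reproduces the filled matrix at full rank
        A = rng.random((5, 4))
        fact = svd_decompose(A)
        rows = tuple(f"L{i}" for i in range(5))
        cols = tuple(f"D{j}" for j in range(4))
        feats = extract_linear_features(fact, 4, rows, cols)
        for i, lname in enumerate(rows):
            for j, dname in enumerate(cols):
                approx = np.dot(
                    feats.lnc_vectors[lname] * fact.sigma[:4],
                    feats.dis_vectors[dname],
                )
                assert abs(approx - A[i, j]) < 1e-10

    def test_k_out_of_range_rejected(self, rng):
        fact = svd_decompose(rng.random((3, 3)))
        with pytest.raises(ContractError):
            extract_linear_features(fact, 4, ("a", "b", "c"), ("x", "y", "z"))

    def test_eckart_young_truncation_error(self, rng):
        A = rng.normal(size=(8, 6))
        fact = svd_decompose(A)
        k = 3
        recon = fact.U[:, :k] @ np.diag(fact.sigma[:k]) @ fact.Vt[:k, :]
        err = np.linalg.norm(A - recon)
        expected = np.sqrt(np.sum(fact.sigma[k:] ** 2))
        assert abs(err - expected) < 1e-8


def test_features_tsv_round_trip(tmp_path, rng):
    vectors = {f"L{i}": rng.normal(size=4) for i in range(5)}
    path = tmp_path / "feat.tsv"
    write_features_tsv(vectors, path)
    back = read_features_tsv(path)
    assert set(back) == set(vectors)
    for name in vectors:
        assert np.array_equal(back[name], vectors[name])
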