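"""Eigen selection against the shuffle null, varimax, and sector assembly."""

import numpy as np
import pytest

from bifanr.bifactor import (
    Sector,
    SectorSet,
    assign_sites,
    eigendecompose,
    merge_sectors,
    null_eigenvalues,
    select_factors,
    varimax_criterion,
    varimax_rotate,
)
from conftest import alignment_from_strings
from oracles import varimax_grid_best


class TestEigendecompose:
    def test_identity_matrix(self):
        vals, vecs = eigendecompose(np.eye(3))
        np.testing.assert_allclose(vals, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(vecs @ vecs.T, np.eye(3), atol=1e-12)

    def test_rank_one_matrix(self):
        v = np.array([1.0, 1.0, 0.0, 0.0])
        vals, _ = eigendecompose(np.outer(v, v))
        np.testing.assert_allclose(vals, [2.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(5, 5))
        W = (A + A.T) / 2
        vals, vecs = eigendecompose(W)
        np.testing.assert_allclose(vecs @ np.diag(vals) @ vecs.T, W, atol=1e-10)
        assert (np.diff(vals) <= 1e-12).all()

    def test_sign_convention(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 6))
        _, vecs = eigendecompose((A + A.T) / 2)
        for k in range(6):
            assert vecs[np.argmax(np.abs(vecs[:, k])), k] > 0

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError):
            eigendecompose(np.arange(9.0).reshape(3, 3))


class TestNullEigenvalues:
    def test_size_is_shuffles_times_sites(self):
        rng = np.random.default_rng(0)
        al = alignment_from_strings(
            ["".join("ACDE"[i] for i in rng.integers(0, 4, 6)) for _ in range(8)]
        )
        E = null_eigenvalues(al, kept=[0, 2, 3, 5], n_shuffles=7, seed=1)
        assert E.shape == (7 * 4,)

    def test_identical_rows_shuffle_invariant(self):
        # all rows equal: any within-column permutation reproduces the data,
        # so the null spectrum equals the real spectrum every time
        from bifanr.covariance import coupling_matrix
        from bifanr.msa_io import frequencies

        al = alignment_from_strings(["ACDE"] * 5)
        E = null_eigenvalues(al, kept=[0, 1, 2, 3], n_shuffles=3, seed=0)
        real = np.sort(np.linalg.eigvalsh(coupling_matrix(frequencies(al)).W))
        np.testing.assert_allclose(np.sort(E[:4]), real, atol=1e-10)
        np.testing.assert_allclose(np.sort(E[4:8]), real, atol=1e-10)

    def test_fast_path_matches_naive_recomputation(self):
        rng = np.random.default_rng(12)
        al = alignment_from_strings(
            ["".join("ACDEFGH"[i] for i in rng.integers(0, 7, 6)) for _ in range(10)]
        )
        kept = [0, 1, 3, 4]
        E_fast = null_eigenvalues(al, kept, n_shuffles=4, seed=99, reuse_weights=True)
        E_slow = null_eigenvalues(al, kept, n_shuffles=4, seed=99, reuse_weights=False)
        np.testing.assert_allclose(E_fast, E_slow, atol=1e-10)

    def test_seed_reproducibility_and_dispersion(self):
        rng = np.random.default_rng(7)
        al = alignment_from_strings(
            ["".join("ACDE"[i] for i in rng.integers(0, 4, 8)) for _ in range(40)]
        )
        kept = list(range(8))
        E1 = null_eigenvalues(al, kept, n_shuffles=10, seed=5)
        E2 = null_eigenvalues(al, kept, n_shuffles=10, seed=5)
        E3 = null_eigenvalues(al, kept, n_shuffles=10, seed=6)
        np.testing.assert_array_equal(E1, E2)
        assert not np.array_equal(E1, E3)
        # max(E) is a stable scale across seeds even though E differs
        assert abs(E1.max() - E3.max()) < 0.5 * E1.max()


class TestSelectFactors:
    def test_direct_counts(self):
        E = np.concatenate([np.full(200, 5.0), np.full(800, 1.0)])
        # lam1 above all of E, lam2 below 200 of them
        t, N = select_factors(np.array([10.0, 2.0]), E, threshold=100)
        assert (t, list(N)) == (1, [0, 200])

    def test_all_inside_bulk_gives_zero(self):
        E = np.linspace(0, 10, 1000)
        t, _ = select_factors(np.array([5.0, 4.0]), E, threshold=100)
        assert t == 0

    def test_strictly_greater_comparison(self):
        E = np.full(150, 2.0)
        # lam == 2.0: no null eigenvalue is STRICTLY bigger -> retained
        t, N = select_factors(np.array([2.0]), E, threshold=100)
        assert N[0] == 0 and t == 1

    def test_N_nondecreasing(self):
        rng = np.random.default_rng(2)
        E = rng.normal(size=500)
        vals = np.sort(rng.normal(size=8))[::-1]
        _, N = select_factors(vals, E, threshold=100)
        assert (np.diff(N) >= 0).all()


class TestVarimax:
    def test_block_indicator_already_simple(self):
        B = np.zeros((8, 2))
        B[:4, 0] = 0.5
        B[4:, 1] = 0.5
        rot, R = varimax_rotate(B)
        np.testing.assert_allclose(np.abs(R), np.eye(2), atol=1e-6)
        assert varimax_criterion(rot) == pytest.approx(varimax_criterion(B), abs=1e-10)

    def test_two_factor_matches_grid_search(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            Q, _ = np.linalg.qr(rng.normal(size=(15, 2)))
            B, _ = varimax_rotate(Q, tol=1e-12)
            assert varimax_criterion(B) == pytest.approx(varimax_grid_best(Q), abs=1e-4)

    def test_rotation_orthogonal_and_communalities_preserved(self):
        rng = np.random.default_rng(22)
        Q, _ = np.linalg.qr(rng.normal(size=(20, 4)))
        B, R = varimax_rotate(Q)
        np.testing.assert_allclose(R.T @ R, np.eye(4), atol=1e-8)
        np.testing.assert_allclose((B ** 2).sum(axis=1), (Q ** 2).sum(axis=1), atol=1e-8)

    def test_criterion_never_decreases(self):
        rng = np.random.default_rng(23)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        B, _ = varimax_rotate(Q, tol=1e-10)
        assert varimax_criterion(B) >= varimax_criterion(Q) - 1e-12

    def test_single_factor_identity(self):
        v = np.array([[0.5], [-0.9], [0.1]])
        B, R = varimax_rotate(v)
        np.testing.assert_allclose(B, -v)  # sign fixed: largest-|entry| positive
        assert R.shape == (1, 1)

    def test_agrees_with_statsmodels_rotation(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        rng = np.random.default_rng(24)
        Q, _ = np.linalg.qr(rng.normal(size=(25, 3)))
        B, _ = varimax_rotate(Q, tol=1e-12, max_iter=5000)
        L, _ = rotate_factors(Q, "varimax")
        assert varimax_criterion(B) == pytest.approx(varimax_criterion(L), abs=1e-6)


class TestAssignSites:
    def test_two_strong_loadings_form_sector(self):
        load = np.full((10, 1), 0.05)
        load[0, 0], load[1, 0] = 0.9, 0.85
        ss = assign_sites(load)  # defaults r0=0.8, p0=0.1, p1=0.4
        # w = mean(0.9, 0.85, 0.05, 0.05, 0.05) = 0.38; r>=0.8 & p>0.1 only for the two
        assert ss.site_lists == [(0, 1)]
        assert ss.sectors[0].sign == "+"

    def test_equal_loadings_all_selected_not_truncated(self):
        load = np.full((6, 1), 0.5)
        ss = assign_sites(load)
        assert ss.site_lists == [(0, 1, 2, 3, 4, 5)]  # r(i)=1 for all, p>=p1 too

    def test_negative_block_recovered_by_negative_pass(self):
        load = np.full((10, 1), -0.02)
        load[3, 0] = load[7, 0] = -0.8
        ss = assign_sites(load)
        assert ss.site_lists == [(3, 7)]
        assert ss.sectors[0].sign == "-"

    def test_p1_overrides_ratio_rule(self):
        # a site failing the ratio rule but with p >= p1 still enters
        load = np.array([[0.9], [0.9], [0.9], [0.9], [0.45], [0.0], [0.0], [0.0]])
        ss = assign_sites(load, r0=0.99, p0=0.1, p1=0.4)
        assert 4 in ss.site_lists[0]

    def test_one_site_candidates_discarded(self):
        load = np.full((10, 1), 0.01)
        load[0, 0] = 0.9
        ss = assign_sites(load)
        assert ss.site_lists == []


class TestMergeSectors:
    W = None

    def setup_method(self):
        # site 4 couples strongly to {2,3}; sites 1 and 5 weakly
        W = np.zeros((6, 6))
        pairs = {(1, 2): 0.2, (1, 3): 0.2, (4, 2): 0.9, (4, 3): 0.9, (5, 2): 0.1, (5, 3): 0.1}
        for (i, j), v in pairs.items():
            W[i, j] = W[j, i] = v
        self.W = W

    def test_hand_traced_greedy_merge(self):
        A = Sector(sites=(1, 2, 3), source_factor=0, sign="+")
        B = Sector(sites=(2, 3, 4, 5), source_factor=1, sign="+")
        out = merge_sectors(SectorSet(sectors=[A, B]), self.W)
        assert [s.sites for s in out] == [(2, 3, 4)]
        assert out.sectors[0].merged_from == (A, B)

    def test_disjoint_unchanged(self):
        A = Sector(sites=(0, 1), source_factor=0, sign="+")
        B = Sector(sites=(2, 3), source_factor=1, sign="+")
        out = merge_sectors(SectorSet(sectors=[A, B]), self.W)
        assert [s.sites for s in out] == [(0, 1), (2, 3)]

    def test_identical_sectors_collapse(self):
        A = Sector(sites=(1, 2, 3), source_factor=0, sign="+")
        B = Sector(sites=(1, 2, 3), source_factor=1, sign="-")
        out = merge_sectors(SectorSet(sectors=[A, B]), self.W)
        assert [s.sites for s in out] == [(1, 2, 3)]

    def test_subset_merge_is_vacuous(self):
        A = Sector(sites=(2, 3), source_factor=0, sign="+")
        B = Sector(sites=(1, 2, 3, 4), source_factor=1, sign="+")
        out = merge_sectors(SectorSet(sectors=[A, B]), self.W)
        assert [s.sites for s in out] == [(2, 3)]

    def test_merged_size_is_min_of_parents_randomized(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = 12
            A = (rng.uniform(size=(n, n)) + rng.uniform(size=(n, n)).T) / 2
            np.fill_diagonal(A, 0.0)
            sa = rng.choice(n, size=rng.integers(2, 7), replace=False)
            sb = rng.choice(n, size=rng.integers(2, 7), replace=False)
            if not set(sa) & set(sb):
                continue
            S1 = Sector(sites=tuple(sorted(int(i) for i in sa)), source_factor=0, sign="+")
            S2 = Sector(sites=tuple(sorted(int(i) for i in sb)), source_factor=1, sign="+")
            out = merge_sectors(SectorSet(sectors=[S1, S2]), A)
            assert len(out) == 1
            assert out.sectors[0].size == min(S1.size, S2.size)

    def test_merging_is_idempotent_and_disjoint(self):
        rng = np.random.default_rng(32)
        n = 15
        A = (rng.uniform(size=(n, n)) + rng.uniform(size=(n, n)).T) / 2
        np.fill_diagonal(A, 0.0)
        sectors = [
            Sector(sites=(0, 1, 2, 3), source_factor=0, sign="+"),
            Sector(sites=(2, 3, 4, 5, 6), source_factor=1, sign="+"),
            Sector(sites=(6, 7, 8), source_factor=2, sign="+"),
            Sector(sites=(10, 11), source_factor=3, sign="+"),
        ]
        out = merge_sectors(SectorSet(sectors=sectors), A)
        seen: set = set()
        for s in out:
            assert not (seen & set(s.sites))
            seen |= set(s.sites)
        again = merge_sectors(out, A)
        assert [s.sites for s in again] == [s.sites for s in out]
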