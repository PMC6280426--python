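import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coexsurv as cs
from coexsurv.screen import (
    DegenerateInputError,
    ScreenParams,
    bh_adjust,
    distance_correlation,
    pairwise_distance_matrix,
    permutation_p,
    screen_genes,
    spearman,
)


def brute_force_dcor(x, y):
    """Independent O(n^2) double-centering oracle, written with plain loops."""
    n = len(x)
    Dx = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    Dy = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(D):
        row = [sum(r) / n for r in D]
        col = [sum(D[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[D[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A, B = center(Dx), center(Dy)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    vx = sum(a * a for r in A for a in r) / n**2
    vy = sum(b * b for r in B for b in r) / n**2
    return (max(dcov2, 0.0) / (vx * vy) ** 0.5) ** 0.5


def brute_force_dcor_paper(x, y):
    """Independent mean-scaling oracle for the covariance-style variant."""
    n = len(x)
    Dx = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    Dy = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]
    mx = sum(Dx[i][j] for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    my = sum(Dy[i][j] for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    s = sum((Dx[i][j] / mx) * (Dy[i][j] / my) for i in range(n) for j in range(n) if i != j)
    return s / (n * (n - 1)) - 1.0


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3], [2, 1, 3], 0.5),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_equals_pearson_on_average_ranks(self):
        rng = np.random.default_rng(0)
        from scipy.stats import rankdata

        for _ in range(50):
            n = rng.integers(5, 60)
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            expected = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y), abs=1e-12)
        assert spearman(x, y**3) == pytest.approx(spearman(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPairwiseDistanceMatrix:
    def test_direct_definition(self):
        D = pairwise_distance_matrix([0.0, 1.0, 3.0, 0.0])
        np.testing.assert_array_equal(D[0], [0, 1, 3, 0])
        np.testing.assert_array_equal(np.diag(D), 0)

    def test_symmetry_and_zero_diagonal(self):
        x = np.random.default_rng(3).normal(size=15)
        D = pairwise_distance_matrix(x)
        np.testing.assert_array_equal(D, D.T)
        assert (D >= 0).all()

    def test_constant_gives_zero_matrix(self):
        assert pairwise_distance_matrix([2.0] * 5).sum() == 0


class TestDistanceCorrelation:
    def test_frozen_example_both_variants(self):
        x, y = [1.0, 2, 3, 5], [2.0, 1, 4, 4]
        assert distance_correlation(x, y) == pytest.approx(0.841347234225754, abs=1e-12)
        assert distance_correlation(x, y, "paper") == pytest.approx(
            0.048951048951048953, abs=1e-12
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(4, 31))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert distance_correlation(x, y) == pytest.approx(
                brute_force_dcor(x, y), abs=1e-10
            )
            assert distance_correlation(x, y, "paper") == pytest.approx(
                brute_force_dcor_paper(x, y), abs=1e-10
            )

    def test_affine_dependence_is_one(self):
        x = np.random.default_rng(9).normal(size=25)
        for b in (2.0, -0.5):
            assert distance_correlation(x, 3.0 + b * x) == pytest.approx(1.0, abs=1e-12)

    def test_self_correlation_is_one(self):
        x = np.arange(8.0)
        assert distance_correlation(x, x) == pytest.approx(1.0)

    def test_constant_input_errors(self):
        x = np.arange(6.0)
        with pytest.raises(DegenerateInputError):
            distance_correlation(x, np.ones(6))
        with pytest.raises(DegenerateInputError):
            distance_correlation(x, np.ones(6), "paper")

    def test_variants_rank_identically_when_grand_means_equal(self):
        # vectors constructed so every distance matrix has the same
        # off-diagonal grand mean: scaling then cancels and both variants
        # are monotone in the same raw covariance
        rng = np.random.default_rng(21)
        x = rng.normal(size=30)
        x = (x - x.mean()) / np.abs(x[:, None] - x[None, :]).sum()
        ys = []
        for _ in range(6):
            y = rng.normal(size=30)
            ys.append((y - y.mean()) / np.abs(y[:, None] - y[None, :]).sum())
        paper_vals = [distance_correlation(x, y, "paper") for y in ys]
        # all scaled matrices share mean 1; ranking by the paper statistic
        # must match ranking by plain distance covariance
        Dx = np.abs(x[:, None] - x[None, :])
        mx = Dx.sum() / (30 * 29)
        raw = []
        for y in ys:
            Dy = np.abs(y[:, None] - y[None, :])
            my = Dy.sum() / (30 * 29)
            off = ~np.eye(30, dtype=bool)
            raw.append((Dx[off] / mx * (Dy[off] / my)).mean())
        assert np.argsort(paper_vals).tolist() == np.argsort(raw).tolist()


class TestPermutationP:
    def test_boundary_when_observed_dominates(self):
        x = np.arange(20.0)
        p = permutation_p(spearman, x, x + 0.01 * np.random.default_rng(0).normal(size=20), 999, 3)
        assert p == pytest.approx(1 / 1000)

    def test_identical_vectors_reach_floor(self):
        # long enough that no random permutation reproduces |rho| = 1
        x = np.random.default_rng(8).permutation(20.0 + np.arange(20))
        p = permutation_p(spearman, x, x, 99, 11)
        assert p == pytest.approx(1 / 100)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        args = (spearman, x, y, 199, 42)
        assert permutation_p(*args) == permutation_p(*args)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        p = permutation_p(lambda a, b: distance_correlation(a, b), x, y, 49, 0, two_sided=False)
        assert 0 < p <= 1


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p_and_order_preserved(self, pvals):
        q = bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-15).all()
        assert (q <= 1.0 + 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


@pytest.fixture(scope="module")
def planted():
    cfg = cs.ExprSimConfig(n_genes=300, n_cells=150, module_size=10, seed=5)
    return cs.simulate_expression(cfg)


class TestScreenGenes:

    def test_anchor_never_in_output(self, planted):
        mat, _ = planted
        recs = screen_genes(mat, ScreenParams(anchor="EGFR", n_permutations=99, seed=1))
        assert all(r.gene_id != "EGFR" for r in recs)

    def test_intersection_flag_consistency(self, planted):
        mat, _ = planted
        recs = screen_genes(mat, ScreenParams(anchor="EGFR", n_permutations=99, seed=1))
        for r in recs:
            assert r.in_intersection == (r.pass_rho and r.pass_dcor)
            assert -1 <= r.rho <= 1
            assert 0 <= r.dcor <= 1
            assert r.rho_q >= r.rho_p - 1e-15
            assert r.dcor_q >= r.dcor_p - 1e-15

    def test_deterministic_under_seed(self, planted):
        mat, _ = planted
        params = ScreenParams(anchor="EGFR", n_permutations=49, seed=9)
        a = screen_genes(mat, params)
        b = screen_genes(mat, params)
        assert a == b

    def test_sorted_by_dcor_then_rho_then_id(self, planted):
        mat, _ = planted
        recs = screen_genes(mat, ScreenParams(anchor="EGFR", n_permutations=49, seed=9))
        keys = [(-r.dcor, -abs(r.rho), r.gene_id) for r in recs]
        assert keys == sorted(keys)

    def test_missing_anchor_errors(self, planted):
        mat, _ = planted
        with pytest.raises(KeyError):
            screen_genes(mat, ScreenParams(anchor="ABSENT", n_permutations=9))

    def test_batched_p_matches_per_pair_permutation(self):
        """The shared-permutation batched screen must agree in distribution
        with the literal shuffle-y permutation test; check observed stats
        exactly and p-values on a tiny matrix with matching seeds."""
        cfg = cs.ExprSimConfig(
            n_genes=6, n_cells=40, module_size=2, zero_inflation=0.0, seed=3
        )
        mat, _ = cs.simulate_expression(cfg)
        recs = screen_genes(mat, ScreenParams(anchor="EGFR", n_permutations=199, seed=12))
        vals = np.log2(1 + mat.values)
        anchor = vals[0]
        by_id = {g: vals[i] for i, g in enumerate(mat.gene_ids)}
        for r in recs:
            assert r.rho == pytest.approx(spearman(anchor, by_id[r.gene_id]), abs=1e-6)
            assert r.dcor == pytest.approx(
                distance_correlation(anchor, by_id[r.gene_id]), abs=1e-5
            )
            exact = permutation_p(spearman, by_id[r.gene_id], anchor, 199, 12)
            # same B, independent draws: agreement within binomial noise
            assert abs(r.rho_p - exact) < 0.2
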