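import itertools

import numpy as np
import pytest

from conftest import make_table
from ystrkit.popdist import (
    DistanceMatrix,
    amova_rst,
    classical_mds,
    delta_matrix,
    hierarchical_clusters,
    pairwise_delta,
    pi_matrices,
    rst_matrix,
)


def amova_bruteforce(X, labels):
    """Independent one-level variance decomposition by literal enumeration."""
    X = [list(map(int, row)) for row in X]
    N = len(X)
    pops = list(dict.fromkeys(labels))
    d = [
        [sum((a - b) ** 2 for a, b in zip(X[i], X[j])) for j in range(N)]
        for i in range(N)
    ]
    ssd_total = sum(d[i][j] for i in range(N) for j in range(N)) / (2 * N)
    ssd_within = 0.0
    sizes = []
    for p in pops:
        idx = [i for i, l in enumerate(labels) if l == p]
        sizes.append(len(idx))
        ssd_within += sum(d[i][j] for i in idx for j in idx) / (2 * len(idx))
    P = len(pops)
    sigma_w = ssd_within / (N - P)
    ms_among = (ssd_total - ssd_within) / (P - 1)
    n_bar = (N - sum(s * s for s in sizes) / N) / (P - 1)
    sigma_a = (ms_among - sigma_w) / n_bar
    tot = sigma_a + sigma_w
    return sigma_a, sigma_w, (0.0 if tot == 0 else sigma_a / tot)


class TestPairwiseDelta:
    def test_identity_is_zero(self):
        assert pairwise_delta([14, 12], [14, 12]) == 0.0

    def test_single_locus_two_steps(self):
        assert pairwise_delta([14], [16]) == 4.0
        assert pairwise_delta([14], [16], metric="step_count") == 2.0

    def test_two_locus_hand_computation(self):
        assert pairwise_delta([13, 30], [14, 28]) == 5.0

    def test_microvariants_rounded_before_differencing(self):
        assert pairwise_delta([17.2], [17.0]) == 0.0

    def test_missing_fails(self):
        with pytest.raises(ValueError):
            pairwise_delta([np.nan], [14.0])


class TestPiMatrices:
    def test_two_fixed_single_locus_populations(self):
        t = make_table(
            [[10.0], [10.0], [12.0], [12.0]],
            ["DYS19"],
            populations=["A", "A", "B", "B"],
        )
        pim = pi_matrices(t)
        assert pim.PiX.tolist() == [0.0, 0.0]
        assert pim.PiXY[0, 1] == 4.0
        assert pim.corrected[0, 1] == 4.0
        assert pim.corrected[0, 0] == 0.0  # self-distance exactly zero

    def test_duplicated_population_corrected_distance_is_minus_pix_over_n(self, rng):
        # when pop B copies pop A row for row, the n cross pairs (i, copy-of-i)
        # have distance 0, so PiXY = PiX (n-1)/n and corrected = -PiX/n exactly
        X = rng.integers(10, 15, size=(6, 3))
        rows = [list(map(float, r)) for r in X] * 2
        t = make_table(rows, ["L1", "L2", "L3"], populations=["A"] * 6 + ["B"] * 6)
        pim = pi_matrices(t)
        assert pim.corrected[0, 1] == pytest.approx(-pim.PiX[0] / 6, abs=1e-12)

    def test_corrected_distance_can_be_negative(self):
        # high within-population diversity, no between-population divergence
        t = make_table(
            [[10.0], [14.0], [10.0], [14.0]],
            ["DYS19"],
            populations=["A", "A", "B", "B"],
        )
        pim = pi_matrices(t)
        assert pim.corrected[0, 1] == pytest.approx(-8.0)

    def test_population_below_two_rows_fails(self):
        t = make_table([[10.0], [11.0], [12.0]], ["DYS19"], populations=["A", "A", "B"])
        with pytest.raises(ValueError, match="B"):
            pi_matrices(t)


class TestAmovaRst:
    def test_fixed_difference_gives_rst_one(self):
        t = make_table(
            [[10.0], [10.0], [12.0], [12.0]],
            ["DYS19"],
            populations=["A", "A", "B", "B"],
        )
        assert amova_rst(t).rst == pytest.approx(1.0)

    def test_duplicated_population_gives_exact_null_rst(self, rng):
        # copying pop A into pop B makes SSD_among exactly 0, so
        # sigma_a = -sigma_w/n and Rst = -1/(n-1): the textbook negative
        # bias of the unbiased estimator at its null
        X = rng.integers(10, 16, size=(8, 4))
        rows = [list(map(float, r)) for r in X] * 2
        t = make_table(rows, ["L1", "L2", "L3", "L4"], populations=["A"] * 8 + ["B"] * 8)
        res = amova_rst(t, permutations=99, seed=3)
        assert res.rst == pytest.approx(-1.0 / 7.0, abs=1e-12)
        assert res.p_value > 0.5

    def test_toy_equals_bruteforce_oracle(self):
        rows = [[10.0], [10.0], [11.0], [13.0], [14.0], [13.0]]
        labels = ["A", "A", "A", "B", "B", "B"]
        t = make_table(rows, ["DYS19"], populations=labels)
        res = amova_rst(t)
        sa, sw, rst = amova_bruteforce([r[:1] for r in rows], labels)
        assert res.sigma_among == pytest.approx(sa)
        assert res.sigma_within == pytest.approx(sw)
        assert res.rst == pytest.approx(rst)

    def test_random_instances_match_bruteforce(self, rng):
        for _ in range(50):
            N = int(rng.integers(4, 13))
            P = int(rng.integers(2, 4))
            labels = [f"p{rng.integers(P)}" for _ in range(N)]
            while len(set(labels)) < 2:
                labels = [f"p{rng.integers(P)}" for _ in range(N)]
            X = rng.integers(8, 16, size=(N, 3))
            t = make_table([list(map(float, r)) for r in X], ["L1", "L2", "L3"], populations=labels)
            res = amova_rst(t)
            _, _, rst = amova_bruteforce(X, labels)
            assert res.rst == pytest.approx(rst, abs=1e-10)

    def test_translation_invariance(self, rng):
        X = rng.integers(10, 16, size=(10, 3))
        labels = ["A"] * 5 + ["B"] * 5
        t1 = make_table([list(map(float, r)) for r in X], ["L1", "L2", "L3"], populations=labels)
        t2 = make_table(
            [list(map(float, r + np.array([5, 0, 7]))) for r in X],
            ["L1", "L2", "L3"],
            populations=labels,
        )
        assert amova_rst(t1).rst == pytest.approx(amova_rst(t2).rst, abs=1e-12)

    def test_permutations_require_seed(self):
        t = make_table([[10.0], [11.0], [12.0], [13.0]], ["DYS19"], populations=["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="seed"):
            amova_rst(t, permutations=10)


class TestRstMatrix:
    def test_symmetric_zero_diagonal_and_null_pairs(self, rng):
        X = rng.integers(10, 16, size=(6, 3))
        rows = [list(map(float, r)) for r in X] * 3
        t = make_table(
            rows, ["L1", "L2", "L3"], populations=["A"] * 6 + ["B"] * 6 + ["C"] * 6
        )
        dm = rst_matrix(t)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        # duplicated pops of size 6: exact null estimate -1/(6-1) off-diagonal
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, -0.2, atol=1e-12)

    def test_negative_estimates_retained(self, rng):
        # sampling noise around Rst=0 regularly yields negative estimates
        seen_negative = False
        for seed in range(12):
            r = np.random.default_rng(seed)
            X = r.integers(10, 18, size=(12, 2)).astype(float)
            t = make_table(
                [list(row) for row in X], ["L1", "L2"], populations=["A", "B"] * 6
            )
            if rst_matrix(t).values[0, 1] < 0:
                seen_negative = True
        assert seen_negative

    def test_csv_round_trip(self, tmp_path, rng):
        labels = ("A", "B", "C")
        v = np.array([[0, 1.5, 2.0], [1.5, 0, 0.7], [2.0, 0.7, 0]])
        dm = DistanceMatrix(labels, v)
        path = tmp_path / "d.csv"
        dm.to_csv(path)
        dm2 = DistanceMatrix.from_csv(path)
        assert dm2.labels == labels
        assert np.allclose(dm2.values, v)


class TestClassicalMds:
    def test_equilateral_triangle_exact(self):
        D = DistanceMatrix(("a", "b", "c"), np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        res = classical_mds(D, dims=2)
        C = res.coordinates
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(C[i] - C[j]) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(C.mean(axis=0), 0, atol=1e-9)

    def test_points_on_a_line_recovered_up_to_reflection(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = DistanceMatrix(("a", "b", "c"), np.abs(pts[:, None] - pts[None, :]))
        res = classical_mds(D, dims=1)
        x = res.coordinates[:, 0]
        recovered = np.abs(x[:, None] - x[None, :])
        assert np.allclose(recovered, D.values, atol=1e-9)

    def test_random_euclidean_configuration_reproduced(self, rng):
        pts = rng.normal(size=(5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = classical_mds(DistanceMatrix(tuple("abcde"), D), dims=2)
        C = res.coordinates
        rec = np.linalg.norm(C[:, None] - C[None, :], axis=2)
        assert np.allclose(rec, D, atol=1e-9)
        assert res.eigenvalues[0] >= res.eigenvalues[1]

    def test_excess_dims_padded_with_zeros(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = DistanceMatrix(("a", "b", "c"), np.abs(pts[:, None] - pts[None, :]))
        res = classical_mds(D, dims=3)
        assert np.allclose(res.coordinates[:, 1:], 0.0)


class TestHierarchicalClusters:
    def ultrametric(self):
        # hand-agglomerable UPGMA toy: a,b merge at 2; c joins at 6; d at 8
        D = np.array(
            [
                [0, 2, 6, 8],
                [2, 0, 6, 8],
                [6, 6, 0, 8],
                [8, 8, 8, 0],
            ],
            dtype=float,
        )
        return DistanceMatrix(("a", "b", "c", "d"), D)

    def test_upgma_merge_heights_match_hand_averages(self):
        res = hierarchical_clusters(self.ultrametric(), linkage="upgma", k=2)
        assert np.allclose(res.linkage_matrix[:, 2], [2.0, 6.0, 8.0])

    def test_two_blobs_split_perfectly(self):
        labels = ("a1", "a2", "a3", "b1", "b2")
        D = np.ones((5, 5)) * 10
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4)]:
            D[i, j] = D[j, i] = 1.0
        np.fill_diagonal(D, 0)
        res = hierarchical_clusters(DistanceMatrix(labels, D), linkage="upgma", k=2)
        a = {res.assignments[l] for l in labels[:3]}
        b = {res.assignments[l] for l in labels[3:]}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_k_equal_n_gives_singletons_and_out_of_range_fails(self):
        dm = self.ultrametric()
        res = hierarchical_clusters(dm, k=4)
        assert len(set(res.assignments.values())) == 4
        with pytest.raises(ValueError):
            hierarchical_clusters(dm, k=5)

    def test_newick_export_contains_all_labels(self):
        res = hierarchical_clusters(self.ultrametric(), linkage="upgma", k=2)
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for label in "abcd":
            assert label in nwk
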