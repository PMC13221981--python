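import numpy as np
import pytest

import _oracles as oracle
from adsbench.data_model import DistanceMatrix
from adsbench.metrics import (cell_mix_score, davies_bouldin, evaluate_all,
                              f_score, f_score_scaled, gpca_delta,
                              kbet_rejection_rate, kl_dist, knn_proportion,
                              min_distance, pearson_distance_matrix)
from conftest import make_ann, make_matrix


def dist(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(values, [f"s{i}" for i in range(values.shape[0])])


def random_labeled_dataset(rng, n, n_genes=6, n_clusters=2):
    """Random data plus labels where every cluster has >=2 members."""
    while True:
        labels = rng.integers(0, n_clusters, size=n)
        counts = np.bincount(labels, minlength=n_clusters)
        if np.all(counts >= 2):
            break
    X = make_matrix(rng.normal(size=(n_genes, n)), kind="logcounts")
    return X, np.array([f"c{l}" for l in labels])


def separated_clusters(rng, n_per=10, n_genes=30, sep=5.0):
    """Two correlation-separated clusters: distinct base profiles + noise."""
    a = rng.normal(size=n_genes)
    b = rng.normal(size=n_genes)
    cols = [a + rng.normal(0, 1 / max(sep, 1e-6), n_genes) for _ in range(n_per)]
    cols += [b + rng.normal(0, 1 / max(sep, 1e-6), n_genes) for _ in range(n_per)]
    X = make_matrix(np.column_stack(cols), kind="logcounts")
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return X, labels


class TestPearsonDistance:
    def test_duplicate_and_negated_columns(self):
        x = np.array([1.0, 2.0, 4.0])
        X = make_matrix(np.column_stack([x, x, -x]), kind="logcounts")
        D = pearson_distance_matrix(X)
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        # negation flips correlation around the mean: rho(x, -x) = -1
        assert D.values[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        X = make_matrix(rng.normal(size=(7, 3)), kind="logcounts")
        D = pearson_distance_matrix(X)
        np.testing.assert_allclose(D.values,
                                   oracle.pearson_distance_oracle(X.values),
                                   atol=1e-12)

    def test_constant_column_raises(self):
        X = make_matrix(np.column_stack([[1, 1, 1], [1, 2, 3]]),
                        kind="logcounts")
        with pytest.raises(ValueError, match="constant sample"):
            pearson_distance_matrix(X)


class TestFScore:
    def test_hand_example_aabb(self):
        # within: D(0,1)=0.2, D(2,3)=0.4; four between pairs of 1.0
        D = np.ones((4, 4))
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.2
        D[2, 3] = D[3, 2] = 0.4
        f = f_score(dist(D), ["A", "A", "B", "B"])
        assert f == pytest.approx(4.0 / 0.6)

    def test_constant_distances_give_pair_count_ratio(self):
        D = 0.7 * (1 - np.eye(4))
        assert f_score(dist(D), list("AABB")) == pytest.approx(2.0)

    def test_single_cluster_raises(self):
        D = 1 - np.eye(4)
        with pytest.raises(ValueError, match=">=2 clusters"):
            f_score(dist(D), ["A"] * 4)

    def test_scaled_equals_plain_when_quantiles_equal(self):
        D = 0.5 * (1 - np.eye(6))
        labels = list("AAABBB")
        assert (f_score_scaled(dist(D), labels, 0.5)
                == pytest.approx(f_score(dist(D), labels)))

    def test_scaled_matches_term_by_term_oracle(self, rng):
        X, labels = random_labeled_dataset(rng, 6)
        D = pearson_distance_matrix(X)
        for p in (0.25, 0.5, 0.9):
            assert (f_score_scaled(D, labels, p)
                    == pytest.approx(
                        oracle.f_score_scaled_oracle(D.values, labels, p),
                        abs=1e-12))


class TestDaviesBouldin:
    def test_tight_separated_clusters_near_zero(self, rng):
        X, labels = separated_clusters(rng, sep=100.0)
        assert davies_bouldin(X, labels) < 0.05

    def test_overlapping_clusters_large(self, rng):
        X, _ = random_labeled_dataset(rng, 12, n_genes=20)
        labels = np.array(["A", "B"] * 6)   # labels carry no structure
        tight, _ = separated_clusters(rng, n_per=6, sep=100.0)
        assert (davies_bouldin(X, labels)
                > 10 * davies_bouldin(tight, ["A"] * 6 + ["B"] * 6))

    def test_matches_oracle(self, rng):
        for _ in range(5):
            X, labels = random_labeled_dataset(rng, 7, n_genes=9)
            assert (davies_bouldin(X, labels)
                    == pytest.approx(
                        oracle.davies_bouldin_oracle(X.values, labels),
                        abs=1e-10))


class TestKnnProportion:
    def test_well_separated_is_one(self, rng):
        X, labels = separated_clusters(rng, n_per=8, sep=50.0)
        D = pearson_distance_matrix(X)
        assert knn_proportion(D, labels, k=5) == 1.0

    def test_interleaved_line_is_zero(self):
        # 1-D points 0, 10, 1, 11 labeled A A B B: nearest neighbours cross
        x = np.array([0.0, 10.0, 1.0, 11.0])
        D = np.abs(x[:, None] - x[None, :])
        assert knn_proportion(dist(D), list("AABB"), k=1) == 0.0

    def test_random_labels_near_half(self, rng):
        n = 300
        X = make_matrix(rng.normal(size=(20, n)), kind="logcounts")
        labels = np.array(["A", "B"] * (n // 2))
        D = pearson_distance_matrix(X)
        # same-label neighbour probability is (n/2 - 1)/(n - 1)
        expect = (n / 2 - 1) / (n - 1)
        assert knn_proportion(D, labels, k=10) == pytest.approx(expect, abs=0.05)

    def test_auto_k_is_mean_cluster_size(self, rng):
        X, _ = random_labeled_dataset(rng, 9)
        labels = ["A"] * 4 + ["B"] * 5   # mean cluster size 4.5 -> k=5
        D = pearson_distance_matrix(X)
        assert (knn_proportion(D, labels, k="auto")
                == knn_proportion(D, labels, k=5))

    def test_k_bounds(self, rng):
        X, labels = random_labeled_dataset(rng, 5)
        D = pearson_distance_matrix(X)
        with pytest.raises(ValueError):
            knn_proportion(D, labels, k=5)
        with pytest.raises(ValueError):
            knn_proportion(D, labels, k=0)


class TestMinDistance:
    def test_three_cluster_hand_example(self):
        # minima between the three cluster pairs: 0.1, 0.2, 0.3
        D = np.full((6, 6), 2.0)
        np.fill_diagonal(D, 0.0)
        labels = list("AABBCC")
        D[0, 2] = D[2, 0] = 0.1   # A-B
        D[1, 4] = D[4, 1] = 0.2   # A-C
        D[3, 5] = D[5, 3] = 0.3   # B-C
        assert min_distance(dist(D), labels) == pytest.approx(0.2)

    def test_shared_duplicate_gives_zero(self):
        D = 1 - np.eye(4)
        D[1, 2] = D[2, 1] = 0.0
        assert min_distance(dist(D), list("AABB")) == 0.0

    def test_two_clusters_reduces_to_single_min(self, rng):
        X, labels = random_labeled_dataset(rng, 8)
        D = pearson_distance_matrix(X)
        a = np.flatnonzero(labels == labels[0])
        b = np.flatnonzero(labels != labels[0])
        assert (min_distance(D, labels)
                == pytest.approx(D.values[np.ix_(a, b)].min()))


class TestKLDist:
    def test_identical_distance_multisets_near_zero(self, rng):
        base = rng.normal(size=(10, 5))
        X = make_matrix(np.column_stack([base, base]), kind="logcounts")
        labels = ["A"] * 5 + ["B"] * 5
        # identical within-group geometry => identical distance densities
        assert kl_dist(pearson_distance_matrix(X), labels) < 1e-6

    def test_disjoint_supports_large(self):
        # group A distances all ~0.05, group B all ~1.5
        n = 8
        D = np.zeros((n, n))
        A, B = range(4), range(4, 8)
        for i in A:
            for j in A:
                if i != j:
                    D[i, j] = 0.05
        for i in B:
            for j in B:
                if i != j:
                    D[i, j] = 1.5
        for i in A:
            for j in B:
                D[i, j] = D[j, i] = 0.8
        labels = ["A"] * 4 + ["B"] * 4
        assert kl_dist(dist(D), labels) > 5.0

    def test_symmetric_under_label_swap(self, rng):
        X, labels = random_labeled_dataset(rng, 10)
        D = pearson_distance_matrix(X)
        swapped = np.where(labels == "c0", "c1", "c0")
        assert kl_dist(D, labels) == pytest.approx(kl_dist(D, swapped))

    def test_tiny_group_raises(self, rng):
        X, _ = random_labeled_dataset(rng, 6)
        D = pearson_distance_matrix(X)
        with pytest.raises(ValueError, match="<2 members"):
            kl_dist(D, ["A"] + ["B"] * 5)


class TestGpcaDelta:
    def test_batch_aligned_with_dominant_direction(self, rng):
        direction = rng.normal(size=40)
        X = 0.05 * rng.normal(size=(40, 30))
        X[:, 15:] += 3.0 * direction[:, None]
        batch = ["b1"] * 15 + ["b2"] * 15
        d = gpca_delta(make_matrix(X, kind="logcounts"), batch)
        assert d > 0.95

    def test_random_batches_far_below_structured(self, rng):
        X = rng.normal(size=(40, 30))
        random_batch = np.array(["b1", "b2"] * 15)
        d_random = gpca_delta(make_matrix(X, kind="logcounts"), random_batch)
        direction = rng.normal(size=40)
        Xs = X + 3.0 * np.outer(direction, np.r_[np.zeros(15), np.ones(15)])
        d_struct = gpca_delta(make_matrix(Xs, kind="logcounts"),
                              ["b1"] * 15 + ["b2"] * 15)
        # unstructured labels give an intermediate ratio (a random direction
        # captures an average eigenvalue); structure drives it to ~1
        assert d_struct > 0.95
        assert d_random < 0.7
        assert d_struct > d_random + 0.25

    def test_invariant_to_gene_shifts(self, rng):
        X = rng.normal(size=(20, 16))
        batch = ["b1", "b2"] * 8
        d1 = gpca_delta(make_matrix(X, kind="logcounts"), batch)
        d2 = gpca_delta(make_matrix(X + rng.normal(size=(20, 1)),
                                    kind="logcounts"), batch)
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_single_batch_raises(self, rng):
        X = make_matrix(rng.normal(size=(5, 6)), kind="logcounts")
        with pytest.raises(ValueError, match=">=2 batches"):
            gpca_delta(X, ["b"] * 6)


class TestKbet:
    def test_alpha_zero_never_rejects(self, rng):
        X, labels = random_labeled_dataset(rng, 30, n_genes=10)
        D = pearson_distance_matrix(X)
        assert kbet_rejection_rate(D, labels, k=5, alpha=0.0,
                                   n_neighborhoods=30, seed=0) == 0.0

    def test_fully_separated_rejects_everywhere(self, rng):
        X, labels = separated_clusters(rng, n_per=30, sep=100.0)
        D = pearson_distance_matrix(X)
        rate = kbet_rejection_rate(D, labels, k=10, alpha=0.05,
                                   n_neighborhoods=60, seed=0)
        assert rate == 1.0

    def test_k_range_validated(self, rng):
        X, labels = random_labeled_dataset(rng, 10)
        D = pearson_distance_matrix(X)
        with pytest.raises(ValueError, match="k must satisfy"):
            kbet_rejection_rate(D, labels, k=1)
        with pytest.raises(ValueError, match="k must satisfy"):
            kbet_rejection_rate(D, labels, k=10)


class TestCellMixScore:
    def test_pure_neighbourhoods_contribute_one(self, rng):
        X, labels = separated_clusters(rng, n_per=10, sep=100.0)
        D = pearson_distance_matrix(X)
        # k smaller than cluster size: every neighbourhood is single-batch
        assert cell_mix_score(D, labels, k=5) == 1.0

    def test_random_split_near_half(self, rng):
        n = 200
        X = make_matrix(rng.normal(size=(25, n)), kind="logcounts")
        labels = rng.permutation(np.array(["A", "B"] * (n // 2)))
        D = pearson_distance_matrix(X)
        score = cell_mix_score(D, labels, k=30)
        assert 0.35 < score < 0.65

    def test_moderately_separated_low_score(self, rng):
        X, labels = separated_clusters(rng, n_per=30, sep=2.0)
        D = pearson_distance_matrix(X)
        # k spans both batches, forcing cross-batch comparisons
        assert cell_mix_score(D, labels, k=45) < 0.1


class TestPermutationInvariance:
    @pytest.mark.parametrize("name", ["f", "f_scaled", "db", "knn", "mindist",
                                      "kldist", "gpca", "cms"])
    def test_metric_invariant_to_sample_permutation(self, rng, name):
        from adsbench.metrics import _compute_metric
        X, labels = random_labeled_dataset(rng, 12, n_genes=15)
        D = pearson_distance_matrix(X)
        perm = rng.permutation(12)
        Xp = make_matrix(X.values[:, perm], kind="logcounts")
        Dp = pearson_distance_matrix(Xp)
        params = {"k": 3} if name in ("knn", "cms") else {}
        v1 = _compute_metric(name, X, D, labels, params)
        v2 = _compute_metric(name, Xp, Dp, labels[perm], params)
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_kbet_all_anchor_invariance(self, rng):
        X, labels = random_labeled_dataset(rng, 16, n_genes=15)
        D = pearson_distance_matrix(X)
        perm = rng.permutation(16)
        Xp = make_matrix(X.values[:, perm], kind="logcounts")
        Dp = pearson_distance_matrix(Xp)
        r1 = kbet_rejection_rate(D, labels, k=4, n_neighborhoods=16, seed=0)
        r2 = kbet_rejection_rate(Dp, labels[perm], k=4, n_neighborhoods=16,
                                 seed=0)
        assert r1 == r2


class TestMonotoneSeparationResponse:
    def test_metrics_track_planted_separation(self):
        seps = [0.5, 2.0, 8.0]
        med = {m: [] for m in ("f", "db", "knn", "mindist", "gpca", "kbet")}
        for sep in seps:
            vals = {m: [] for m in med}
            for rep in range(8):
                rng = np.random.default_rng(1000 + rep)
                X, labels = separated_clusters(rng, n_per=8, sep=sep)
                D = pearson_distance_matrix(X)
                vals["f"].append(f_score(D, labels))
                vals["db"].append(davies_bouldin(X, labels))
                vals["knn"].append(knn_proportion(D, labels, k=4))
                vals["mindist"].append(min_distance(D, labels))
                vals["gpca"].append(gpca_delta(X, labels))
                vals["kbet"].append(kbet_rejection_rate(
                    D, labels, k=6, n_neighborhoods=16, seed=rep))
            for m in med:
                med[m].append(np.median(vals[m]))
        for m in ("f", "knn", "mindist", "gpca", "kbet"):
            assert np.all(np.diff(med[m]) >= 0), m
        assert np.all(np.diff(med["db"]) <= 0)


class TestEvaluateAll:
    def test_ratio_is_batch_over_bio(self, rng):
        X, _ = random_labeled_dataset(rng, 12, n_genes=15)
        ann = make_ann(["b1", "b2"] * 6, ["g1"] * 6 + ["g2"] * 6)
        res = evaluate_all(X, ann, ("f",))
        by_signal = {r.signal: r.value for r in res}
        assert set(by_signal) == {"batch", "bio", "ratio"}
        assert by_signal["ratio"] == pytest.approx(
            by_signal["batch"] / by_signal["bio"])

    def test_kbet_reports_batch_only(self, rng):
        X, _ = random_labeled_dataset(rng, 30, n_genes=15)
        ann = make_ann(["b1", "b2"] * 15, ["g1"] * 15 + ["g2"] * 15)
        res = evaluate_all(X, ann, ("kbet", "cms"))
        assert all(r.signal == "batch" for r in res)

    def test_empty_metric_set(self, rng):
        X, _ = random_labeled_dataset(rng, 8)
        ann = make_ann(["b1", "b2"] * 4, ["g1"] * 4 + ["g2"] * 4)
        assert evaluate_all(X, ann, ()) == []

    def test_unknown_metric_raises(self, rng):
        X, _ = random_labeled_dataset(rng, 8)
        ann = make_ann(["b1", "b2"] * 4, ["g1"] * 4 + ["g2"] * 4)
        with pytest.raises(KeyError, match="unknown metric"):
            evaluate_all(X, ann, ("silhouette",))
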