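import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from endopheno.discovery import (
    AffinityMatrix,
    Partition,
    adjusted_rand_index,
    compare_algorithms,
    internal_index,
    rbf_affinity,
    select_stable_geneset,
    spectral_cluster,
    vote_k,
)
from endopheno.preprocess import ExpressionMatrix

from conftest import two_blob_matrix


def ari_pair_counting_oracle(a, b):
    """Brute-force ARI over all sample pairs (comembership counts)."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    n11 = n10 = n01 = n00 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n10 += sa and not sb
        n01 += sb and not sa
        n00 += not sa and not sb
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return 1.0 if den == 0 else num / den


class TestRBFAffinity:
    def test_identical_samples_have_unit_affinity(self):
        df = pd.DataFrame(np.ones((4, 3)), index=list("abcd"), columns=["s1", "s2", "s3"])
        a = rbf_affinity(ExpressionMatrix(df, "arcsinh"), sigma=1.0)
        assert np.allclose(a.values, 1.0)

    def test_closed_form_value(self):
        # two samples at squared distance 2, sigma 0.5 -> exp(-1)
        df = pd.DataFrame([[0.0, 1.0], [0.0, 1.0]], index=["g1", "g2"], columns=["x", "y"])
        a = rbf_affinity(ExpressionMatrix(df, "arcsinh"), sigma=0.5)
        assert a.values[0, 1] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_affinity_decreases_with_distance(self):
        df = pd.DataFrame([[0.0, 1.0, 5.0]], index=["g"], columns=["a", "b", "c"])
        a = rbf_affinity(ExpressionMatrix(df, "arcsinh"), sigma=1.0)
        assert a.values[0, 1] > a.values[0, 2]

    def test_symmetry_validation(self):
        with pytest.raises(ValueError):
            AffinityMatrix(values=np.array([[1.0, 0.2], [0.5, 1.0]]), sample_ids=["a", "b"], sigma=1.0)


class TestSpectralCluster:
    def test_two_separated_blobs_recovered_exactly(self):
        m, labels = two_blob_matrix()
        part = spectral_cluster(rbf_affinity(m, "auto"), 2, seed=0)
        assert adjusted_rand_index(part.as_array(), labels) == pytest.approx(1.0)

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(3, 8)), index=list("abc"), columns=[f"s{i}" for i in range(8)])
        part = spectral_cluster(rbf_affinity(ExpressionMatrix(df, "arcsinh"), "auto"), 8, seed=0)
        assert sorted(part.labels) == list(range(1, 9))

    def test_planted_three_subgroups_recovered(self, top300, cohort):
        part = spectral_cluster(rbf_affinity(top300, "auto"), 3, seed=0)
        ari = adjusted_rand_index(part.as_array(), cohort["truth"].labels.to_numpy())
        assert ari >= 0.9

    def test_block_diagonal_affinity_recovers_blocks_exactly(self):
        blocks = [4, 5, 6]
        n = sum(blocks)
        a = np.zeros((n, n))
        start = 0
        truth = np.empty(n, dtype=int)
        for bi, b in enumerate(blocks):
            a[start : start + b, start : start + b] = 0.9
            truth[start : start + b] = bi
            start += b
        np.fill_diagonal(a, 1.0)
        aff = AffinityMatrix(values=a, sample_ids=[f"s{i}" for i in range(n)], sigma=1.0)
        part = spectral_cluster(aff, 3, seed=0)
        assert adjusted_rand_index(part.as_array(), truth) == pytest.approx(1.0)

    def test_deterministic_under_seed(self, top300):
        a = rbf_affinity(top300, "auto")
        p1 = spectral_cluster(a, 3, seed=5)
        p2 = spectral_cluster(a, 3, seed=5)
        assert p1.labels.equals(p2.labels)


class TestAdjustedRandIndex:
    def test_identical_and_relabelled_partitions_score_one(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        b = np.array([3, 3, 1, 1, 2, 2])
        assert adjusted_rand_index(a, a) == pytest.approx(1.0)
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_worked_six_item_example_matches_oracle(self):
        a = np.array([1, 1, 1, 2, 2, 2])  # {abc | def}
        b = np.array([1, 1, 2, 2, 3, 3])  # {ab | cd | ef}
        oracle = ari_pair_counting_oracle(a, b)
        assert adjusted_rand_index(a, b) == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(0.242424242424, abs=1e-9)

    def test_mismatched_sample_sets_rejected(self):
        p = Partition.from_labels([1, 2], ["a", "b"])
        q = Partition.from_labels([1, 2], ["a", "c"])
        with pytest.raises(ValueError):
            adjusted_rand_index(p, q)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=3), min_size=3, max_size=9),
        st.lists(st.integers(min_value=0, max_value=3), min_size=3, max_size=9),
    )
    def test_matches_pair_counting_oracle_and_is_symmetric(self, la, lb):
        n = min(len(la), len(lb))
        a, b = np.array(la[:n]), np.array(lb[:n])
        ours = adjusted_rand_index(a, b)
        assert ours == pytest.approx(ari_pair_counting_oracle(a, b), abs=1e-12)
        assert ours == pytest.approx(adjusted_rand_index(b, a), abs=1e-12)
        assert ours <= 1.0 + 1e-12

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 4, 30)
            assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)


class TestCompareAlgorithms:
    def test_identical_variations_are_perfectly_consistent(self, top300):
        variations = {"spectral": [{"sigma": "auto", "seed": 0}, {"sigma": "auto", "seed": 0}]}
        out = compare_algorithms(top300, 3, variations)
        assert out.loc["spectral", "mean_ari"] == pytest.approx(1.0)
        assert out.loc["spectral", "sd_ari"] == pytest.approx(0.0)

    def test_single_variation_rejected(self, top300):
        with pytest.raises(ValueError):
            compare_algorithms(top300, 3, {"kmeans": [{"seed": 0}]})

    def test_random_labels_have_near_zero_consistency(self):
        rng = np.random.default_rng(0)
        parts = [rng.integers(0, 3, 200) for _ in range(6)]
        aris = [
            adjusted_rand_index(parts[i], parts[j])
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        assert abs(np.mean(aris)) < 0.05

    def test_spectral_beats_kmeans_on_concentric_rings(self):
        # non-convex structure: Euclidean k-means must split each ring
        rng = np.random.default_rng(4)
        n = 80
        theta = rng.uniform(0, 2 * np.pi, n)
        r = np.concatenate([np.full(n // 2, 1.0), np.full(n // 2, 6.0)]) + rng.normal(0, 0.05, n)
        x = np.c_[r * np.cos(theta), r * np.sin(theta)] + 10
        df = pd.DataFrame(x.T, index=["g1", "g2"], columns=[f"s{i}" for i in range(n)])
        m = ExpressionMatrix(df, "arcsinh")
        out = compare_algorithms(
            m,
            2,
            {
                "spectral": [{"sigma": 2.0, "seed": s} for s in range(3)],
                "kmeans": [{"seed": s, "n_init": 1} for s in range(3)],
            },
        )
        truth = np.array([1] * (n // 2) + [2] * (n // 2))
        part = spectral_cluster(rbf_affinity(m, 2.0), 2, seed=0)
        assert adjusted_rand_index(part.as_array(), truth) == pytest.approx(1.0)
        assert out.loc["spectral", "mean_ari"] >= out.loc["kmeans", "mean_ari"]


class TestStability:
    def test_separated_clusters_are_maximally_stable(self, top300):
        res = select_stable_geneset(top300, [50, 300], 3, n_boot=10, seed=0)
        assert res.per_size[300]["mean"] >= 0.95

    def test_noise_matrix_is_less_stable_than_planted(self, top300):
        rng = np.random.default_rng(0)
        noise = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(3, 1, size=(300, top300.n_samples)),
                index=[f"n{i}" for i in range(300)],
                columns=top300.sample_ids,
            ),
            "arcsinh",
        )
        planted = select_stable_geneset(top300, [300], 3, n_boot=10, seed=1)
        null = select_stable_geneset(noise, [300], 3, n_boot=10, seed=1)
        assert planted.per_size[300]["mean"] - null.per_size[300]["mean"] >= 0.2

    def test_reproducible_and_rejects_tiny_bootstrap(self, top300):
        r1 = select_stable_geneset(top300, [100], 3, n_boot=5, seed=2)
        r2 = select_stable_geneset(top300, [100], 3, n_boot=5, seed=2)
        assert r1.per_size == r2.per_size
        with pytest.raises(ValueError):
            select_stable_geneset(top300, [100], 3, n_boot=1, seed=0)


class TestInternalIndexes:
    def test_far_separated_blobs_have_silhouette_near_one(self):
        m, labels = two_blob_matrix(sep=50.0, sd=0.01)
        p = Partition.from_labels(labels, m.sample_ids)
        assert internal_index(m, p, "silhouette") > 0.95

    def test_single_cluster_rejected(self):
        m, _ = two_blob_matrix()
        p = Partition.from_labels(np.ones(m.n_samples, dtype=int), m.sample_ids)
        with pytest.raises(ValueError):
            internal_index(m, p, "silhouette")

    def test_calinski_harabasz_matches_hand_computation(self):
        # 1-D six points: {0,1,2} and {10,11,12}; BSS=150, WSS=4 -> CH=150
        df = pd.DataFrame([[0.0, 1.0, 2.0, 10.0, 11.0, 12.0]], index=["g"], columns=list("abcdef"))
        m = ExpressionMatrix(df, "arcsinh")
        p = Partition.from_labels([1, 1, 1, 2, 2, 2], list("abcdef"))
        assert internal_index(m, p, "calinski_harabasz") == pytest.approx(150.0)

    def test_unknown_index_rejected(self):
        m, labels = two_blob_matrix()
        p = Partition.from_labels(labels, m.sample_ids)
        with pytest.raises(KeyError):
            internal_index(m, p, "no_such_index")


class TestVoteK:
    def test_planted_three_subgroups_win_the_vote(self, top300):
        res = vote_k(top300, [2, 3, 4, 5, 6, 7, 8], seed=0)
        assert res.majority_k == 3

    def test_single_index_vote_equals_its_argmax(self, top300):
        res = vote_k(top300, [2, 3, 4], indexes=["silhouette"], seed=0)
        ks = sorted(res.scores["silhouette"])
        best = max(ks, key=lambda k: res.scores["silhouette"][k])
        assert res.majority_k == best == res.votes["silhouette"]

    def test_tie_breaks_toward_smaller_k(self):
        from endopheno.discovery import KVoteResult

        # tally construction mirrors vote_k's resolution rule
        votes = {"i1": 3, "i2": 4, "i3": 3, "i4": 4}
        tally = {}
        for v in votes.values():
            tally[v] = tally.get(v, 0) + 1
        top = max(tally.values())
        assert min(k for k, c in tally.items() if c == top) == 3

    def test_vote_invariant_to_index_order(self, top300):
        a = vote_k(top300, [2, 3, 4], indexes=["silhouette", "dunn", "c_index"], seed=1)
        b = vote_k(top300, [2, 3, 4], indexes=["c_index", "silhouette", "dunn"], seed=1)
        assert a.majority_k == b.majority_k and a.votes == b.votes

    def test_empty_candidates_rejected(self, top300):
        with pytest.raises(ValueError):
            vote_k(top300, [], seed=0)
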