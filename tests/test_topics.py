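import numpy as np
import pandas as pd
import pytest

from forumscope import topics as tp


def block_docs(rng, n_docs, blocks, words_per_doc=40, prefix_size=25):
    """Documents drawn from disjoint vocabulary blocks (one per group)."""
    docs = {}
    per_group = n_docs // blocks
    for i in range(n_docs):
        b = min(i // per_group, blocks - 1)
        words = rng.integers(0, prefix_size, words_per_doc)
        docs[f"u{i:03d}"] = [f"g{b}_{w}" for w in words]
    return docs


class TestEmbedding:
    def test_identical_documents_identical_vectors(self):
        docs = {"a": ["x", "y", "x"], "b": ["x", "y", "x"], "c": ["z", "w", "q"]}
        vec = tp.embed_documents(docs, dim=2, seed=0)
        np.testing.assert_allclose(vec.loc["a"], vec.loc["b"], atol=1e-12)

    def test_disjoint_vocabulary_less_similar_than_identical(self):
        docs = {"a": ["x", "y"] * 5, "b": ["x", "y"] * 5, "c": ["z", "w"] * 5}
        vec = tp.embed_documents(docs, dim=2, seed=0)

        def cos(u, v):
            return float(vec.loc[u] @ vec.loc[v]) / (
                np.linalg.norm(vec.loc[u]) * np.linalg.norm(vec.loc[v])
            )

        assert cos("a", "c") < cos("a", "b") - 1e-6

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        docs = block_docs(rng, 20, 2)
        v1 = tp.embed_documents(docs, dim=5, seed=3)
        v2 = tp.embed_documents(docs, dim=5, seed=3)
        pd.testing.assert_frame_equal(v1, v2)

    def test_excessive_dim_reduced_with_warning(self):
        docs = {"a": ["x", "y"], "b": ["y", "z"], "c": ["z", "x"]}
        with pytest.warns(UserWarning, match="rank limit"):
            vec = tp.embed_documents(docs, dim=50, seed=0)
        assert vec.shape[1] < 50


class TestKMeans:
    def test_two_points_one_cluster(self):
        vec = pd.DataFrame([[0.0], [2.0]], index=["a", "b"])
        result = tp.kmeans_cluster(vec, k=1, seed=0)
        assert result.centers[0, 0] == pytest.approx(1.0)
        assert result.sse == pytest.approx(2.0)

    def test_k_equals_n_distinct_points_zero_sse(self):
        vec = pd.DataFrame([[0.0], [5.0], [9.0]], index=list("abc"))
        assert tp.kmeans_cluster(vec, k=3, seed=0).sse == pytest.approx(0.0)

    def test_sse_path_non_increasing(self):
        rng = np.random.default_rng(2)
        vec = pd.DataFrame(rng.normal(size=(60, 4)))
        result = tp.kmeans_cluster(vec, k=4, seed=1)
        path = np.array(result.sse_path)
        assert (np.diff(path) <= 1e-9).all()

    def test_k_larger_than_n_rejected(self):
        vec = pd.DataFrame([[0.0], [1.0]])
        with pytest.raises(ValueError):
            tp.kmeans_cluster(vec, k=3, seed=0)


class TestSelectK:
    def test_three_planted_clouds_recovered(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([c + rng.normal(scale=0.3, size=(30, 2)) for c in centers])
        vec = pd.DataFrame(X)
        sel = tp.select_k(vec, range(1, 9), seed=0)
        assert sel.chosen_k == 3 and not sel.used_fallback

    def test_degenerate_single_point_cloud_chooses_smallest_k(self):
        vec = pd.DataFrame(np.zeros((20, 3)))
        sel = tp.select_k(vec, range(1, 7), seed=0)
        assert sel.chosen_k == 1 and sel.used_fallback

    def test_narrow_range_falls_back_to_raw_minimum(self):
        rng = np.random.default_rng(1)
        vec = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.warns(UserWarning, match="narrow"):
            sel = tp.select_k(vec, [2, 3], seed=0)
        assert sel.used_fallback and sel.chosen_k == sel.raw_min_k

    def test_sse_curve_non_increasing(self):
        rng = np.random.default_rng(4)
        vec = pd.DataFrame(rng.normal(size=(50, 3)))
        sel = tp.select_k(vec, range(1, 8), seed=0, n_restarts=10)
        ks = sorted(sel.sse_curve)
        diffs = [sel.sse_curve[b] - sel.sse_curve[a] for a, b in zip(ks, ks[1:])]
        assert all(d <= 1e-9 for d in diffs)


class TestTopicModel:
    def test_thetas_sum_to_one(self):
        rng = np.random.default_rng(3)
        result = tp.fit_topic_model(block_docs(rng, 30, 3), seed=0, max_topics=8)
        np.testing.assert_allclose(result.thetas.sum(axis=1), 1.0, atol=1e-9)

    def test_two_disjoint_blocks_recovered(self):
        rng = np.random.default_rng(5)
        docs = block_docs(rng, 40, 2, words_per_doc=60)
        result = tp.fit_topic_model(docs, seed=0, max_topics=8)
        assert result.n_topics == 2
        dominant = result.thetas.to_numpy().argmax(axis=1)
        first, second = dominant[:20], dominant[20:]
        purity = max(
            (np.mean(first == a) + np.mean(second == b)) / 2
            for a in (0, 1)
            for b in (0, 1)
            if a != b
        )
        assert purity >= 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        docs = block_docs(rng, 20, 2)
        r1 = tp.fit_topic_model(docs, seed=9, max_topics=4)
        r2 = tp.fit_topic_model(docs, seed=9, max_topics=4)
        pd.testing.assert_frame_equal(r1.thetas, r2.thetas)

    def test_single_word_corpus_degenerates_gracefully(self):
        docs = {"a": ["w", "w"], "b": ["w"]}
        result = tp.fit_topic_model(docs, seed=0, max_topics=4)
        assert result.degenerate and result.n_topics == 1


class TestSimilarity:
    def test_identical_distributions(self):
        assert tp.topic_similarity([0.3, 0.7], [0.3, 0.7]) == pytest.approx(1.0)

    def test_disjoint_one_hot(self):
        assert tp.topic_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_half_mixture_vs_one_hot(self):
        assert tp.topic_similarity([0.5, 0.5], [1.0, 0.0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_signalled(self):
        with pytest.raises(ValueError):
            tp.topic_similarity([0.0, 0.0], [1.0, 0.0])

    def test_pair_average_formula(self):
        assert tp.average_similarity_from_pairs([1.0, 0.0, 0.5], 3) == pytest.approx(0.5)

    def test_two_members_average_equals_their_similarity(self):
        thetas = pd.DataFrame([[0.2, 0.8], [0.9, 0.1]], index=["a", "b"])
        expected = tp.topic_similarity([0.2, 0.8], [0.9, 0.1])
        assert tp.average_topic_similarity(["a", "b"], thetas) == pytest.approx(expected)

    def test_identical_members_average_one(self):
        thetas = pd.DataFrame([[0.5, 0.5]] * 4, index=list("abcd"))
        assert tp.average_topic_similarity(list("abcd"), thetas) == pytest.approx(1.0)

    def test_average_matches_explicit_pairwise_mean(self):
        rng = np.random.default_rng(11)
        theta = rng.dirichlet(np.ones(4), size=6)
        thetas = pd.DataFrame(theta, index=[f"u{i}" for i in range(6)])
        pairs = [
            tp.topic_similarity(theta[i], theta[j]) for i in range(6) for j in range(i + 1, 6)
        ]
        expected = tp.average_similarity_from_pairs(pairs, 6)
        assert tp.average_topic_similarity(thetas.index, thetas) == pytest.approx(expected, abs=1e-12)

    def test_single_member_signalled(self):
        thetas = pd.DataFrame([[1.0, 0.0]], index=["a"])
        with pytest.raises(ValueError):
            tp.average_topic_similarity(["a"], thetas)


class TestKeywords:
    def test_ubiquitous_word_scores_zero(self):
        docs = {i: ["common", f"unique{i}"] for i in range(4)}
        tables = tp.tfidf_keywords(docs, top_n=10)
        for table in tables.values():
            scores = dict(table)
            assert scores.get("common", 0.0) == pytest.approx(0.0)

    def test_score_is_tf_times_log_ratio(self):
        docs = {0: ["rare", "rare"]}
        docs.update({i: ["filler"] for i in range(1, 10)})
        tables = tp.tfidf_keywords(docs, top_n=5)
        assert dict(tables[0])["rare"] == pytest.approx(2 * np.log(10))

    def test_stopwords_removed_before_ranking(self):
        docs = {0: ["的"] * 50 + ["term"], 1: ["other"]}
        tables = tp.tfidf_keywords(docs, top_n=10, stopwords={"的"})
        assert "的" not in dict(tables[0])

    def test_top_n_and_ordering(self):
        rng = np.random.default_rng(2)
        docs = {i: [f"w{rng.integers(0, 200)}" for _ in range(400)] for i in range(3)}
        tables = tp.tfidf_keywords(docs, top_n=100)
        for table in tables.values():
            assert len(table) <= 100
            scores = [s for _, s in table]
            assert scores == sorted(scores, reverse=True)

    def test_needs_two_communities(self):
        with pytest.raises(ValueError):
            tp.tfidf_keywords({0: ["a"]})


class TestOverlap:
    def test_identical_sets(self):
        t = {0: [("a", 1.0), ("b", 0.5)], 1: [("a", 1.0), ("b", 0.5)]}
        assert tp.keyword_overlap(t) == {"shared_pct": 100.0, "distinct_pct": 0.0}

    def test_disjoint_sets(self):
        t = {0: [("a", 1.0)], 1: [("b", 1.0)]}
        assert tp.keyword_overlap(t)["shared_pct"] == 0.0

    def test_partial_overlap_ratio(self):
        t = {
            0: [(f"s{i}", 1.0) for i in range(50)] + [(f"x{i}", 1.0) for i in range(75)],
            1: [(f"s{i}", 1.0) for i in range(50)] + [(f"y{i}", 1.0) for i in range(75)],
        }
        result = tp.keyword_overlap(t)
        assert result["shared_pct"] == pytest.approx(25.0)
        assert result["distinct_pct"] == pytest.approx(75.0)
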