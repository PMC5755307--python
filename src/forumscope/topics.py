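"""Document embedding, text clustering, topic modelling and keywords.

Per-user documents (token lists) are embedded as dense vectors, clustered
with k-means under an SSE (within-cluster sum of squares) criterion, and
summarised by a latent topic model whose per-user mixture vectors feed the
pairwise topic-similarity statistics.  TF-IDF ranks each community's
popular keywords.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import LatentDirichletAllocation, TruncatedSVD
from sklearn.feature_extraction.text import CountVectorizer

__all__ = [
    "DocumentEmbedder",
    "TopicModel",
    "ClusteringResult",
    "KSelection",
    "TopicModelResult",
    "embed_documents",
    "kmeans_cluster",
    "select_k",
    "fit_topic_model",
    "topic_similarity",
    "average_similarity_from_pairs",
    "average_topic_similarity",
    "tfidf_keywords",
    "keyword_overlap",
]


def _identity(tokens):
    return tokens


class DocumentEmbedder(BaseEstimator, TransformerMixin):
    """Deterministic document embedding: term counts reduced by truncated SVD.

    Parameters
    ----------
    dim : target embedding dimension; silently reduced (with a warning) when
        it reaches the rank limit ``min(n_docs, vocab) - 1``.
    seed : random state for the randomised SVD solver.
    """

    def __init__(self, dim: int = 50, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def fit(self, docs: Sequence[Sequence[str]], y=None):
        self.vectorizer_ = CountVectorizer(analyzer=_identity)
        counts = self.vectorizer_.fit_transform(docs)
        max_dim = min(counts.shape) - 1
        dim = self.dim
        if dim > max_dim:
            warnings.warn(
                f"embedding dim {dim} exceeds the rank limit {max_dim}; reduced",
                stacklevel=2,
            )
            dim = max(1, max_dim)
        self.svd_ = TruncatedSVD(n_components=dim, random_state=self.seed)
        self.svd_.fit(counts)
        self.n_components_ = dim
        return self

    def transform(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        return self.svd_.transform(self.vectorizer_.transform(docs))


def embed_documents(
    documents: Mapping[str, Sequence[str]], dim: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Embed token-list documents; returns a (user x dim) frame."""
    if not documents:
        raise ValueError("empty corpus")
    ids = list(documents)
    embedder = DocumentEmbedder(dim=dim, seed=seed).fit([documents[i] for i in ids])
    matrix = embedder.transform([documents[i] for i in ids])
    return pd.DataFrame(matrix, index=pd.Index(ids, name="user_id"))


@dataclass
class ClusteringResult:
    k: int
    centers: np.ndarray
    assignment: dict[str, int]
    sse: float
    #: SSE after each Lloyd assignment step; non-increasing by construction.
    sse_path: list[float] = field(default_factory=list)


def _sse(X: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def kmeans_cluster(vectors: pd.DataFrame, k: int, seed: int = 0, max_iter: int = 300) -> ClusteringResult:
    """Lloyd's algorithm from a seeded k-means++ start.

    Iterates to an assignment fixpoint (or ``max_iter``); the within-cluster
    sum of squares SSE = sum_i sum_{x in C_i} ||x - u_i||^2 is recorded
    after every assignment step.
    """
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, n={n}]")
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    labels = np.full(n, -1)
    path: list[float] = []
    for _ in range(max_iter):
        new_labels = cdist(X, centers).argmin(axis=1)
        path.append(_sse(X, centers, new_labels))
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members):  # empty clusters keep their previous center
                centers[j] = members.mean(axis=0)
        path.append(_sse(X, centers, labels))
    assignment = {uid: int(lab) for uid, lab in zip(vectors.index, labels)}
    return ClusteringResult(k=k, centers=centers, assignment=assignment, sse=path[-1], sse_path=path)


@dataclass
class KSelection:
    chosen_k: int
    sse_curve: dict[int, float]
    raw_min_k: int
    used_fallback: bool


def select_k(
    vectors: pd.DataFrame,
    k_range: Iterable[int],
    seed: int = 0,
    n_restarts: int = 5,
) -> KSelection:
    """Choose the number of clusters from the SSE curve.

    SSE(k) is the best of ``n_restarts`` seeded runs per k.  Because SSE is
    monotone non-increasing in k, its literal minimiser is degenerate; the
    returned k is the knee of the curve — the interior k maximising the
    second difference SSE(k-1) - 2 SSE(k) + SSE(k+1) — while the raw
    minimiser is reported alongside.  Ranges too narrow for a second
    difference (width < 3) fall back to the raw minimum with a flag.
    """
    ks = sorted(set(k_range))
    if not ks or ks[0] < 1 or ks[-1] > len(vectors):
        raise ValueError("k_range must lie within [1, n]")
    ss = np.random.SeedSequence([int(seed), 0x5EE])
    sub_seeds = ss.generate_state(len(ks) * n_restarts) >> 1
    curve: dict[int, float] = {}
    for i, k in enumerate(ks):
        curve[k] = min(
            kmeans_cluster(vectors, k, seed=int(sub_seeds[i * n_restarts + r])).sse
            for r in range(n_restarts)
        )
    raw_min_k = min(curve, key=lambda k: (curve[k], k))
    if len(ks) < 3:
        warnings.warn("k_range too narrow for knee detection; using raw SSE minimum", stacklevel=2)
        return KSelection(raw_min_k, curve, raw_min_k, used_fallback=True)
    second_diff = {
        ks[i]: curve[ks[i - 1]] - 2 * curve[ks[i]] + curve[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    best = max(second_diff, key=lambda k: (second_diff[k], -k))
    scale = max(curve[ks[0]], 1.0)
    if second_diff[best] <= 1e-9 * scale:  # flat or linear curve: no knee
        return KSelection(raw_min_k, curve, raw_min_k, used_fallback=True)
    return KSelection(best, curve, raw_min_k, used_fallback=False)


class TopicModel(BaseEstimator):
    """Latent Dirichlet topic model with automatic topic-count selection.

    Candidate topic counts on a grid up to ``max_topics`` are each fitted on
    an 80% split and scored by held-out perplexity; the smallest count whose
    perplexity is within ``rel_tol`` of the grid minimum is chosen (larger
    counts must earn their complexity), then refitted on the full corpus.

    Fitted attributes: ``n_topics_``, ``doc_topic_`` (rows sum to 1),
    ``topic_word_``, ``perplexity_by_k_``, ``degenerate_``.
    """

    def __init__(self, max_topics: int = 12, seed: int = 0, rel_tol: float = 0.01):
        self.max_topics = max_topics
        self.seed = seed
        self.rel_tol = rel_tol

    def _candidates(self) -> list[int]:
        grid = [2, 4, 8, 12, 16, 24, 32]
        return [t for t in grid if t <= self.max_topics] or [2]

    def fit(self, docs: Sequence[Sequence[str]], y=None):
        if len(docs) == 0:
            raise ValueError("empty corpus")
        self.vectorizer_ = CountVectorizer(analyzer=_identity)
        counts = self.vectorizer_.fit_transform(docs)
        n_docs, vocab = counts.shape
        self.degenerate_ = vocab < 2
        if self.degenerate_:
            self.n_topics_ = 1
            self.doc_topic_ = np.ones((n_docs, 1))
            self.topic_word_ = np.ones((1, vocab))
            self.perplexity_by_k_ = {}
            return self

        rng = np.random.default_rng([int(self.seed), 0x70])
        perm = rng.permutation(n_docs)
        n_test = max(1, n_docs // 5)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        if len(train_idx) == 0:
            train_idx = test_idx
        lda_seed = int(rng.integers(2**31))

        self.perplexity_by_k_ = {}
        for t in self._candidates():
            # shorter EM scan for model selection; the chosen count is refitted fully
            lda = LatentDirichletAllocation(
                n_components=t, random_state=lda_seed, learning_method="batch", max_iter=5
            )
            lda.fit(counts[train_idx])
            self.perplexity_by_k_[t] = float(lda.perplexity(counts[test_idx]))
        best_perp = min(self.perplexity_by_k_.values())
        self.n_topics_ = min(
            t for t, p in self.perplexity_by_k_.items() if p <= best_perp * (1 + self.rel_tol)
        )
        self.lda_ = LatentDirichletAllocation(
            n_components=self.n_topics_, random_state=lda_seed, learning_method="batch"
        )
        doc_topic = self.lda_.fit_transform(counts)
        self.doc_topic_ = doc_topic / doc_topic.sum(axis=1, keepdims=True)
        self.topic_word_ = self.lda_.components_ / self.lda_.components_.sum(axis=1, keepdims=True)
        return self

    def transform(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        if self.degenerate_:
            return np.ones((len(docs), 1))
        theta = self.lda_.transform(self.vectorizer_.transform(docs))
        return theta / theta.sum(axis=1, keepdims=True)


@dataclass
class TopicModelResult:
    thetas: pd.DataFrame  # user x topic, rows sum to 1
    topic_word: pd.DataFrame  # topic x word
    n_topics: int
    degenerate: bool
    perplexity_by_k: dict[int, float]


def fit_topic_model(
    documents: Mapping[str, Sequence[str]], seed: int = 0, max_topics: int = 12
) -> TopicModelResult:
    """Fit the topic model and return per-user topic mixtures."""
    ids = list(documents)
    model = TopicModel(max_topics=max_topics, seed=seed).fit([documents[i] for i in ids])
    vocab = model.vectorizer_.get_feature_names_out()
    return TopicModelResult(
        thetas=pd.DataFrame(model.doc_topic_, index=pd.Index(ids, name="user_id")),
        topic_word=pd.DataFrame(model.topic_word_, columns=vocab),
        n_topics=model.n_topics_,
        degenerate=model.degenerate_,
        perplexity_by_k=model.perplexity_by_k_,
    )


def topic_similarity(theta_i: np.ndarray, theta_j: np.ndarray) -> float:
    """Cosine similarity of two topic mixtures; in [0, 1] on the simplex."""
    a = np.asarray(theta_i, dtype=float)
    b = np.asarray(theta_j, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("topic similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def average_similarity_from_pairs(pair_similarities: Sequence[float], n_members: int) -> float:
    """Community-average similarity S = 2/(n(n-1)) * sum over unordered pairs.

    ``pair_similarities`` must hold one value per unordered member pair,
    i.e. n(n-1)/2 values for ``n_members`` members.
    """
    n = n_members
    if n < 2:
        raise ValueError("average similarity needs at least 2 members")
    if len(pair_similarities) != n * (n - 1) // 2:
        raise ValueError(f"expected {n * (n - 1) // 2} pair similarities, got {len(pair_similarities)}")
    return 2.0 / (n * (n - 1)) * float(np.sum(pair_similarities))


def average_topic_similarity(members: Iterable[str], thetas: pd.DataFrame) -> float:
    """Mean pairwise topic similarity S over all unordered member pairs."""
    members = sorted(set(members), key=str)
    n = len(members)
    if n < 2:
        raise ValueError("average topic similarity needs at least 2 members")
    M = thetas.loc[members].to_numpy(dtype=float)
    norms = np.linalg.norm(M, axis=1)
    if (norms == 0).any():
        raise ValueError("topic similarity undefined for a zero vector")
    unit = M / norms[:, None]
    gram = unit @ unit.T
    return float((gram.sum() - np.trace(gram)) / (n * (n - 1)))


def tfidf_keywords(
    community_docs: Mapping[object, Iterable[str]],
    top_n: int = 100,
    stopwords: Iterable[str] = frozenset(),
) -> dict[object, list[tuple[str, float]]]:
    """Rank each community's keywords by TF-IDF.

    Each community's member documents are pooled into one community
    document; tf is the raw in-community count and idf = ln(N / df) over the
    N community documents.  Stop-words are removed before ranking; ties are
    broken lexicographically and the top ``top_n`` kept.
    """
    if len(community_docs) < 2:
        raise ValueError("tf-idf needs at least 2 community documents")
    stopwords = frozenset(stopwords)
    counts: dict[object, dict[str, int]] = {}
    for label, tokens in community_docs.items():
        bag: dict[str, int] = {}
        for tok in tokens:
            if tok not in stopwords:
                bag[tok] = bag.get(tok, 0) + 1
        counts[label] = bag
    n_communities = len(counts)
    df: dict[str, int] = {}
    for bag in counts.values():
        for word in bag:
            df[word] = df.get(word, 0) + 1
    tables = {}
    for label, bag in counts.items():
        scored = [(w, tf * np.log(n_communities / df[w])) for w, tf in bag.items()]
        scored.sort(key=lambda ws: (-ws[1], ws[0]))
        tables[label] = [(w, float(s)) for w, s in scored[:top_n]]
    return tables


def keyword_overlap(tables: Mapping[object, list[tuple[str, float]]]) -> dict[str, float]:
    """Shared/distinct keyword percentages across communities.

    shared% = |intersection of the keyword sets| / |union| * 100.
    """
    if len(tables) < 2:
        raise ValueError("keyword overlap needs at least 2 keyword tables")
    sets = [set(w for w, _ in table) for table in tables.values()]
    union = set.union(*sets)
    inter = set.intersection(*sets)
    shared = 100.0 * len(inter) / len(union) if union else 0.0
    return {"shared_pct": shared, "distinct_pct": 100.0 - shared}
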