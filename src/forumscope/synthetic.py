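"""Synthetic forum generator with planted structure.

Emulates the statistical structure of a crawled forum dump: users organised
into communities, per-user topic mixtures drawn from community-level
Dirichlet profiles, homophilous reply/comment arcs whose probability rises
with topic similarity, bag-of-words documents over block-structured topic
vocabularies, planted per-user sentiment polarity via injected lexicon
words, and diurnal (evening-peaked) timestamps.

The generator models the *active* sub-population of a forum — every
synthetic user opens several threads — because that is the population the
analysis pipeline operates on after its activity filter.

Homophily is governed by ``gamma``: the probability of an arc between
within-community users u, v is

    p_intra * ((1 - gamma) + gamma * cos(theta_u, theta_v)),

so ``gamma = 0`` decouples structure from content (the null condition) and
``gamma = 1`` couples them fully.  Communities differ in their Dirichlet
concentration ``alpha``; diffuse communities (small alpha) discuss diverse
topics and, under homophily, interact less — the mechanism that makes
per-community topic similarity and network efficiency co-vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ForumTables

__all__ = ["SyntheticConfig", "PlantedTruth", "generate_forum", "truth_community_stats", "TOY_LEXICON"]

#: Small built-in lexicon used by the generator; intensities in +/-1..5.
TOY_LEXICON: dict[str, int] = {
    "calm": 1,
    "joyful": 2,
    "hope": 3,
    "grateful": 4,
    "relieved": 5,
    "anxious": -1,
    "worried": -2,
    "fear": -3,
    "panic": -4,
    "despair": -5,
}

#: Evening-peaked diurnal activity profile (peak 22:00, trough 03:00-05:00).
DEFAULT_HOURLY_PROFILE: tuple[float, ...] = (
    2.0, 1.2, 0.7, 0.4, 0.4, 0.5, 1.0, 1.8, 2.5, 3.0, 3.4, 3.6,
    3.8, 3.6, 3.4, 3.5, 3.8, 4.2, 4.8, 5.5, 6.4, 7.2, 8.0, 4.5,
)


class ConfigError(ValueError):
    """Inconsistent synthetic-forum configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic forum; defaults define the study design.

    The default design plants 30 communities of 20-60 users whose Dirichlet
    concentrations span two orders of magnitude (0.5 to 50) under full
    homophily, a ~60% negative-user fraction, and an evening-peaked hourly
    activity profile.
    """

    n_communities: int = 30
    community_sizes: list[int] | None = None  # drawn from size_range when None
    size_range: tuple[int, int] = (20, 60)
    n_users: int | None = None  # optional cross-check against community_sizes
    n_topics: int = 8
    vocab_size: int = 400
    alpha_by_community: list[float] | None = None  # default: log-spaced alpha_range
    alpha_range: tuple[float, float] = (0.5, 50.0)
    gamma: float = 1.0
    p_intra: float = 0.25
    p_inter: float = 0.0005
    min_posts_per_user: int = 4
    extra_posts_lam: float = 2.0
    words_per_post: int = 25
    words_per_interaction: int = 8
    fraction_negative: float = 0.6
    lexicon: dict[str, int] = field(default_factory=lambda: dict(TOY_LEXICON))
    injection_rate: int = 6
    comment_fraction: float = 0.3
    multiplicity_lam: float = 0.3
    hourly_profile: Sequence[float] = DEFAULT_HOURLY_PROFILE
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.gamma <= 1:
            raise ConfigError("gamma must lie in [0, 1]")
        if not (0 <= self.p_inter <= self.p_intra <= 1):
            raise ConfigError("need 0 <= p_inter <= p_intra <= 1")
        if not 0 <= self.fraction_negative <= 1:
            raise ConfigError("fraction_negative must lie in [0, 1]")
        if self.community_sizes is not None:
            if len(self.community_sizes) != self.n_communities:
                raise ConfigError("community_sizes length must equal n_communities")
            if self.n_users is not None and sum(self.community_sizes) != self.n_users:
                raise ConfigError("community_sizes do not sum to n_users")
        if self.alpha_by_community is not None:
            if len(self.alpha_by_community) != self.n_communities:
                raise ConfigError("alpha_by_community length must equal n_communities")
            if any(a <= 0 for a in self.alpha_by_community):
                raise ConfigError("alpha values must be positive")
        profile = np.asarray(self.hourly_profile, dtype=float)
        if profile.shape != (24,) or (profile < 0).any() or profile.sum() <= 0:
            raise ConfigError("hourly_profile must be 24 non-negative weights with positive sum")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("size_range", "alpha_range", "hourly_profile", "community_sizes", "alpha_by_community"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key]) if key.endswith("_range") else list(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


@dataclass
class PlantedTruth:
    """Ground truth behind a generated forum."""

    community_label: dict[str, int]
    theta: pd.DataFrame  # user x topic, rows sum to 1
    polarity: dict[str, str]  # "positive" | "negative"


def _draw_theta(rng: np.random.Generator, alpha_vec: np.ndarray) -> np.ndarray:
    draws = rng.gamma(shape=alpha_vec)
    total = draws.sum()
    if total < 1e-300:  # all-underflow guard for very small concentrations
        one_hot = np.zeros_like(alpha_vec)
        one_hot[int(rng.integers(len(alpha_vec)))] = 1.0
        return one_hot
    return draws / total


def _topic_word_rows(n_topics: int, vocab_size: int) -> np.ndarray:
    """Block-diagonal-dominant topic-word distributions.

    Each topic owns a contiguous vocabulary block carrying 85% of its mass;
    the remaining 15% is uniform background, keeping topics identifiable at
    small corpus sizes.
    """
    rows = np.full((n_topics, vocab_size), 0.15 / vocab_size)
    bounds = np.linspace(0, vocab_size, n_topics + 1).astype(int)
    for t in range(n_topics):
        lo, hi = bounds[t], bounds[t + 1]
        rows[t, lo:hi] += 0.85 / (hi - lo)
    return rows / rows.sum(axis=1, keepdims=True)


def _draw_words(rng: np.random.Generator, theta: np.ndarray, topic_word_cum: np.ndarray, n_words: int) -> list[str]:
    topics = rng.choice(len(theta), size=n_words, p=theta)
    # inverse-CDF word draw per sampled topic
    words = np.minimum(
        topic_word_cum.shape[1] - 1,
        np.array([np.searchsorted(topic_word_cum[t], r) for t, r in zip(topics, rng.random(n_words))]),
    )
    return [f"w{w:04d}" for w in words]


def _draw_timestamps(rng: np.random.Generator, profile: np.ndarray, n: int) -> list[pd.Timestamp]:
    hours = rng.choice(24, size=n, p=profile / profile.sum())
    days = rng.integers(0, 180, size=n)
    minutes = rng.integers(0, 60, size=n)
    seconds = rng.integers(0, 60, size=n)
    base = pd.Timestamp("2016-01-01")
    return [
        base + pd.Timedelta(days=int(d), hours=int(h), minutes=int(m), seconds=int(s))
        for d, h, m, s in zip(days, hours, minutes, seconds)
    ]


def generate_forum(config: SyntheticConfig) -> tuple[ForumTables, PlantedTruth]:
    """Generate a forum dump with planted community/topic/sentiment truth.

    Deterministic given ``config.seed``: each generation stage draws from
    its own stream spawned from the master seed, so adding a stage never
    perturbs earlier draws.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    rng_layout, rng_theta, rng_docs, rng_edges, rng_sent, rng_time = (
        np.random.default_rng(s) for s in master.spawn(6)
    )

    # --- community layout ------------------------------------------------
    K = config.n_communities
    if config.community_sizes is not None:
        sizes = list(config.community_sizes)
    else:
        lo, hi = config.size_range
        sizes = [int(s) for s in rng_layout.integers(lo, hi + 1, size=K)]
    if config.n_users is not None and config.community_sizes is None and sum(sizes) != config.n_users:
        # honour an explicit n_users by trimming/padding the last community
        raise ConfigError("n_users given without community_sizes; sizes are drawn — omit n_users")
    n_users = sum(sizes)
    if config.alpha_by_community is not None:
        alphas = list(config.alpha_by_community)
    else:
        alphas = list(np.geomspace(config.alpha_range[0], config.alpha_range[1], K))

    user_ids = [f"u{i:05d}" for i in range(n_users)]
    community_label: dict[str, int] = {}
    idx = 0
    for k, size in enumerate(sizes):
        for _ in range(size):
            community_label[user_ids[idx]] = k
            idx += 1

    # --- topic mixtures ---------------------------------------------------
    T = config.n_topics
    profiles = np.vstack([_draw_theta(rng_theta, np.ones(T)) for _ in range(K)])
    theta = np.vstack(
        [_draw_theta(rng_theta, alphas[community_label[u]] * profiles[community_label[u]] + 1e-6)
         for u in user_ids]
    )
    theta_df = pd.DataFrame(theta, index=pd.Index(user_ids, name="user_id"))

    # --- sentiment polarity ----------------------------------------------
    polarity = {
        u: ("negative" if rng_sent.random() < config.fraction_negative else "positive")
        for u in user_ids
    }
    pos_words = sorted(w for w, s in config.lexicon.items() if s > 0)
    neg_words = sorted(w for w, s in config.lexicon.items() if s < 0)
    if not pos_words or not neg_words:
        raise ConfigError("lexicon must contain both positive and negative words")

    # --- threads (floor-1 comments) ---------------------------------------
    topic_word_cum = np.cumsum(_topic_word_rows(T, config.vocab_size), axis=1)
    comments: list[dict] = []
    posts_by_user: dict[str, list[str]] = {}
    opener_comment: dict[str, str] = {}  # post_id -> its floor-1 comment_id
    floor_counter: dict[str, int] = {}
    injected: dict[str, tuple[int, int]] = {}  # user -> (pos_sum, neg_sum)
    post_serial = comment_serial = 0
    for u in user_ids:
        n_posts = config.min_posts_per_user + int(rng_docs.poisson(config.extra_posts_lam))
        posts_by_user[u] = []
        pos_sum = neg_sum = 0
        for _ in range(n_posts):
            post_id = f"p{post_serial:06d}"
            comment_id = f"c{comment_serial:07d}"
            post_serial += 1
            comment_serial += 1
            words = _draw_words(rng_docs, theta_df.loc[u].to_numpy(), topic_word_cum, config.words_per_post)
            maj_words = neg_words if polarity[u] == "negative" else pos_words
            min_words = pos_words if polarity[u] == "negative" else neg_words
            n_maj = max(1, config.injection_rate)
            n_min = config.injection_rate // 3
            inj = [maj_words[int(i)] for i in rng_sent.integers(len(maj_words), size=n_maj)]
            inj += [min_words[int(i)] for i in rng_sent.integers(len(min_words), size=n_min)]
            for w in inj:
                s = config.lexicon[w]
                if s > 0:
                    pos_sum += s
                else:
                    neg_sum -= s
            words = words + inj
            comments.append(
                {"comment_id": comment_id, "post_id": post_id, "floor": 1, "author_id": u,
                 "content": " ".join(words)}
            )
            posts_by_user[u].append(post_id)
            opener_comment[post_id] = comment_id
            floor_counter[post_id] = 2
        # guarantee the planted polarity is strict over the user's corpus
        maj_words = neg_words if polarity[u] == "negative" else pos_words
        while (neg_sum <= pos_sum) if polarity[u] == "negative" else (pos_sum <= neg_sum):
            w = maj_words[int(rng_sent.integers(len(maj_words)))]
            s = config.lexicon[w]
            if s > 0:
                pos_sum += s
            else:
                neg_sum -= s
            comments[-1]["content"] += " " + w
        injected[u] = (pos_sum, neg_sum)

    # --- homophilous interaction arcs --------------------------------------
    unit = theta / np.linalg.norm(theta, axis=1, keepdims=True)
    prob = np.full((n_users, n_users), config.p_inter)
    start = 0
    for k, size in enumerate(sizes):
        block = slice(start, start + size)
        cos = unit[block] @ unit[block].T
        prob[block, block] = config.p_intra * ((1 - config.gamma) + config.gamma * cos)
        start += size
    np.fill_diagonal(prob, 0.0)
    arcs = np.argwhere(rng_edges.random((n_users, n_users)) < prob)

    replies: list[dict] = []
    reply_serial = 0
    for ui, vi in arcs:
        u, v = user_ids[int(ui)], user_ids[int(vi)]
        weight = 1 + int(rng_edges.poisson(config.multiplicity_lam))
        for _ in range(weight):
            target_post = posts_by_user[v][int(rng_edges.integers(len(posts_by_user[v])))]
            words = _draw_words(rng_docs, theta_df.loc[u].to_numpy(), topic_word_cum, config.words_per_interaction)
            content = " ".join(words)
            if rng_edges.random() < config.comment_fraction:
                comments.append(
                    {"comment_id": f"c{comment_serial:07d}", "post_id": target_post,
                     "floor": floor_counter[target_post], "author_id": u, "content": content}
                )
                comment_serial += 1
                floor_counter[target_post] += 1
            else:
                replies.append(
                    {"reply_id": f"r{reply_serial:07d}", "comment_id": opener_comment[target_post],
                     "author_id": u, "reply_to_whom": v, "content": content}
                )
                reply_serial += 1

    # --- assemble tables ----------------------------------------------------
    profile = np.asarray(config.hourly_profile, dtype=float)
    comments_df = pd.DataFrame(comments)
    comments_df["time"] = _draw_timestamps(rng_time, profile, len(comments_df))
    replies_df = pd.DataFrame(replies, columns=["reply_id", "comment_id", "author_id", "reply_to_whom", "content"])
    replies_df["time"] = _draw_timestamps(rng_time, profile, len(replies_df))
    users_df = pd.DataFrame(
        {
            "user_id": user_ids,
            "name": [f"user_{i}" for i in range(n_users)],
            "sex": [["male", "female", "unknown"][int(i)] for i in rng_layout.integers(0, 3, size=n_users)],
            "level": [int(x) for x in rng_layout.poisson(3, size=n_users)],
        }
    )
    tables = ForumTables(users_df, comments_df[["comment_id", "post_id", "floor", "author_id", "content", "time"]], replies_df)
    truth = PlantedTruth(community_label=community_label, theta=theta_df, polarity=polarity)
    return tables, truth


def truth_community_stats(truth: PlantedTruth) -> pd.DataFrame:
    """Exact per-community statistics of the planted values.

    One row per community: size, true mean pairwise topic similarity
    (cosine) and true negative-user fraction.  Singleton communities report
    similarity 1.0 by convention.
    """
    rows = []
    theta = truth.theta
    for k in sorted(set(truth.community_label.values())):
        members = sorted(u for u, lab in truth.community_label.items() if lab == k)
        M = theta.loc[members].to_numpy(dtype=float)
        unit = M / np.linalg.norm(M, axis=1, keepdims=True)
        n = len(members)
        if n < 2:
            sim = 1.0
        else:
            gram = unit @ unit.T
            sim = float((gram.sum() - np.trace(gram)) / (n * (n - 1)))
        neg = sum(1 for u in members if truth.polarity[u] == "negative")
        rows.append({"community": k, "size": n, "true_mean_similarity": sim, "true_negative_fraction": neg / n})
    return pd.DataFrame(rows)
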