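"""Per-community statistics, content-structure correlations and the
end-to-end pipeline.

The pipeline mirrors a two-route community analysis: users are grouped
once by text similarity (embedding + k-means) and once by interaction-graph
topology (modularity communities); for every community it computes the
average topic similarity S, the network efficiency E, density, the largest
weakly connected component and sentiment proportions, then correlates
content similarity with network structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import io as fio
from . import network as net
from . import communities as comm
from . import topics as tp
from . import sentiment as snt
from .synthetic import SyntheticConfig, generate_forum

__all__ = [
    "CorrelationResult",
    "PipelineConfig",
    "PipelineReport",
    "community_stats_table",
    "pearson_correlation",
    "gcc_similarity_comparison",
    "hourly_activity_profile",
    "run_pipeline",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n_points: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_points": self.n_points}


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson r with a two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n_points=len(x))


def community_stats_table(
    partition: comm.Partition,
    graph: nx.DiGraph,
    thetas: pd.DataFrame,
    sentiments: Mapping[str, snt.DocumentSentiment],
) -> pd.DataFrame:
    """One row per community: size, S, E, density, Gcc size, S_gcc, sentiment.

    Metrics are computed on the community's induced subgraph and member set.
    Communities where a metric's precondition fails (fewer than 2 members
    with topic mixtures, Gcc smaller than 2) carry NaN in that column and
    ``flagged=True`` rather than being dropped.
    """
    rows = []
    for label, members in enumerate(partition.communities):
        sub = graph.subgraph(members)
        with_theta = sorted(m for m in members if m in thetas.index)
        flagged = len(members) < 2 or len(with_theta) < 2
        S = tp.average_topic_similarity(with_theta, thetas) if len(with_theta) >= 2 else np.nan
        _, gcc = net.weakly_connected_components(sub) if len(members) else ([], set())
        gcc_theta = sorted(m for m in gcc if m in thetas.index)
        S_gcc = tp.average_topic_similarity(gcc_theta, thetas) if len(gcc_theta) >= 2 else np.nan
        sent = snt.community_sentiment(members, sentiments)
        rows.append(
            {
                "community": label,
                "size": len(members),
                "S": S,
                "E": net.network_efficiency(sub),
                "density": net.network_density(sub),
                "gcc_size": len(gcc),
                "S_gcc": S_gcc,
                "pos_prop": sent["positive"] if sent["positive"] is not None else np.nan,
                "neg_prop": sent["negative"] if sent["negative"] is not None else np.nan,
                "n_neutral": sent["n_neutral"],
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def gcc_similarity_comparison(rows: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-community S_gcc - S differences and the fraction with S_gcc > S.

    Only communities whose largest weakly connected component has at least
    two members enter the comparison.
    """
    eligible = rows.loc[(rows["gcc_size"] >= 2) & rows["S"].notna() & rows["S_gcc"].notna()]
    table = eligible[["community", "size", "gcc_size", "S", "S_gcc"]].copy()
    table["difference"] = table["S_gcc"] - table["S"]
    frac = float((table["difference"] > 0).mean()) if len(table) else float("nan")
    return table.reset_index(drop=True), frac


def hourly_activity_profile(tables: fio.ForumTables) -> np.ndarray:
    """Proportion of authored records (comments + replies) per hour of day."""
    times = pd.concat([tables.comments["time"], tables.replies["time"]], ignore_index=True)
    times = pd.to_datetime(times, errors="coerce").dropna()
    if times.empty:
        raise ValueError("no parseable timestamps in the tables")
    counts = times.dt.hour.value_counts().reindex(range(24), fill_value=0).sort_index()
    return (counts / counts.sum()).to_numpy(dtype=float)


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    Exactly one of ``table_paths`` (users/comments/replies files) or
    ``synthetic`` must be provided.
    """

    table_paths: tuple[str, str, str] | None = None
    synthetic: SyntheticConfig | None = None
    seed: int = 0
    min_posts: int = 3
    #: the clustering/topic corpus uses opened-thread (floor-1) content only
    #: by default: follow-up comment and reply volume scales with a user's
    #: interaction degree, which would couple topic-mixture estimation noise
    #: to network density. "comments" adds follow-up comments, "all" adds
    #: replies too.
    corpus_scope: str = "posts"
    embed_dim: int = 50
    k_range: tuple[int, ...] = tuple(range(2, 41, 2))
    n_restarts: int = 3
    max_topics: int = 12
    top_n_keywords: int = 100
    lexicon: dict[str, int] | None = None
    lexicon_paths: tuple[str, ...] | None = None
    stopwords: frozenset[str] = fio.DEFAULT_STOPWORDS


@dataclass
class PipelineReport:
    """Everything the pipeline computed, plus a stage-by-stage run log."""

    n_users: int
    n_active: int
    graph_summary: dict
    chosen_k: int
    text_stats: pd.DataFrame
    topology_stats: pd.DataFrame
    n_topology_communities: int
    n_meaningful: int
    fully_connected_frac: float
    correlations: dict[str, dict[str, CorrelationResult]]
    gcc_fraction: dict[str, float]
    keywords: dict
    keyword_overlap: dict[str, float]
    sentiment_summary: dict
    hourly_profile: list[float]
    thetas: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (tables as records, floats rounded)."""
        return {
            "n_users": self.n_users,
            "n_active": self.n_active,
            "graph": self.graph_summary,
            "chosen_k": self.chosen_k,
            "n_topology_communities": self.n_topology_communities,
            "n_meaningful": self.n_meaningful,
            "fully_connected_frac": self.fully_connected_frac,
            "correlations": {
                route: {name: res.to_dict() for name, res in cors.items()}
                for route, cors in self.correlations.items()
            },
            "gcc_fraction": self.gcc_fraction,
            "keyword_overlap": self.keyword_overlap,
            "sentiment": self.sentiment_summary,
            "hourly_profile": self.hourly_profile,
            "text_stats": json.loads(self.text_stats.to_json(orient="records", double_precision=10)),
            "topology_stats": json.loads(self.topology_stats.to_json(orient="records", double_precision=10)),
            "log": self.log,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8")


def _route_correlations(stats_table: pd.DataFrame, log: list[str], route: str) -> dict[str, CorrelationResult]:
    """The content-structure correlations over one route's community table."""
    ok = stats_table.loc[~stats_table["flagged"] & stats_table["S"].notna()]
    excluded = len(stats_table) - len(ok)
    log.append(f"{route}: {excluded} of {len(stats_table)} communities excluded from correlations")
    pairs = {
        "S_vs_E": ("S", "E"),
        "S_vs_density": ("S", "density"),
        "S_vs_size": ("S", "size"),
        "S_vs_gcc_size": ("S", "gcc_size"),
        "negprop_vs_size": ("neg_prop", "size"),
    }
    out = {}
    for name, (xcol, ycol) in pairs.items():
        sub = ok.loc[ok[xcol].notna() & ok[ycol].notna()]
        try:
            out[name] = pearson_correlation(sub[xcol], sub[ycol])
        except ValueError as exc:
            log.append(f"{route}: correlation {name} skipped ({exc})")
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis end to end; deterministic given config + seed."""
    log: list[str] = []
    ss = np.random.SeedSequence([int(config.seed), 0xF0])
    seeds = [int(s) for s in (ss.generate_state(8) >> 1)]

    if (config.table_paths is None) == (config.synthetic is None):
        raise ValueError("provide exactly one of table_paths or synthetic config")
    if config.synthetic is not None:
        tables, _truth = generate_forum(config.synthetic)
        log.append(f"generated synthetic forum with seed {config.synthetic.seed}")
    else:
        tables = fio.read_forum_tables(*config.table_paths)
        log.append(f"read tables, dropped rows: {tables.n_bad_rows}")

    if config.corpus_scope not in ("posts", "comments", "all"):
        raise ValueError(f"unknown corpus_scope {config.corpus_scope!r}")
    documents = fio.assemble_user_documents(
        tables,
        include_replies=config.corpus_scope == "all",
        include_followup_comments=config.corpus_scope != "posts",
        stopwords=config.stopwords,
    )
    active = fio.filter_active(documents, min_posts=config.min_posts)
    log.append(f"{len(documents)} users with text; {len(active)} active (> {config.min_posts} posts)")
    if len(active) < 3:
        raise RuntimeError("pipeline: fewer than 3 active users; nothing to analyse")

    graph = net.build_interaction_network(tables)
    log.append(f"interaction network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} arcs")

    token_docs = {uid: doc.tokens for uid, doc in active.items()}

    # text route: embed + select k + cluster
    vectors = tp.embed_documents(token_docs, dim=config.embed_dim, seed=seeds[0])
    k_range = [k for k in config.k_range if k <= len(vectors)]
    selection = tp.select_k(vectors, k_range, seed=seeds[1], n_restarts=config.n_restarts)
    clustering = tp.kmeans_cluster(vectors, selection.chosen_k, seed=seeds[2])
    log.append(f"text clustering: chose k={selection.chosen_k} (raw minimum k={selection.raw_min_k})")
    cluster_sets: dict[int, set] = {}
    for uid, lab in clustering.assignment.items():
        cluster_sets.setdefault(lab, set()).add(uid)
    text_partition = comm.Partition(
        assignment=dict(clustering.assignment),
        communities=[cluster_sets[lab] for lab in sorted(cluster_sets)],
        quality=float("nan"),
    )

    # topology route
    partition = comm.detect_communities(graph, seed=seeds[3])
    meaningful, counts = comm.filter_meaningful(partition, graph)
    log.append(
        f"topology communities: {len(partition.communities)} found, {counts['kept']} meaningful"
    )
    subgraphs = [graph.subgraph(c) for c in meaningful.communities]
    fc_frac = comm.fully_connected_fraction(subgraphs) if subgraphs else float("nan")

    # topics and sentiment
    topic_result = tp.fit_topic_model(token_docs, seed=seeds[4], max_topics=config.max_topics)
    log.append(f"topic model: {topic_result.n_topics} topics")
    if config.lexicon is not None:
        lexicon = snt.SentimentLexicon(dict(config.lexicon))
    elif config.lexicon_paths:
        lexicon = snt.load_lexicon(config.lexicon_paths)
    else:
        from .synthetic import TOY_LEXICON

        lexicon = snt.SentimentLexicon(dict(TOY_LEXICON))
        log.append("no lexicon supplied; using the built-in toy lexicon")
    sentiments = {
        uid: snt.score_document(doc.tokens, lexicon, user_id=uid) for uid, doc in active.items()
    }
    labels = [s.label for s in sentiments.values()]
    sentiment_summary = {
        "n_positive": labels.count("positive"),
        "n_negative": labels.count("negative"),
        "n_neutral": labels.count("neutral"),
        "negative_fraction": (
            labels.count("negative") / max(1, labels.count("positive") + labels.count("negative"))
        ),
    }

    # per-community statistics + correlations for both routes
    text_stats = community_stats_table(text_partition, graph, topic_result.thetas, sentiments)
    topo_stats = community_stats_table(meaningful, graph, topic_result.thetas, sentiments)
    correlations = {
        "text": _route_correlations(text_stats, log, "text"),
        "topology": _route_correlations(topo_stats, log, "topology"),
    }
    gcc_fraction = {
        "text": gcc_similarity_comparison(text_stats)[1],
        "topology": gcc_similarity_comparison(topo_stats)[1],
    }

    # keywords per text cluster
    community_docs = {
        lab: [t for uid in sorted(members) for t in token_docs.get(uid, [])]
        for lab, members in enumerate(text_partition.communities)
    }
    community_docs = {lab: toks for lab, toks in community_docs.items() if toks}
    if len(community_docs) >= 2:
        keywords = tp.tfidf_keywords(community_docs, top_n=config.top_n_keywords, stopwords=config.stopwords)
        overlap = tp.keyword_overlap(keywords)
    else:
        keywords, overlap = {}, {"shared_pct": float("nan"), "distinct_pct": float("nan")}
        log.append("fewer than 2 non-empty text clusters; keyword stage skipped")

    return PipelineReport(
        n_users=len(documents),
        n_active=len(active),
        graph_summary={
            "n_nodes": graph.number_of_nodes(),
            "n_arcs": graph.number_of_edges(),
            "density": net.network_density(graph),
        },
        chosen_k=selection.chosen_k,
        text_stats=text_stats,
        topology_stats=topo_stats,
        n_topology_communities=len(partition.communities),
        n_meaningful=counts["kept"],
        fully_connected_frac=fc_frac,
        correlations=correlations,
        gcc_fraction=gcc_fraction,
        keywords={lab: kw[:10] for lab, kw in keywords.items()},
        keyword_overlap=overlap,
        sentiment_summary=sentiment_summary,
        hourly_profile=[float(x) for x in hourly_activity_profile(tables)],
        thetas=topic_result.thetas,
        log=log,
    )
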