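import networkx as nx
import pandas as pd
import pytest

from forumscope.io import ForumTables


def make_tables(users=(), comments=(), replies=()):
    """Build ForumTables from row tuples; a convenience for hand-made fixtures.

    users: (user_id, name, sex, level)
    comments: (comment_id, post_id, floor, author_id, content, time)
    replies: (reply_id, comment_id, author_id, reply_to_whom, content, time)
    """
    users_df = pd.DataFrame(list(users), columns=["user_id", "name", "sex", "level"])
    comments_df = pd.DataFrame(
        list(comments), columns=["comment_id", "post_id", "floor", "author_id", "content", "time"]
    )
    replies_df = pd.DataFrame(
        list(replies), columns=["reply_id", "comment_id", "author_id", "reply_to_whom", "content", "time"]
    )
    for frame in (comments_df, replies_df):
        frame["time"] = pd.to_datetime(frame["time"])
    return ForumTables(users_df, comments_df, replies_df)


def random_digraph(rng, n, p, max_weight=3):
    g = nx.DiGraph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}", weight=int(rng.integers(1, max_weight + 1)))
    return g


@pytest.fixture(scope="session")
def small_forum():
    """A small generated forum shared by read-only tests."""
    from forumscope.synthetic import SyntheticConfig, generate_forum

    config = SyntheticConfig(n_communities=5, size_range=(8, 14), seed=11)
    tables, truth = generate_forum(config)
    return config, tables, truth
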