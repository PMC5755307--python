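"""Reading, writing and preprocessing of the three-table forum dump.

A forum dump consists of three linked delimited-text tables:

* ``users`` — one row per registered user (id, display name, sex, level);
* ``comments`` — one row per comment posted in a thread; the comment at
  floor 1 *is* the thread-opening post, higher floors are responses;
* ``replies`` — one row per reply addressed to a specific user beneath a
  comment.

All text is UTF-8; the delimiter (comma or tab) is auto-detected from the
header line.  Per-user documents are assembled by concatenating, in time
order, everything a user wrote.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ForumTables",
    "UserDocument",
    "SchemaError",
    "read_forum_tables",
    "write_forum_tables",
    "assemble_user_documents",
    "filter_active",
    "preprocess",
    "regex_tokenizer",
    "whitespace_tokenizer",
    "load_stopwords",
    "DEFAULT_STOPWORDS",
]

USER_COLUMNS = ("user_id", "name", "sex", "level")
COMMENT_COLUMNS = ("comment_id", "post_id", "floor", "author_id", "content", "time")
REPLY_COLUMNS = ("reply_id", "comment_id", "author_id", "reply_to_whom", "content", "time")

#: Minimal built-in stop-word list used by tests and as a fallback when the
#: caller supplies no list of their own.  Real analyses should pass a
#: language-appropriate file via :func:`load_stopwords`.
DEFAULT_STOPWORDS = frozenset(
    "the a an of to and or is are was in on at for with this that it i you he she we".split()
)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MARKUP_RE = re.compile(r"<[^>]{0,100}>")
# Latin/digit runs and contiguous CJK runs are kept whole: Chinese input is
# expected pre-segmented (whitespace-delimited); plug in a dictionary
# segmenter via the ``tokenizer`` argument for raw unsegmented text.
_TOKEN_RE = re.compile(r"[a-z0-9_]+|[一-鿿]+")


class SchemaError(ValueError):
    """A table file is missing a mandatory column."""


@dataclass
class ForumTables:
    """The three forum tables plus a per-table count of dropped rows."""

    users: pd.DataFrame
    comments: pd.DataFrame
    replies: pd.DataFrame
    n_bad_rows: dict[str, int] = field(default_factory=lambda: {"users": 0, "comments": 0, "replies": 0})

    def __post_init__(self) -> None:
        for frame, cols, name in (
            (self.users, USER_COLUMNS, "users"),
            (self.comments, COMMENT_COLUMNS, "comments"),
            (self.replies, REPLY_COLUMNS, "replies"),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise SchemaError(f"{name} table is missing column(s) {missing}")


@dataclass
class UserDocument:
    """All text authored by one user, concatenated in time order."""

    user_id: str
    raw_text: str
    tokens: list[str]
    n_posts: int


def _detect_sep(path: Path) -> str:
    header = path.open(encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path, columns: Sequence[str], name: str, sep: str | None) -> tuple[pd.DataFrame, int]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    frame = pd.read_csv(path, sep=sep or _detect_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name} table {path} is missing column(s) {missing}")

    bad = pd.Series(False, index=frame.index)
    id_cols = [c for c in columns if c.endswith("_id") or c == "reply_to_whom"]
    for col in id_cols:
        bad |= frame[col].str.strip() == ""
    if "level" in columns:
        level = pd.to_numeric(frame["level"], errors="coerce")
        bad |= level.isna() | (level < 0)
        frame["level"] = level
    if "floor" in columns:
        floor = pd.to_numeric(frame["floor"], errors="coerce")
        bad |= floor.isna() | (floor < 1)
        frame["floor"] = floor
    if "time" in columns:
        time = pd.to_datetime(frame["time"], errors="coerce", format="mixed")
        bad |= time.isna()
        frame["time"] = time

    n_bad = int(bad.sum())
    frame = frame.loc[~bad].reset_index(drop=True)
    if "level" in frame.columns:
        frame["level"] = frame["level"].astype(int)
    if "floor" in frame.columns:
        frame["floor"] = frame["floor"].astype(int)
    return frame, n_bad


def read_forum_tables(
    users_path: str | Path,
    comments_path: str | Path,
    replies_path: str | Path,
    sep: str | None = None,
) -> ForumTables:
    """Read the three forum tables from delimited text files.

    The delimiter is auto-detected from each header line unless ``sep`` is
    given.  Rows whose mandatory fields cannot be parsed (blank identifiers,
    non-numeric floor/level, unparseable timestamps) are dropped and counted
    in :attr:`ForumTables.n_bad_rows`, never silently discarded.

    Raises
    ------
    FileNotFoundError
        If any of the three files does not exist.
    SchemaError
        If a file lacks one of its mandatory columns.
    """
    users, bad_u = _read_table(users_path, USER_COLUMNS, "users", sep)
    comments, bad_c = _read_table(comments_path, COMMENT_COLUMNS, "comments", sep)
    replies, bad_r = _read_table(replies_path, REPLY_COLUMNS, "replies", sep)
    return ForumTables(users, comments, replies, {"users": bad_u, "comments": bad_c, "replies": bad_r})


def write_forum_tables(tables: ForumTables, out_dir: str | Path, sep: str = "\t") -> dict[str, Path]:
    """Write the three tables under ``out_dir`` as ``users/comments/replies.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if sep == "\t" else "csv"
    paths = {}
    for name, frame in (("users", tables.users), ("comments", tables.comments), ("replies", tables.replies)):
        frame = frame.copy()
        if "time" in frame.columns:
            frame["time"] = pd.to_datetime(frame["time"]).dt.strftime("%Y-%m-%d %H:%M:%S")
        path = out_dir / f"{name}.{ext}"
        frame.to_csv(path, sep=sep, index=False)
        paths[name] = path
    return paths


def whitespace_tokenizer(text: str) -> list[str]:
    """Split on whitespace only; suitable for pre-segmented or Latin text."""
    return text.split()


def regex_tokenizer(text: str) -> list[str]:
    """Default segmenter: lower-cases and keeps Latin/digit words and
    contiguous CJK runs whole (CJK input is expected pre-segmented)."""
    return _TOKEN_RE.findall(text.lower())


def preprocess(
    raw_text: str,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    tokenizer: Callable[[str], list[str]] | None = None,
) -> list[str]:
    """Clean and segment one document into an ordered token list.

    URLs and angle-bracket markup are stripped before segmentation;
    stop-words are removed afterwards.  An empty input yields an empty list.
    """
    tokenizer = tokenizer or regex_tokenizer
    stopwords = frozenset(stopwords)
    text = _URL_RE.sub(" ", raw_text)
    text = _MARKUP_RE.sub(" ", text)
    return [tok for tok in tokenizer(text) if tok not in stopwords]


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stop-word file, one word per line, ignoring blanks."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(w.strip() for w in lines if w.strip())


def assemble_user_documents(
    tables: ForumTables,
    include_replies: bool = True,
    include_followup_comments: bool = True,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    tokenizer: Callable[[str], list[str]] | None = None,
) -> dict[str, UserDocument]:
    """Concatenate each user's authored text into one document.

    ``raw_text`` joins, in time order, the content the user authored:
    always their thread-opening (floor-1) comments, plus follow-up comments
    in other threads and replies unless the corresponding flag is off.
    ``n_posts`` counts the distinct threads the user opened, i.e. the
    distinct ``post_id`` values whose floor-1 comment they wrote.  Users who
    authored nothing are absent from the result.
    """
    comments = tables.comments
    if not include_followup_comments:
        comments = comments.loc[comments["floor"] == 1]
    pieces = [comments[["author_id", "content", "time"]]]
    if include_replies:
        pieces.append(tables.replies[["author_id", "content", "time"]])
    authored = pd.concat(pieces, ignore_index=True)
    authored = authored.sort_values("time", kind="stable")

    openers = tables.comments.loc[tables.comments["floor"] == 1]
    n_posts: Mapping[str, int] = openers.groupby("author_id")["post_id"].nunique().to_dict()

    documents: dict[str, UserDocument] = {}
    for author, group in authored.groupby("author_id", sort=True):
        text = " ".join(str(c) for c in group["content"] if str(c).strip())
        documents[author] = UserDocument(
            user_id=author,
            raw_text=text,
            tokens=preprocess(text, stopwords=stopwords, tokenizer=tokenizer),
            n_posts=int(n_posts.get(author, 0)),
        )
    return documents


def filter_active(documents: Mapping[str, UserDocument], min_posts: int = 3) -> dict[str, UserDocument]:
    """Keep users who opened strictly more than ``min_posts`` threads.

    The default of 3 reproduces the usual "active user" cut: a user survives
    with at least four authored posts.
    """
    if min_posts < 0:
        raise ValueError("min_posts must be non-negative")
    return {uid: doc for uid, doc in documents.items() if doc.n_posts > min_posts}
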