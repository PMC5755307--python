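"""Dictionary-based sentiment scoring of user documents.

Each lexicon word carries a signed integer intensity: positive words score
1..5, negative words -1..-5.  A document's positive (negative) score is the
intensity-weighted count of positive (negative) lexicon words it contains;
the document is labelled positive when the positive sum strictly exceeds
the negative sum, negative otherwise, and neutral only when it contains no
sentiment words at all.  Community sentiment is the share of positive and
negative users among the non-neutral members.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import logging

__all__ = [
    "SentimentLexicon",
    "DocumentSentiment",
    "load_lexicon",
    "score_document",
    "community_sentiment",
    "evaluate_sentiment",
]

logger = logging.getLogger(__name__)


@dataclass
class SentimentLexicon:
    """Word -> signed intensity map; intensities in {-5..-1, 1..5}."""

    entries: dict[str, int]

    def __post_init__(self) -> None:
        for word, intensity in self.entries.items():
            if not 1 <= abs(intensity) <= 5:
                raise ValueError(f"intensity for {word!r} outside +/-1..5: {intensity}")


@dataclass
class DocumentSentiment:
    user_id: str
    pos_sum: int
    neg_sum: int  # absolute value of the negative intensity total
    label: str  # "positive" | "negative" | "neutral"


def load_lexicon(paths: Iterable[str | Path] | str | Path) -> SentimentLexicon:
    """Load and merge one or more lexicon files (``word<TAB>intensity`` lines).

    When two files disagree on a word, the entry with the larger absolute
    intensity wins and the conflict is logged.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    entries: dict[str, int] = {}
    for path in paths:
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                word, raw = line.split("\t") if "\t" in line else line.split()
                intensity = int(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed lexicon line {line!r}") from exc
            if intensity == 0 or abs(intensity) > 5:
                raise ValueError(f"{path}:{lineno}: intensity {intensity} outside +/-1..5")
            if word in entries and entries[word] != intensity:
                keep = intensity if abs(intensity) > abs(entries[word]) else entries[word]
                logger.warning(
                    "lexicon conflict for %r: %d vs %d, keeping %d", word, entries[word], intensity, keep
                )
                entries[word] = keep
            else:
                entries[word] = intensity
    return SentimentLexicon(entries)


def score_document(tokens: Sequence[str], lexicon: SentimentLexicon, user_id: str = "") -> DocumentSentiment:
    """Intensity-weighted sentiment sums and the resulting document label.

    Every occurrence counts (frequency x intensity).  Positive requires the
    positive sum to strictly exceed the negative sum; a nonzero tie is
    labelled negative, and only a document with no sentiment words at all
    is neutral.
    """
    pos = neg = 0
    for tok in tokens:
        intensity = lexicon.entries.get(tok)
        if intensity is None:
            continue
        if intensity > 0:
            pos += intensity
        else:
            neg -= intensity
    if pos == 0 and neg == 0:
        label = "neutral"
    elif pos > neg:
        label = "positive"
    else:
        label = "negative"
    return DocumentSentiment(user_id=user_id, pos_sum=pos, neg_sum=neg, label=label)


def community_sentiment(
    members: Iterable[str], sentiments: Mapping[str, DocumentSentiment]
) -> dict[str, float | int | None]:
    """Positive/negative user proportions among non-neutral members.

    Neutral members are excluded from the proportions (and counted
    separately); when every member is neutral the proportions are undefined
    and returned as ``None``.
    """
    labels = [sentiments[m].label for m in members if m in sentiments]
    n_pos = labels.count("positive")
    n_neg = labels.count("negative")
    n_neutral = labels.count("neutral")
    scored = n_pos + n_neg
    if scored == 0:
        return {"positive": None, "negative": None, "n_neutral": n_neutral, "n_scored": 0}
    return {
        "positive": n_pos / scored,
        "negative": n_neg / scored,
        "n_neutral": n_neutral,
        "n_scored": scored,
    }


def evaluate_sentiment(
    predictions: Mapping[str, str], reference: Mapping[str, str]
) -> dict[str, dict[str, float | None]]:
    """Per-class precision and recall of predicted labels against a reference.

    Degenerate cells are returned as ``None``: precision when the class is
    never predicted, recall when it is absent from the reference.
    """
    if not reference:
        raise ValueError("empty reference labels")
    if set(predictions) != set(reference):
        raise ValueError("predictions and reference must cover the same ids")
    classes = sorted(set(reference.values()) | set(predictions.values()))
    result = {}
    for cls in classes:
        tp = sum(1 for i in reference if predictions[i] == cls and reference[i] == cls)
        fp = sum(1 for i in reference if predictions[i] == cls and reference[i] != cls)
        fn = sum(1 for i in reference if predictions[i] != cls and reference[i] == cls)
        result[cls] = {
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
        }
    return result
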