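"""Topic-quality evaluation by direct string matching.

A ranked topic list is scored against an unordered human gold standard by
exact (case-insensitive) full-string matches, counted separately for ranks
1-5 and ranks 6-10; topics below rank 10 are considered too far down the
list to count.  Corpus quality is the plain sum of per-document counts.
Exact matching means a multiword gold topic ("natural gas") can never match
a single-word item; such topics simply score as unmatched.  No precision /
recall / F1-style scores are computed: with an open-ended, varying number
of topics per document those measures behave erratically, whereas a match
count states directly how many gold topics were recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .core import TopicRanking

__all__ = [
    "MatchCounts",
    "count_matches",
    "aggregate",
    "load_gold_json",
    "load_gold_tsv",
]


@dataclass(frozen=True)
class MatchCounts:
    """Exact-match counts for ranks 1-5 (`top5`) and 6-10 (`next5`)."""

    top5: int = 0
    next5: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.top5 <= 5 and 0 <= self.next5 <= 5):
            raise ValueError("match counts must lie in [0, 5]")

    @property
    def top10(self) -> int:
        return self.top5 + self.next5

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.top5 + other.top5, self.next5 + other.next5)


def count_matches(ranking: TopicRanking, gold: set[str]) -> MatchCounts:
    """Count exact string matches of ranks 1-5 and 6-10 against *gold*.

    Comparison is case-insensitive full-string equality.  Rankings shorter
    than 5 or 10 use whatever ranks exist; ranks beyond 10 are ignored.
    """
    gold_lower = {g.lower() for g in gold}
    items = [item.lower() for item, _ in ranking[:10]]
    top5 = sum(1 for item in set(items[:5]) if item in gold_lower)
    next5 = sum(1 for item in set(items[5:10]) if item in gold_lower)
    return MatchCounts(top5=top5, next5=next5)


def aggregate(counts: list[MatchCounts]) -> tuple[int, int]:
    """Component-wise totals over per-document counts: (total_top5, total_next5)."""
    return (sum(c.top5 for c in counts), sum(c.next5 for c in counts))


def load_gold_json(path: str | Path) -> dict[str, set[str]]:
    """Load a gold standard: ``{"doc_id": ["topic", ...], ...}`` (lowercased sets)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValueError("gold standard JSON must map document ids to topic lists")
    return {doc: {str(t).lower() for t in topics} for doc, topics in data.items()}


def load_gold_tsv(path: str | Path) -> dict[str, set[str]]:
    """Load a gold standard from TSV lines ``doc_id<TAB>topic`` ('#' comments allowed)."""
    gold: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            doc, topic = line.split("\t", 1)
        except ValueError as exc:
            raise ValueError(f"malformed gold TSV line: {line!r}") from exc
        gold.setdefault(doc.strip(), set()).add(topic.strip().lower())
    return gold
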