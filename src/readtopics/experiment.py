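"""Parameter sweeps over STM capacity and decay rate.

For every (stm_capacity, decay_rate) pair in a grid, every document in a
corpus is processed, its top-10 topics are matched against the gold
standard, and the match counts are summed over documents — separately for
ranks 1-5 and 6-10.  The no-decay / no-STM configuration is computed once
as the upper-quality control baseline.  Results go to a tidy CSV (one row
per grid cell, the baseline row flagged) that round-trips through
:func:`read_results`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import ReadParams, process_document
from .evaluation import MatchCounts, aggregate, count_matches
from .lexicon import EMPTY_WORDLIST, LexiconBackend, WordList, normalize_document

__all__ = ["SweepGrid", "SweepResult", "run_sweep", "write_results", "read_results", "load_corpus_dir"]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["stm", "decay", "total_top5", "total_next5", "baseline"]


@dataclass(frozen=True)
class SweepGrid:
    """The grid of STM capacities and decay rates to sweep.

    Defaults mirror the published experimental ranges: capacities 0-10 in
    steps of two, decay rates 0 (the no-decay baseline) through 25.
    """

    stm_values: tuple[int, ...] = (0, 2, 4, 6, 8, 10)
    decay_values: tuple[float, ...] = tuple(range(0, 26))

    def __post_init__(self) -> None:
        if not self.stm_values or not self.decay_values:
            raise ValueError("grid axes must be non-empty")
        if any(s < 0 for s in self.stm_values) or any(d < 0 for d in self.decay_values):
            raise ValueError("grid values must be >= 0")
        object.__setattr__(self, "stm_values", tuple(self.stm_values))
        object.__setattr__(self, "decay_values", tuple(float(d) for d in self.decay_values))


@dataclass
class SweepResult:
    """One row of totals per grid cell, plus the control-baseline totals."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))
    baseline_top5: int = 0
    baseline_next5: int = 0

    def cell(self, stm: int, decay: float) -> tuple[int, int]:
        """(total_top5, total_next5) at a grid cell."""
        row = self.table[(self.table.stm == stm) & (self.table.decay == decay)]
        if row.empty:
            raise KeyError(f"no sweep cell (stm={stm}, decay={decay})")
        return int(row.total_top5.iloc[0]), int(row.total_next5.iloc[0])


def _corpus_totals(
    documents: dict[str, list[str]],
    gold: dict[str, set[str]],
    params: ReadParams,
    backend: LexiconBackend,
    stopwords: WordList,
    undesirable: WordList,
    cache: dict[str, tuple[str, ...]],
) -> tuple[int, int]:
    counts: list[MatchCounts] = []
    for doc_id, tokens in documents.items():
        if doc_id not in gold:
            logger.warning("document %s has no gold-standard entry; skipped", doc_id)
            continue
        ranking = process_document(
            tokens, params, backend, stopwords, undesirable, k=10, lookup_cache=cache
        )
        counts.append(count_matches(ranking, gold[doc_id]))
    return aggregate(counts)


def run_sweep(
    documents: dict[str, list[str]],
    gold: dict[str, set[str]],
    grid: SweepGrid,
    backend: LexiconBackend,
    stopwords: WordList = EMPTY_WORDLIST,
    undesirable: WordList = EMPTY_WORDLIST,
    decay_law: str = "linear",
) -> SweepResult:
    """Evaluate every grid cell on *documents* (normalized token lists).

    The (stm=0, decay=0) control baseline is always computed, whether or
    not the grid contains it.  Per-word lexicon lookups are memoized across
    the whole sweep; results are deterministic given identical inputs.
    """
    cache: dict[str, tuple[str, ...]] = {}
    base_params = ReadParams(stm_capacity=0, decay_rate=0.0, decay_law=decay_law)
    baseline_top5, baseline_next5 = _corpus_totals(
        documents, gold, base_params, backend, stopwords, undesirable, cache
    )
    rows = []
    for stm in grid.stm_values:
        for decay in grid.decay_values:
            if stm == 0 and decay == 0.0:
                top5, next5 = baseline_top5, baseline_next5
            else:
                params = ReadParams(stm_capacity=stm, decay_rate=decay, decay_law=decay_law)
                top5, next5 = _corpus_totals(
                    documents, gold, params, backend, stopwords, undesirable, cache
                )
            rows.append(
                {
                    "stm": stm,
                    "decay": decay,
                    "total_top5": top5,
                    "total_next5": next5,
                    "baseline": int(stm == 0 and decay == 0.0),
                }
            )
            logger.info("stm=%d decay=%g: top5=%d next5=%d", stm, decay, top5, next5)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return SweepResult(table=table, baseline_top5=baseline_top5, baseline_next5=baseline_next5)


def write_results(result: SweepResult, path: str | Path, header_comment: str | None = None) -> Path:
    """Write a sweep result as CSV (optionally with '#' metadata comments)."""
    path = Path(path)
    lines = []
    if header_comment:
        lines.extend(f"# {line}" for line in header_comment.splitlines())
    lines.append(f"# baseline_top5={result.baseline_top5} baseline_next5={result.baseline_next5}")
    csv_body = result.table.to_csv(index=False, lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + csv_body, encoding="utf-8")
    return path


def read_results(path: str | Path) -> SweepResult:
    """Read a CSV written by :func:`write_results` back into a SweepResult."""
    path = Path(path)
    baseline_top5 = baseline_next5 = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("# baseline_top5="):
            parts = dict(p.split("=") for p in line[2:].split())
            baseline_top5 = int(parts["baseline_top5"])
            baseline_next5 = int(parts["baseline_next5"])
    table = pd.read_csv(path, comment="#")
    return SweepResult(table=table, baseline_top5=baseline_top5, baseline_next5=baseline_next5)


def load_corpus_dir(
    path: str | Path,
    backend: LexiconBackend,
    stopwords: WordList = EMPTY_WORDLIST,
) -> dict[str, list[str]]:
    """Read every .txt file under *path* and normalize it into tokens.

    The document id is the file stem; files are read in sorted order for
    deterministic iteration.
    """
    path = Path(path)
    documents: dict[str, list[str]] = {}
    for txt in sorted(path.glob("*.txt")):
        documents[txt.stem] = normalize_document(
            txt.read_text(encoding="utf-8"), backend, stopwords
        )
    return documents
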