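"""The retrieval–activation–decay reading loop.

For each word read from a document, in order:

1. **Retrieval** — the word's items (its long-term-memory "ideas") are
   looked up in the lexicon.
2. **Activation** — each retrieved item's activation increases by a fixed
   increment (default 1), and the step index of its first activation is
   recorded for deterministic tie-breaking.
3. **Attention** — the word enters a bounded short-term-memory (STM)
   buffer.  A word already present is *rehearsed* (moved to most-recent);
   when the buffer is full the least-recently-rehearsed word is evicted.
4. **Decay** — every item NOT retrieved by any word currently in STM loses
   activation (linear law: delta = 1/eta per step for decay rate eta > 0;
   eta = 0 disables decay), floored at the resting value 0.

After the last word, items are ranked by decreasing activation; the most
activated items are the document's topics.  With no STM and no decay the
loop reduces exactly to counting item frequencies, which serves as the
upper-quality control baseline.

The decay-rate convention follows the model's parameter sweep: *low* eta
means *rapid* decay (a unit of activation fully decays in eta word-steps),
and decay ticks once per word read.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field

from .lexicon import (
    EMPTY_WORDLIST,
    LexiconBackend,
    WordList,
    lookup_items,
)

__all__ = [
    "ReadParams",
    "STMBuffer",
    "ActivationState",
    "TopicRanking",
    "stm_update",
    "decay_step",
    "rank_topics",
    "process_document",
    "baseline_frequency",
]

DECAY_LAWS = ("linear", "exponential")


@dataclass(frozen=True)
class ReadParams:
    """Model parameters.

    stm_capacity
        Number of words the short-term-memory buffer holds (0 disables it).
    decay_rate
        Decay rate eta >= 0.  Low values mean rapid decay; 0 means no decay.
        Under the linear law an unprotected item loses 1/eta activation
        units per word read.
    top_k
        Ranking cutoffs reported by experiments (default (5, 10)).
    decay_law
        "linear" (default) or "exponential" (a <- a * exp(-1/eta)).
    activation_increment
        Activation added per retrieval (default 1.0).
    """

    stm_capacity: int = 0
    decay_rate: float = 0.0
    top_k: tuple[int, ...] = (5, 10)
    decay_law: str = "linear"
    activation_increment: float = 1.0

    def __post_init__(self) -> None:
        if self.stm_capacity < 0:
            raise ValueError("stm_capacity must be >= 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.activation_increment <= 0:
            raise ValueError("activation_increment must be > 0")
        if self.decay_law not in DECAY_LAWS:
            raise ValueError(f"decay_law must be one of {DECAY_LAWS}")
        ks = tuple(self.top_k)
        if not ks or any(k <= 0 for k in ks) or list(ks) != sorted(set(ks)):
            raise ValueError("top_k must be strictly increasing positive integers")
        object.__setattr__(self, "top_k", ks)

    @property
    def delta(self) -> float:
        """Linear per-step decay magnitude delta(eta) = 1/eta (0 when eta = 0)."""
        return 0.0 if self.decay_rate == 0 else 1.0 / self.decay_rate


class STMBuffer:
    """Bounded recency-ordered word buffer (least-recently-rehearsed first)."""

    def __init__(self, capacity: int) -> None:
        if capacity < 0:
            raise ValueError("capacity must be >= 0")
        self.capacity = capacity
        self._slots: OrderedDict[str, None] = OrderedDict()

    @property
    def slots(self) -> tuple[str, ...]:
        return tuple(self._slots)

    def __contains__(self, word: str) -> bool:
        return word in self._slots

    def __len__(self) -> int:
        return len(self._slots)


def stm_update(buffer: STMBuffer, word: str) -> str | None:
    """Insert or rehearse *word*; return the evicted word, if any.

    Capacity 0 is a degenerate no-op (the word never enters).  A word
    already present is moved to the most-recent slot (rehearsal).  When a
    new word overflows the buffer, the word unrehearsed for longest is
    evicted and returned.
    """
    if buffer.capacity == 0:
        return None
    if word in buffer._slots:
        buffer._slots.move_to_end(word)
        return None
    buffer._slots[word] = None
    if len(buffer._slots) > buffer.capacity:
        evicted, _ = buffer._slots.popitem(last=False)
        return evicted
    return None


@dataclass
class ActivationState:
    """Per-item activation levels plus first-activation bookkeeping."""

    activation: dict[str, float] = field(default_factory=dict)
    first_seen: dict[str, int] = field(default_factory=dict)

    def activate(self, items: tuple[str, ...], step: int, increment: float = 1.0) -> None:
        for item in items:
            if item not in self.first_seen:
                self.first_seen[item] = step
            self.activation[item] = self.activation.get(item, 0.0) + increment


def decay_step(state: ActivationState, protected_items: set[str], delta: float) -> ActivationState:
    """Apply one linear decay tick in place: unprotected items lose *delta*, floored at 0."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0:
        return state
    act = state.activation
    for item, value in act.items():
        if value > 0 and item not in protected_items:
            act[item] = value - delta if value > delta else 0.0
    return state


def _exponential_decay_step(state: ActivationState, protected_items: set[str], eta: float) -> None:
    factor = math.exp(-1.0 / eta)
    act = state.activation
    for item, value in act.items():
        if value > 0 and item not in protected_items:
            act[item] = value * factor


#: A ranking is a list of (item, activation) pairs in decreasing activation,
#: ties broken by earlier first activation, then lexicographically.
TopicRanking = list[tuple[str, float]]


def rank_topics(state: ActivationState, k: int | None = None) -> TopicRanking:
    """Top-*k* positively activated items; ``k=None`` returns the full ranking."""
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    first = state.first_seen
    ranked = sorted(
        ((item, a) for item, a in state.activation.items() if a > 0),
        key=lambda pair: (-pair[1], first[pair[0]], pair[0]),
    )
    return ranked if k is None else ranked[:k]


def process_document(
    tokens: list[str],
    params: ReadParams,
    backend: LexiconBackend,
    stopwords: WordList = EMPTY_WORDLIST,
    undesirable: WordList = EMPTY_WORDLIST,
    k: int | None = None,
    lookup_cache: dict[str, tuple[str, ...]] | None = None,
) -> TopicRanking:
    """Run the full reading loop over normalized *tokens* and rank the topics.

    *lookup_cache* optionally memoizes per-word item lists across documents
    (lexicon lookups dominate runtime in sweeps); it never changes results.
    """
    cache = lookup_cache if lookup_cache is not None else {}
    state = ActivationState()
    stm = STMBuffer(params.stm_capacity)
    # Item sets of the words currently in STM, for the protected-set union.
    decaying = params.decay_rate > 0

    for step, word in enumerate(tokens):
        items = cache.get(word)
        if items is None:
            items = lookup_items(word, backend, stopwords, undesirable).items
            cache[word] = items
        state.activate(items, step, params.activation_increment)
        stm_update(stm, word)
        if decaying:
            protected: set[str] = set()
            for w in stm.slots:
                protected.update(cache.get(w, ()))
            if params.decay_law == "linear":
                decay_step(state, protected, params.delta)
            else:
                _exponential_decay_step(state, protected, params.decay_rate)
    return rank_topics(state, k)


def baseline_frequency(
    tokens: list[str],
    backend: LexiconBackend,
    stopwords: WordList = EMPTY_WORDLIST,
    undesirable: WordList = EMPTY_WORDLIST,
    k: int | None = None,
    increment: float = 1.0,
    lookup_cache: dict[str, tuple[str, ...]] | None = None,
) -> TopicRanking:
    """No-decay, no-STM control: rank items by raw retrieval frequency.

    Implemented independently of :func:`process_document` (a plain counting
    pass) so the two routes can cross-check each other; tie-breaking is
    identical (count desc, first occurrence asc, item asc).
    """
    cache = lookup_cache if lookup_cache is not None else {}
    counts: dict[str, float] = {}
    first: dict[str, int] = {}
    for step, word in enumerate(tokens):
        items = cache.get(word)
        if items is None:
            items = lookup_items(word, backend, stopwords, undesirable).items
            cache[word] = items
        for item in items:
            if item not in first:
                first[item] = step
            counts[item] = counts.get(item, 0.0) + increment
    ranked = sorted(counts.items(), key=lambda pair: (-pair[1], first[pair[0]], pair[0]))
    return ranked if k is None else ranked[:k]
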