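"""Synthetic corpora with planted recurring themes.

Real evaluations of the model need a dictionary, documents and human gold
standards.  This module fabricates all three at a controlled, miniature
scale so every other module is testable without downloads:

* a toy lexicon in which the words of each *theme* share a few common items
  (the planted topics) while *distractor* words carry pairwise-disjoint
  items — mimicking how semantically related words in a text activate the
  same long-term-memory ideas while unrelated words do not;
* documents that draw tokens i.i.d., choosing a word from the document's
  theme with fixed probability and a distractor otherwise;
* a gold standard assigning each document exactly its theme's shared items.

Everything is deterministic under the spec's seed.  Token names are plain
alphanumeric strings so documents round-trip through text normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lexicon import ToyLexicon

__all__ = ["SynthSpec", "SyntheticCorpus", "generate_lexicon", "generate_corpus", "write_corpus"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic generator.

    Defaults are the regression-corpus conditions used throughout the test
    suite: 3 themes of 4 words each, 2 shared items per theme, 60% theme
    token probability, 200-token documents, 30 documents.
    """

    n_themes: int = 3
    n_theme_words: int = 4          # words per theme
    n_distractor_words: int = 40
    items_per_word: int = 6         # total items per word, shared ones included
    shared_items_per_theme: int = 2
    doc_length: int = 200
    theme_word_probability: float = 0.6
    n_docs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_themes,
            self.n_theme_words,
            self.n_distractor_words,
            self.items_per_word,
            self.shared_items_per_theme,
            self.doc_length,
            self.n_docs,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all synthetic-spec counts must be positive")
        if not 0.0 < self.theme_word_probability < 1.0:
            raise ValueError("theme_word_probability must lie strictly in (0, 1)")
        if self.shared_items_per_theme > self.items_per_word:
            raise ValueError(
                "shared_items_per_theme cannot exceed items_per_word "
                f"({self.shared_items_per_theme} > {self.items_per_word})"
            )


@dataclass
class SyntheticCorpus:
    """Generated documents (token lists), gold standard, and the lexicon used."""

    documents: dict[str, list[str]] = field(default_factory=dict)
    gold: dict[str, set[str]] = field(default_factory=dict)
    lexicon: ToyLexicon = field(default_factory=ToyLexicon)
    spec: SynthSpec = field(default_factory=SynthSpec)


def theme_words(spec: SynthSpec, theme: int) -> list[str]:
    return [f"t{theme}w{j}" for j in range(spec.n_theme_words)]


def shared_items(spec: SynthSpec, theme: int) -> list[str]:
    return [f"topic{theme}x{s}" for s in range(spec.shared_items_per_theme)]


def distractor_words(spec: SynthSpec) -> list[str]:
    return [f"d{j}" for j in range(spec.n_distractor_words)]


def generate_lexicon(spec: SynthSpec) -> ToyLexicon:
    """Build the planted-theme toy lexicon.

    Every word of theme *t* lists that theme's shared items first, followed
    by its own private items; distractor words get pairwise-disjoint item
    lists.  The construction is deterministic (the seed only affects corpus
    sampling).
    """
    entries: dict[str, list[str]] = {}
    n_private = spec.items_per_word - spec.shared_items_per_theme
    for t in range(spec.n_themes):
        shared = shared_items(spec, t)
        for j, word in enumerate(theme_words(spec, t)):
            entries[word] = shared + [f"t{t}w{j}p{k}" for k in range(n_private)]
    for j, word in enumerate(distractor_words(spec)):
        entries[word] = [f"d{j}i{k}" for k in range(spec.items_per_word)]
    return ToyLexicon(entries=entries, morphology={})


def generate_corpus(spec: SynthSpec) -> SyntheticCorpus:
    """Sample documents and their gold standards under *spec*.

    Each document is assigned a theme (round-robin so every theme is
    represented evenly); tokens are drawn i.i.d. — a uniformly chosen word
    of the document's theme with probability ``theme_word_probability``,
    else a uniformly chosen distractor.  The gold standard of a document is
    exactly its theme's shared items.
    """
    rng = np.random.default_rng(spec.seed)
    lexicon = generate_lexicon(spec)
    distractors = distractor_words(spec)
    documents: dict[str, list[str]] = {}
    gold: dict[str, set[str]] = {}
    for d in range(spec.n_docs):
        theme = d % spec.n_themes
        words = theme_words(spec, theme)
        is_theme = rng.random(spec.doc_length) < spec.theme_word_probability
        theme_idx = rng.integers(0, len(words), size=spec.doc_length)
        distractor_idx = rng.integers(0, len(distractors), size=spec.doc_length)
        tokens = [
            words[theme_idx[i]] if is_theme[i] else distractors[distractor_idx[i]]
            for i in range(spec.doc_length)
        ]
        doc_id = f"doc{d:03d}"
        documents[doc_id] = tokens
        gold[doc_id] = set(shared_items(spec, theme))
    return SyntheticCorpus(documents=documents, gold=gold, lexicon=lexicon, spec=spec)


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> Path:
    """Write lexicon.json, gold.json and docs/<id>.txt under *outdir*."""
    outdir = Path(outdir)
    (outdir / "docs").mkdir(parents=True, exist_ok=True)
    corpus.lexicon.to_json(outdir / "lexicon.json")
    gold_payload = {doc: sorted(topics) for doc, topics in sorted(corpus.gold.items())}
    (outdir / "gold.json").write_text(
        json.dumps(gold_payload, indent=1, sort_keys=True), encoding="utf-8"
    )
    for doc_id, tokens in sorted(corpus.documents.items()):
        (outdir / "docs" / f"{doc_id}.txt").write_text(" ".join(tokens) + "\n", encoding="utf-8")
    return outdir
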