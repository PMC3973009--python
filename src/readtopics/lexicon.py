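"""Lexical knowledge backends: the long-term-memory surrogate.

A lexicon maps a document word to *items* — single words drawn from the
word's dictionary entry (synonym-set members, definition words, direct
hypernyms and their definitions, example glosses).  Items stand in for the
loosely organized "ideas" a reader's long-term memory would activate upon
reading the word.  No sense disambiguation is performed: the items of every
noun sense are returned (exhaustive access), and items are deliberately NOT
stemmed or otherwise normalized — they are raw dictionary words.

Document words, by contrast, ARE normalized (lowercased, punctuation
stripped, stop words removed, mapped to their dictionary base form when the
backend knows one).

Three backends are provided:

* :class:`ToyLexicon` — a flat JSON mapping ``word -> [items]``, for
  synthetic corpora and tests.
* :class:`SenseLexicon` — structured WordNet-style noun sense records
  (synonyms / definition / examples / hypernyms) from which items are
  extracted in reading order.
* :class:`WordNetLexicon` — an adapter over an installed NLTK WordNet
  corpus (optional; only useful where nltk and its corpus are available).
"""

from __future__ import annotations

import json
import re
from collections.abc import Iterable
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "WordList",
    "LexiconEntry",
    "LexiconBackend",
    "ToyLexicon",
    "SenseLexicon",
    "WordNetLexicon",
    "tokenize",
    "lookup_items",
    "normalize_document",
    "load_wordlist",
    "load_lexicon",
    "default_stopwords",
    "default_undesirable",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase *text* and split it on every non-alphanumeric character."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class WordList:
    """A set of lowercase words with a role ("stopwords" or "undesirable")."""

    words: frozenset[str] = frozenset()
    role: str = "stopwords"

    def __post_init__(self) -> None:
        for w in self.words:
            if w != w.lower() or any(c.isspace() for c in w):
                raise ValueError(f"word list entries must be lowercase tokens: {w!r}")

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)

    @classmethod
    def from_words(cls, words: Iterable[str], role: str = "stopwords") -> "WordList":
        return cls(frozenset(w.strip().lower() for w in words if w.strip()), role)


EMPTY_WORDLIST = WordList(frozenset(), "stopwords")


@dataclass(frozen=True)
class LexiconEntry:
    """A word together with its filtered, deduplicated item list.

    Item order is the order of first occurrence in the concatenated sense
    text, so earlier senses contribute earlier items.
    """

    word: str
    items: tuple[str, ...] = ()


class LexiconBackend:
    """Interface every lexicon backend implements.

    ``raw_items`` returns the unfiltered item stream (duplicates and stop
    words included) in dictionary-entry order; filtering and deduplication
    are applied uniformly by :func:`lookup_items`.
    """

    kind: str = "abstract"

    def raw_items(self, word: str) -> list[str]:
        raise NotImplementedError

    def has_entry(self, word: str) -> bool:
        raise NotImplementedError

    def base_form(self, word: str) -> str | None:
        """Dictionary base form of a surface word, or None if unknown."""
        return None


@dataclass
class ToyLexicon(LexiconBackend):
    """Flat JSON lexicon: ``{"entries": {word: [items]}, "morphology": {surface: base}}``."""

    entries: dict[str, list[str]] = field(default_factory=dict)
    morphology: dict[str, str] = field(default_factory=dict)
    kind: str = "toy-json"

    @classmethod
    def from_json(cls, path: str | Path) -> "ToyLexicon":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(entries=dict(data.get("entries", {})), morphology=dict(data.get("morphology", {})))

    def to_json(self, path: str | Path) -> None:
        payload = {"entries": self.entries, "morphology": self.morphology}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")

    def raw_items(self, word: str) -> list[str]:
        out: list[str] = []
        for item in self.entries.get(word, []):
            out.extend(tokenize(item))
        return out

    def has_entry(self, word: str) -> bool:
        return word in self.entries

    def base_form(self, word: str) -> str | None:
        return self.morphology.get(word)


@dataclass
class SenseLexicon(LexiconBackend):
    """WordNet-style structured noun entries.

    JSON schema::

        {"nouns": {word: [sense, ...]}, "morphology": {surface: base}}

    where each sense is ``{"synonyms": [...], "definition": str,
    "examples": [str, ...], "hypernyms": [sense-like, ...]}``.  Multiword
    synonyms ("precious metal") are split into individual tokens.  For each
    sense the item stream is: synonyms, definition words, example-gloss
    words, then each direct hypernym's synonyms, definition and glosses.
    """

    nouns: dict[str, list[dict]] = field(default_factory=dict)
    morphology: dict[str, str] = field(default_factory=dict)
    kind: str = "dictionary"

    @classmethod
    def from_json(cls, path: str | Path) -> "SenseLexicon":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(nouns=dict(data.get("nouns", {})), morphology=dict(data.get("morphology", {})))

    @staticmethod
    def _sense_tokens(sense: dict) -> list[str]:
        out: list[str] = []
        for syn in sense.get("synonyms", []):
            out.extend(tokenize(syn))
        out.extend(tokenize(sense.get("definition", "")))
        for gloss in sense.get("examples", []):
            out.extend(tokenize(gloss))
        return out

    def raw_items(self, word: str) -> list[str]:
        out: list[str] = []
        for sense in self.nouns.get(word, []):
            out.extend(self._sense_tokens(sense))
            for hyper in sense.get("hypernyms", []):
                out.extend(self._sense_tokens(hyper))
        return out

    def has_entry(self, word: str) -> bool:
        return word in self.nouns

    def base_form(self, word: str) -> str | None:
        return self.morphology.get(word)


class WordNetLexicon(LexiconBackend):
    """Adapter over an installed NLTK WordNet corpus (noun senses only).

    Requires ``nltk`` with the ``wordnet`` corpus; imported lazily so the
    rest of the package works without it.
    """

    kind = "dictionary"

    def __init__(self) -> None:
        try:
            from nltk.corpus import wordnet  # type: ignore
        except ImportError as exc:  # pragma: no cover - depends on host env
            raise RuntimeError(
                "WordNetLexicon requires nltk with the 'wordnet' corpus installed"
            ) from exc
        self._wn = wordnet

    def _synset_tokens(self, synset) -> list[str]:  # pragma: no cover - env-dependent
        out: list[str] = []
        for lemma in synset.lemma_names():
            out.extend(tokenize(lemma.replace("_", " ")))
        out.extend(tokenize(synset.definition()))
        for gloss in synset.examples():
            out.extend(tokenize(gloss))
        return out

    def raw_items(self, word: str) -> list[str]:  # pragma: no cover - env-dependent
        out: list[str] = []
        for synset in self._wn.synsets(word, pos=self._wn.NOUN):
            out.extend(self._synset_tokens(synset))
            for hyper in synset.hypernyms():
                out.extend(self._synset_tokens(hyper))
        return out

    def has_entry(self, word: str) -> bool:  # pragma: no cover - env-dependent
        return bool(self._wn.synsets(word, pos=self._wn.NOUN))

    def base_form(self, word: str) -> str | None:  # pragma: no cover - env-dependent
        return self._wn.morphy(word, self._wn.NOUN)


def lookup_items(
    word: str,
    backend: LexiconBackend,
    stopwords: WordList = EMPTY_WORDLIST,
    undesirable: WordList = EMPTY_WORDLIST,
) -> LexiconEntry:
    """Return the filtered, deduplicated item list for *word*.

    Items are single lowercase tokens in order of first occurrence across
    all noun senses.  Stop words and undesirable words are removed; items
    are not stemmed.  Unknown words yield an empty entry.
    """
    seen: set[str] = set()
    items: list[str] = []
    for tok in backend.raw_items(word):
        if tok in seen or tok in stopwords or tok in undesirable:
            continue
        seen.add(tok)
        items.append(tok)
    return LexiconEntry(word=word, items=tuple(items))


def normalize_document(
    text: str,
    backend: LexiconBackend,
    stopwords: WordList = EMPTY_WORDLIST,
) -> list[str]:
    """Normalize document text into the token stream the model reads.

    Tokens are lowercased, punctuation is stripped, stop words removed, and
    each remaining token is mapped to its dictionary base form when the
    backend's morphology knows one.  Words without a dictionary entry are
    kept: they still occupy a reading step (and a short-term-memory slot)
    even though they retrieve no items.
    """
    out: list[str] = []
    for tok in tokenize(text):
        if tok in stopwords:
            continue
        base = backend.base_form(tok)
        out.append(base if base else tok)
    return out


def load_wordlist(path: str | Path, role: str = "stopwords") -> WordList:
    """Load a word list: one word per line, '#' comments, deduplicated, lowercased."""
    path = Path(path)
    words: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.add(line.lower())
    return WordList(frozenset(words), role)


def load_lexicon(path: str | Path, kind: str = "toy") -> LexiconBackend:
    """Load a lexicon backend: ``kind`` is "toy" (flat), "senses", or "wordnet"."""
    if kind == "toy":
        return ToyLexicon.from_json(path)
    if kind == "senses":
        return SenseLexicon.from_json(path)
    if kind == "wordnet":
        return WordNetLexicon()
    raise ValueError(f"unknown lexicon kind: {kind!r}")


def _packaged(name: str) -> Path:
    return Path(str(resources.files("readtopics").joinpath("data", name)))


def default_stopwords() -> WordList:
    """The packaged English stop-word list."""
    return load_wordlist(_packaged("stopwords.txt"), "stopwords")


def default_undesirable() -> WordList:
    """The packaged undesirable-item list (overly general dictionary words)."""
    return load_wordlist(_packaged("undesirable.txt"), "undesirable")


def packaged_gold_senses() -> SenseLexicon:
    """The packaged two-sense WordNet 2.1 entry for "gold" (demo fixture)."""
    return SenseLexicon.from_json(_packaged("gold_senses.json"))
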