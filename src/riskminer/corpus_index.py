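"""Parsed-sentence corpus: loading, Penn-Treebank trees, and phrase queries.

A corpus is a JSON Lines file, one sentence per line::

    {"doc_id": "12345", "sent_idx": 0, "text": "...", "tree": "(S ...)" | null}

The ``tree`` field holds a bracketed constituency parse. Tokenization is
fixed by the parse: when a tree is present the tree leaves *are* the tokens;
when it is absent, a PTB-style fallback tokenizer is applied to ``text``
(possessive ``'s`` and punctuation split off, curly apostrophes normalized).
All matching is case-insensitive; token spans are 0-based half-open
throughout.

The :class:`CorpusIndex` is a plain in-memory inverted index serving exact
contiguous phrase queries — the small-corpus stand-in for a full-text search
engine over sentences and their parse trees.
"""

from __future__ import annotations

import json
import logging
import pickle
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

SentenceKey = tuple[str, int]

_INDEX_FORMAT_VERSION = 1

# Splits possessives and punctuation off words: "bowen's" -> bowen 's ,
# "vulva." -> vulva .
_TOKEN_RE = re.compile(r"'s\b|[A-Za-z0-9][A-Za-z0-9\-]*|[^\sA-Za-z0-9]")


def tokenize(text: str) -> list[str]:
    """PTB-style fallback tokenizer for sentences without a parse tree.

    Normalizes the Unicode right single quote to an ASCII apostrophe so
    lexicon terms like "bowen's disease" match text printed with curly
    quotes, then splits off possessive ``'s`` and punctuation marks.
    """
    text = text.replace("’", "'").replace("‘", "'")
    return _TOKEN_RE.findall(text)


def fold(token: str) -> str:
    """Case-fold a token for matching (apostrophes normalized)."""
    return token.replace("’", "'").replace("‘", "'").lower()


class PTBParseError(ValueError):
    """Raised for malformed bracketed tree strings; carries the offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass
class ParseTree:
    """A constituency-tree node with a half-open leaf span.

    Internal nodes hold ``children``; preterminals hold a single ``leaf``
    token. Child spans partition the parent span left to right.
    """

    label: str
    children: list["ParseTree"] = field(default_factory=list)
    leaf: str | None = None
    span: tuple[int, int] = (0, 0)

    def leaves(self) -> list[str]:
        if self.leaf is not None:
            return [self.leaf]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def iter_nodes(self) -> Iterator["ParseTree"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def serialize(self) -> str:
        """Canonical bracketed form: single spaces, no outer whitespace."""
        if self.leaf is not None:
            return f"({self.label} {self.leaf})"
        inner = " ".join(c.serialize() for c in self.children)
        return f"({self.label} {inner})"


_PTB_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_ptb(s: str) -> ParseTree:
    """Parse a bracketed Penn-Treebank tree string into a :class:`ParseTree`.

    Spans are assigned left to right starting at 0. Raises
    :class:`PTBParseError` (naming the character offset) on unbalanced or
    empty input.
    """
    pieces = [(m.group(0), m.start()) for m in _PTB_TOKEN_RE.finditer(s)]
    if not pieces:
        raise PTBParseError("empty tree string", 0)

    pos = 0
    leaf_counter = [0]

    def parse_node() -> ParseTree:
        nonlocal pos
        tok, off = pieces[pos]
        if tok != "(":
            raise PTBParseError(f"expected '(' but found {tok!r}", off)
        pos += 1
        if pos >= len(pieces):
            raise PTBParseError("unexpected end of input after '('", off)
        label_tok, label_off = pieces[pos]
        if label_tok in "()":
            raise PTBParseError("missing node label", label_off)
        pos += 1
        node = ParseTree(label=label_tok)
        start = leaf_counter[0]
        while pos < len(pieces):
            tok, off = pieces[pos]
            if tok == ")":
                pos += 1
                if node.leaf is None and not node.children:
                    raise PTBParseError("node has no children or leaf", off)
                node.span = (start, leaf_counter[0])
                return node
            if tok == "(":
                if node.leaf is not None:
                    raise PTBParseError(
                        "mixed leaf and subtree under one node", off
                    )
                node.children.append(parse_node())
            else:
                if node.children:
                    raise PTBParseError(
                        "mixed leaf and subtree under one node", off
                    )
                if node.leaf is not None:
                    raise PTBParseError(
                        "multiple leaves under one preterminal", off
                    )
                node.leaf = tok
                leaf_counter[0] += 1
                pos += 1
        raise PTBParseError("unbalanced parentheses: missing ')'", len(s))

    root = parse_node()
    if pos != len(pieces):
        raise PTBParseError("trailing material after tree", pieces[pos][1])
    return root


def np_spans(tree: ParseTree) -> set[tuple[int, int]]:
    """Spans of all constituents whose label begins with ``NP``."""
    return {
        node.span for node in tree.iter_nodes() if node.label.startswith("NP")
    }


@dataclass
class SentenceRecord:
    """One parsed sentence: identity, raw text, tokens, optional tree."""

    doc_id: str
    sent_idx: int
    text: str
    tokens: list[str]
    tree: ParseTree | None = None

    @property
    def key(self) -> SentenceKey:
        return (self.doc_id, self.sent_idx)

    @property
    def folded(self) -> list[str]:
        return [fold(t) for t in self.tokens]


def load_corpus(path) -> tuple[list[SentenceRecord], int]:
    """Read a JSON Lines corpus file.

    Returns ``(records, n_skipped)``. Lines with malformed JSON or
    unparseable trees are skipped with a logged warning; an unreadable file
    raises.
    """
    records: list[SentenceRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                logger.warning("line %d: malformed JSON (%s); skipped", lineno, exc)
                skipped += 1
                continue
            try:
                doc_id = str(obj["doc_id"])
                sent_idx = int(obj["sent_idx"])
                text = str(obj["text"])
                tree_s = obj.get("tree")
            except (KeyError, TypeError, ValueError) as exc:
                logger.warning("line %d: bad record (%s); skipped", lineno, exc)
                skipped += 1
                continue
            tree = None
            if tree_s is not None:
                try:
                    tree = parse_ptb(tree_s)
                except PTBParseError as exc:
                    logger.warning("line %d: bad tree (%s); skipped", lineno, exc)
                    skipped += 1
                    continue
            tokens = tree.leaves() if tree is not None else tokenize(text)
            records.append(
                SentenceRecord(
                    doc_id=doc_id,
                    sent_idx=sent_idx,
                    text=text,
                    tokens=tokens,
                    tree=tree,
                )
            )
    return records, skipped


class CorpusIndex:
    """Token inverted index plus sentence store over a corpus.

    Postings map a folded token to ``[(sentence key, position), ...]``;
    query results are independent of insertion order.
    """

    def __init__(self) -> None:
        self.sentences: dict[SentenceKey, SentenceRecord] = {}
        self._postings: dict[str, list[tuple[SentenceKey, int]]] = {}

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[SentenceRecord]:
        return iter(self.sentences.values())

    def add(self, record: SentenceRecord) -> None:
        if record.key in self.sentences:
            raise ValueError(f"duplicate sentence key {record.key}")
        self.sentences[record.key] = record
        for pos, tok in enumerate(record.folded):
            self._postings.setdefault(tok, []).append((record.key, pos))

    def get(self, key: SentenceKey) -> SentenceRecord:
        return self.sentences[key]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": _INDEX_FORMAT_VERSION, "index": self}, fh)

    @staticmethod
    def load(path) -> "CorpusIndex":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != _INDEX_FORMAT_VERSION:
            raise ValueError(
                f"unsupported index format version {payload.get('version')!r}"
            )
        return payload["index"]


def build_index(records: Iterable[SentenceRecord]) -> CorpusIndex:
    """Index a corpus; duplicate (doc_id, sent_idx) keys are an error."""
    index = CorpusIndex()
    for record in records:
        index.add(record)
    return index


def query_phrase(
    index: CorpusIndex, phrase: Sequence[str]
) -> set[tuple[SentenceKey, int]]:
    """All exact contiguous case-folded occurrences of ``phrase``.

    Returns ``{(sentence key, start position), ...}``. A zero-length phrase
    matches at every token boundary of every sentence (used for adjacency
    patterns, where two mentions abut with nothing between them).
    """
    if len(phrase) == 0:
        return {
            (key, pos)
            for key, rec in index.sentences.items()
            for pos in range(len(rec.tokens) + 1)
        }
    folded = [fold(t) for t in phrase]
    hits: set[tuple[SentenceKey, int]] = set()
    for key, start in index._postings.get(folded[0], ()):
        toks = index.sentences[key].folded
        if toks[start : start + len(folded)] == folded:
            hits.add((key, start))
    return hits
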