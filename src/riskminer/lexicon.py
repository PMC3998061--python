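"""Entity (disease) lexicon: loading, mention finding, NP filtering.

The lexicon maps surface terms to concept identifiers. Terms are tokenized
with the corpus tokenizer and case-folded at load time, so "Bowen's disease"
in a lexicon file matches "bowen ’s disease" in text. Mention finding is an
exact dictionary scan returning *all* matches including nested ones;
:func:`filter_np_mentions` then applies the two precision devices:

1. the noun-phrase constraint — a mention survives only if its span is
   exactly the span of an NP-labeled constituent in the parse tree, and
2. maximal match — a surviving mention nested inside a longer surviving
   mention is dropped, so "infection" loses to
   "herpes simplex virus type 2 infection" when the long form is an NP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .corpus_index import ParseTree, fold, np_spans, tokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Mention:
    """A lexicon hit in a token sequence; span is half-open."""

    concept_id: str
    span: tuple[int, int]
    is_np: bool | None = None

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    def __len__(self) -> int:
        return self.span[1] - self.span[0]


class Lexicon:
    """Term token-sequence -> concept id, plus concept id -> preferred name."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, ...], str] = {}
        self._names: dict[str, str] = {}
        self._lengths: set[int] = set()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, term_tokens: tuple[str, ...]) -> bool:
        return tuple(fold(t) for t in term_tokens) in self._entries

    @property
    def term_lengths(self) -> set[int]:
        return set(self._lengths)

    def add(self, term: str, concept_id: str, preferred_name: str) -> None:
        toks = tuple(fold(t) for t in tokenize(term))
        if not toks:
            raise ValueError(f"empty term for concept {concept_id!r}")
        existing = self._entries.get(toks)
        if existing is not None and existing != concept_id:
            raise ValueError(
                f"term {' '.join(toks)!r} maps to two concepts: "
                f"{existing!r} and {concept_id!r}"
            )
        self._entries[toks] = concept_id
        self._names.setdefault(concept_id, preferred_name)
        self._lengths.add(len(toks))

    def concept_of(self, term_tokens: Sequence[str]) -> str | None:
        return self._entries.get(tuple(fold(t) for t in term_tokens))

    def name_of(self, concept_id: str) -> str:
        return self._names.get(concept_id, concept_id)

    @property
    def concept_ids(self) -> set[str]:
        return set(self._names)

    def items(self) -> Iterable[tuple[tuple[str, ...], str]]:
        return self._entries.items()


def load_lexicon(path, header: bool = False) -> Lexicon:
    """Load a 3-column TSV (term, concept_id, preferred_name).

    Duplicate (term, concept) rows are deduplicated silently; a term mapped
    to two different concepts is a fatal error listing the offenders.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        header=0 if header else None,
        names=["term", "concept_id", "preferred_name"],
        dtype=str,
        keep_default_na=False,
    )
    lex = Lexicon()
    for row in frame.itertuples(index=False):
        lex.add(row.term, row.concept_id, row.preferred_name)
    return lex


def find_mentions(tokens: Sequence[str], lex: Lexicon) -> list[Mention]:
    """All lexicon matches in ``tokens``, nested/overlapping included.

    Ordered by (start, -length); ``is_np`` is left unset.
    """
    folded = [fold(t) for t in tokens]
    lengths = sorted(lex.term_lengths, reverse=True)
    out: list[Mention] = []
    for start in range(len(folded)):
        for length in lengths:
            end = start + length
            if end > len(folded):
                continue
            concept = lex.concept_of(folded[start:end])
            if concept is not None:
                out.append(Mention(concept_id=concept, span=(start, end)))
    out.sort(key=lambda m: (m.start, -len(m)))
    return out


def filter_np_mentions(
    mentions: Sequence[Mention], tree: ParseTree
) -> list[Mention]:
    """Keep NP-exact mentions, then drop mentions nested in longer ones.

    The NP test is exact span equality with an NP constituent, not
    containment: "bowen 's disease" survives inside the larger phrase
    "bowen 's disease of the vulva" because the short form is itself an NP
    node, while a bare "infection" token inside a six-token NP is not.
    """
    spans = np_spans(tree)
    np_valid = [
        Mention(m.concept_id, m.span, is_np=True)
        for m in mentions
        if m.span in spans
    ]
    kept: list[Mention] = []
    for m in np_valid:
        nested = any(
            o.start <= m.start and m.end <= o.end and len(o) > len(m)
            for o in np_valid
        )
        if not nested:
            kept.append(m)
    kept.sort(key=lambda m: (m.start, -len(m)))
    return kept
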