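"""Build and export the directed disease→disease risk knowledge base.

Pattern acceptance in the original workflow is a short manual step: from the
F1-ranked candidate list, a curator keeps the risk-specific patterns with
enough distinct supporting pairs. Here that step is a plain-text config
(one ``pattern <TAB> direction <TAB> score`` line per accepted pattern) so
it is versioned and reproducible. :func:`build_kb` then re-extracts every
occurrence of each accepted pattern, orients it so the stored tuple is
always ``(cause, effect)``, aggregates per-pattern counts at the concept
level, and scores each pair from its supporting patterns.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .corpus_index import CorpusIndex, SentenceKey
from .lexicon import Lexicon
from .pattern_learning import (
    FORWARD,
    REVERSE,
    Pattern,
    PatternStats,
    extract_pairs,
    np_mention_map,
    score_pair,
)

logger = logging.getLogger(__name__)

MAX_WITNESSES = 20  # supporting sentence keys stored per pair


@dataclass(frozen=True)
class AcceptedPattern:
    """One curated pattern: surface form, orientation, ranking score."""

    pattern: Pattern
    direction: str
    score: float

    def __post_init__(self) -> None:
        if self.direction not in (FORWARD, REVERSE):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.score <= 0:
            raise ValueError("accepted pattern needs a positive ranking score")


@dataclass
class RiskPair:
    """A directed (cause, effect) concept pair with its evidence."""

    cause: str
    effect: str
    pattern_counts: dict[str, int]
    score: float
    witnesses: tuple[SentenceKey, ...]

    @property
    def n_occurrences(self) -> int:
        return sum(self.pattern_counts.values())

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_counts)


@dataclass
class RiskKB:
    """The knowledge base: unique (cause, effect) pairs plus metadata."""

    pairs: dict[tuple[str, str], RiskPair]
    names: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(
            sorted(
                self.pairs.values(),
                key=lambda p: (-p.score, p.cause, p.effect),
            )
        )

    @property
    def diseases(self) -> set[str]:
        out: set[str] = set()
        for cause, effect in self.pairs:
            out.add(cause)
            out.add(effect)
        return out

    def causes_of(self, concept: str) -> set[str]:
        """In-neighbors: predisposing diseases of ``concept``."""
        return {c for (c, e) in self.pairs if e == concept}

    def effects_of(self, concept: str) -> set[str]:
        """Out-neighbors: diseases ``concept`` predisposes to."""
        return {e for (c, e) in self.pairs if c == concept}


def load_accepted_patterns(path) -> list[AcceptedPattern]:
    """Read the accepted-pattern TSV (pattern, direction, score)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["pattern", "direction", "score"],
        dtype={"pattern": str, "direction": str, "score": float},
        comment="#",
        keep_default_na=False,
    )
    return [
        AcceptedPattern(
            pattern=Pattern.from_string(row.pattern),
            direction=row.direction,
            score=float(row.score),
        )
        for row in frame.itertuples(index=False)
    ]


def accepted_from_stats(
    stats: Iterable[PatternStats], method: str = "f1"
) -> list[AcceptedPattern]:
    """Convenience: turn ranked bootstrap stats into accepted patterns."""
    attr = {"precision": "rs_precision", "recall": "rs_recall", "f1": "rs_f1"}[
        method
    ]
    return [
        AcceptedPattern(
            pattern=s.pattern, direction=s.direction, score=getattr(s, attr)
        )
        for s in stats
    ]


def select_candidates(
    stats: Iterable[PatternStats],
    min_support: int,
    include_adjacency: bool = False,
) -> list[PatternStats]:
    """Support-filtered, F1-ranked candidate list for manual review.

    Keeps patterns whose output covers at least ``min_support`` distinct
    concept pairs, sorted by F1 descending. Zero-length (adjacency)
    patterns such as bare "D1 D2" are excluded by default: they rank well
    on recall-heavy corpora but carry no relational semantics.
    """
    out = [
        s
        for s in stats
        if s.support >= min_support
        and (include_adjacency or len(s.pattern) > 0)
    ]
    out.sort(key=lambda s: (-s.rs_f1, -s.support, s.pattern.id))
    return out


def build_kb(
    index: CorpusIndex,
    lex: Lexicon,
    accepted: Sequence[AcceptedPattern],
    score_mode: str = "rectified",
    corpus_id: str = "",
) -> RiskKB:
    """Apply accepted patterns to the corpus and aggregate into a KB.

    Every occurrence is oriented by its pattern's direction (FORWARD keeps
    the surface order, REVERSE flips it) so stored tuples are always
    (cause, effect); counts aggregate at the concept level, and each pair
    is scored from its supporting patterns' (score, count) evidence.
    """
    if not accepted:
        raise ValueError("accepted pattern list is empty")
    mention_map = np_mention_map(index, lex)
    counts: dict[tuple[str, str], dict[str, int]] = {}
    witnesses: dict[tuple[str, str], list[SentenceKey]] = {}
    score_of = {a.pattern.id: a.score for a in accepted}
    for acc in accepted:
        occs = extract_pairs(index, acc.pattern, lex, mention_map)
        if not occs:
            logger.warning("pattern %s matched nothing", acc.pattern.id)
            continue
        for occ in sorted(occs, key=lambda o: (o.key, o.d1, o.d2)):
            if acc.direction == FORWARD:
                cause, effect = occ.d1, occ.d2
            else:
                cause, effect = occ.d2, occ.d1
            pc = counts.setdefault((cause, effect), {})
            pc[acc.pattern.id] = pc.get(acc.pattern.id, 0) + 1
            wl = witnesses.setdefault((cause, effect), [])
            if len(wl) < MAX_WITNESSES and occ.key not in wl:
                wl.append(occ.key)

    pairs: dict[tuple[str, str], RiskPair] = {}
    for (cause, effect), pc in counts.items():
        score = score_pair(
            [(score_of[pid], n) for pid, n in sorted(pc.items())],
            mode=score_mode,
        )
        pairs[(cause, effect)] = RiskPair(
            cause=cause,
            effect=effect,
            pattern_counts=dict(sorted(pc.items())),
            score=score,
            witnesses=tuple(witnesses[(cause, effect)]),
        )
    config_hash = hashlib.sha256(
        json.dumps(
            sorted((a.pattern.id, a.direction, a.score) for a in accepted)
        ).encode()
    ).hexdigest()[:12]
    names = {c: lex.name_of(c) for p in pairs.values() for c in (p.cause, p.effect)}
    return RiskKB(
        pairs=pairs,
        names=names,
        metadata={
            "patterns": [a.pattern.id for a in accepted],
            "corpus_id": corpus_id,
            "score_mode": score_mode,
            "config_hash": config_hash,
        },
    )


def to_digraph(kb: RiskKB) -> nx.DiGraph:
    """The whole KB as a weighted directed graph (edge weight = score)."""
    g = nx.DiGraph()
    for concept in sorted(kb.diseases):
        g.add_node(concept, name=kb.names.get(concept, concept))
    for pair in kb:
        g.add_edge(
            pair.cause,
            pair.effect,
            weight=pair.score,
            n_occurrences=pair.n_occurrences,
        )
    return g


def ego_graph(kb: RiskKB, disease: str, depth: int = 1) -> nx.DiGraph:
    """The weighted directed neighborhood of one disease.

    In-edges come from its predisposing (cause) diseases, out-edges go to
    its effect diseases. Unknown concepts raise with near-miss suggestions.
    """
    if disease not in kb.diseases:
        candidates = {kb.names.get(c, c): c for c in kb.diseases}
        near = difflib.get_close_matches(
            kb.names.get(disease, disease), list(candidates) + sorted(kb.diseases), n=3
        )
        raise KeyError(
            f"concept {disease!r} not in the knowledge base; close matches: {near}"
        )
    full = to_digraph(kb)
    return nx.ego_graph(full, disease, radius=depth, undirected=True)


def export(kb: RiskKB, path, fmt: str = "tsv") -> None:
    """Write the KB as TSV, GraphML, or DOT.

    The TSV carries the human-facing columns (ids, names, score, evidence
    counts, example documents) plus machine-facing ``pattern_counts`` /
    ``witnesses`` JSON columns so a re-import reproduces the KB exactly.
    """
    if fmt == "tsv":
        rows = []
        for pair in kb:
            rows.append(
                {
                    "cause_id": pair.cause,
                    "cause_name": kb.names.get(pair.cause, pair.cause),
                    "effect_id": pair.effect,
                    "effect_name": kb.names.get(pair.effect, pair.effect),
                    "score": pair.score,
                    "n_occurrences": pair.n_occurrences,
                    "n_patterns": pair.n_patterns,
                    "example_doc_ids": ";".join(
                        dict.fromkeys(doc for doc, _ in pair.witnesses)
                    ),
                    "pattern_counts": json.dumps(pair.pattern_counts),
                    "witnesses": json.dumps([list(w) for w in pair.witnesses]),
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "cause_id",
                "cause_name",
                "effect_id",
                "effect_name",
                "score",
                "n_occurrences",
                "n_patterns",
                "example_doc_ids",
                "pattern_counts",
                "witnesses",
            ],
        )
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(to_digraph(kb), path)
    elif fmt == "dot":
        g = to_digraph(kb)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("digraph riskkb {\n")
            for node, data in g.nodes(data=True):
                fh.write(f'  "{node}" [label="{data.get("name", node)}"];\n')
            for u, v, data in g.edges(data=True):
                fh.write(f'  "{u}" -> "{v}" [weight={data["weight"]:g}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_kb(path) -> RiskKB:
    """Re-import a TSV export produced by :func:`export`."""
    frame = pd.read_csv(path, sep="\t", dtype={"cause_id": str, "effect_id": str})
    pairs: dict[tuple[str, str], RiskPair] = {}
    names: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        witnesses = tuple(
            (str(d), int(i)) for d, i in json.loads(row.witnesses)
        )
        pair = RiskPair(
            cause=row.cause_id,
            effect=row.effect_id,
            pattern_counts=json.loads(row.pattern_counts),
            score=float(row.score),
            witnesses=witnesses,
        )
        pairs[(pair.cause, pair.effect)] = pair
        names[pair.cause] = row.cause_name
        names[pair.effect] = row.effect_name
    return RiskKB(pairs=pairs, names=names, metadata={})
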