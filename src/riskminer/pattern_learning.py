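"""Semi-supervised bootstrap of relation patterns from a seed.

The learner alternates two steps over an indexed, parsed corpus:

* **pair extraction** — given a pattern ``p`` (a token sequence), find every
  sentence matching ``D1 p D2`` where D1 and D2 are maximal noun-phrase
  lexicon mentions, and emit the (D1, D2) concept pair;
* **pattern extraction** — given a pool of known concept pairs, find every
  sentence where two pooled concepts appear as NP mentions and emit the
  intervening token sequence as a candidate pattern.

Starting from a seed such as "D1 due to D2", two iterations suffice on
redundant corpora. Patterns are then ranked against the seed's output
``ins(p0)`` (the gold standard) with three scores over *unordered* concept
pairs ``ins(p)``:

    precision(p) = |ins(p) ∩ ins(p0)| / |ins(p)|
    recall(p)    = |ins(p) ∩ ins(p0)| / |ins(p0)|
    F1(p)        = harmonic mean of the two

Unordered comparison lets patterns that state the relation in the opposite
surface order ("D1 causing D2" vs "D1 due to D2") still overlap the seed;
orientation is recovered separately by :func:`assign_direction` from the
*ordered* outputs. Extracted pairs are finally scored by aggregating the
scores and frequencies of their supporting patterns (:func:`score_pair`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_index import CorpusIndex, SentenceKey, fold, query_phrase, tokenize
from .lexicon import Lexicon, Mention, filter_np_mentions, find_mentions

logger = logging.getLogger(__name__)

# Surface orientation of a pattern: FORWARD means the left-hand mention (D1)
# is the cause ("D1 causing D2"); REVERSE means D1 is the effect
# ("D1 due to D2").
FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class Pattern:
    """A token sequence connecting two entity mentions (possibly empty)."""

    tokens: tuple[str, ...]

    @staticmethod
    def from_string(s: str) -> "Pattern":
        toks = [fold(t) for t in tokenize(s)]
        if toks[:1] == ["d1"]:
            toks = toks[1:]
        if toks[-1:] == ["d2"]:
            toks = toks[:-1]
        return Pattern(tuple(toks))

    @property
    def id(self) -> str:
        inner = " ".join(self.tokens)
        return f"D1 {inner} D2" if inner else "D1 D2"

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class PairOccurrence:
    """A mention-level directed match of one pattern in one sentence."""

    d1: str
    d2: str
    pattern_id: str
    key: SentenceKey


@dataclass
class PatternStats:
    """A pattern's output and its ranking against the seed's output."""

    pattern: Pattern
    ins: frozenset[frozenset[str]]
    ordered: frozenset[tuple[str, str]]
    overlap: int
    seed_size: int
    rs_precision: float
    rs_recall: float
    rs_f1: float
    direction: str
    is_seed: bool = False
    low_confidence: bool = False

    @property
    def support(self) -> int:
        """Number of distinct unordered concept pairs in the output."""
        return len(self.ins)


@dataclass
class BootstrapConfig:
    """Knobs of the bootstrap loop.

    ``max_iterations`` defaults to 2: on a redundant corpus the second round
    of pattern extraction adds little, and the loop also stops early when
    the newly discovered distinct patterns number less than
    ``min_new_fraction`` of the cumulative pattern set.
    ``seed_direction`` states the surface orientation of the seed(s);
    "due to"-style seeds put the effect first (REVERSE).
    """

    seeds: Sequence[str] = ("due to",)
    max_iterations: int = 2
    max_pattern_len: int = 8
    min_pattern_support: int = 1
    pattern_cap: int = 10_000
    min_new_fraction: float = 0.05
    seed_direction: str = REVERSE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.seed_direction not in (FORWARD, REVERSE):
            raise ValueError(f"bad seed_direction {self.seed_direction!r}")


def np_mention_map(
    index: CorpusIndex,
    lex: Lexicon,
    keys: Iterable[SentenceKey] | None = None,
) -> dict[SentenceKey, list[Mention]]:
    """Maximal NP-valid mentions per sentence (tree-less sentences skipped)."""
    out: dict[SentenceKey, list[Mention]] = {}
    if keys is None:
        keys = index.sentences.keys()
    for key in keys:
        rec = index.sentences[key]
        if rec.tree is None:
            continue
        out[key] = filter_np_mentions(find_mentions(rec.tokens, lex), rec.tree)
    return out


def extract_pairs(
    index: CorpusIndex,
    pattern: Pattern,
    lex: Lexicon,
    mention_map: Mapping[SentenceKey, list[Mention]] | None = None,
) -> set[PairOccurrence]:
    """Mention-level ``D1 pattern D2`` matches across the corpus.

    For each occurrence of the pattern tokens, a pair is emitted when one
    maximal NP-valid mention ends immediately before the occurrence and
    another begins immediately after it. Occurrences are retained at the
    sentence level; concept-level aggregation happens downstream.
    """
    hits = query_phrase(index, pattern.tokens)
    out: set[PairOccurrence] = set()
    for key, pos in hits:
        rec = index.sentences[key]
        if rec.tree is None:
            continue
        if mention_map is not None:
            mentions = mention_map.get(key, [])
        else:
            mentions = filter_np_mentions(
                find_mentions(rec.tokens, lex), rec.tree
            )
        end = pos + len(pattern.tokens)
        left = [m for m in mentions if m.end == pos]
        right = [m for m in mentions if m.start == end]
        for m1 in left:
            for m2 in right:
                if m1.concept_id != m2.concept_id:
                    out.add(
                        PairOccurrence(
                            d1=m1.concept_id,
                            d2=m2.concept_id,
                            pattern_id=pattern.id,
                            key=key,
                        )
                    )
    return out


def _as_unordered(pairs: Iterable) -> set[frozenset[str]]:
    out = set()
    for p in pairs:
        if isinstance(p, frozenset):
            out.add(p)
        else:
            a, b = p
            out.add(frozenset((a, b)))
    return out


def extract_patterns(
    index: CorpusIndex,
    pairs: Iterable,
    lex: Lexicon,
    cfg: BootstrapConfig,
    mention_map: Mapping[SentenceKey, list[Mention]] | None = None,
) -> list[tuple[Pattern, int]]:
    """Candidate patterns connecting known concept pairs.

    For every sentence containing NP-valid mentions of both concepts of some
    input pair (unordered), the intervening token sequence becomes a
    candidate if it is at most ``max_pattern_len`` tokens and contains no
    lexicon mention of its own. Support counts distinct unordered concept
    pairs. Results are sorted by (support desc, pattern id), filtered by
    ``min_pattern_support`` and capped at ``pattern_cap``.
    """
    wanted = _as_unordered(pairs)
    if not wanted:
        raise ValueError("pattern extraction requires a non-empty pair set")
    if mention_map is None:
        mention_map = np_mention_map(index, lex)
    support: dict[tuple[str, ...], set[frozenset[str]]] = {}
    for key, mentions in mention_map.items():
        if len(mentions) < 2:
            continue
        folded = index.sentences[key].folded
        for m1 in mentions:
            for m2 in mentions:
                if m1 is m2 or m1.end > m2.start:
                    continue
                upair = frozenset((m1.concept_id, m2.concept_id))
                if len(upair) < 2 or upair not in wanted:
                    continue
                gap = tuple(folded[m1.end : m2.start])
                if len(gap) > cfg.max_pattern_len:
                    continue
                if gap and find_mentions(gap, lex):
                    continue  # pattern tokens may not contain a mention
                support.setdefault(gap, set()).add(upair)
    ranked = sorted(
        ((Pattern(toks), len(ps)) for toks, ps in support.items()),
        key=lambda t: (-t[1], t[0].id),
    )
    ranked = [t for t in ranked if t[1] >= cfg.min_pattern_support]
    return ranked[: cfg.pattern_cap]


def rank_precision(stats: PatternStats) -> float:
    """Overlap with the seed's output over the pattern's own output size."""
    if not stats.ins:
        raise ValueError("precision undefined for a pattern with empty output")
    return stats.overlap / len(stats.ins)


def rank_recall(stats: PatternStats) -> float:
    """Overlap with the seed's output over the seed's output size."""
    if not stats.seed_size:
        raise ValueError("recall undefined for an empty seed output")
    return stats.overlap / stats.seed_size


def rank_f1(stats: PatternStats) -> float:
    """Harmonic mean of the precision and recall scores; 0 when both are 0."""
    return _f1(rank_precision(stats), rank_recall(stats))


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def assign_direction(
    ordered: Iterable[tuple[str, str]],
    seed_ordered: Iterable[tuple[str, str]],
    seed_direction: str = REVERSE,
) -> tuple[str, bool]:
    """Orient a pattern relative to the seed from ordered-output overlap.

    Compares the pattern's ordered (left mention, right mention) pairs with
    the seed's ordered output as-is and flipped; the larger overlap wins,
    ties keep the seed's orientation. Returns ``(direction,
    low_confidence)`` where low confidence flags a zero overlap both ways.
    """
    ordered = set(ordered)
    seed_set = set(seed_ordered)
    same = len(ordered & seed_set)
    flipped = len(ordered & {(b, a) for a, b in seed_set})
    other = FORWARD if seed_direction == REVERSE else REVERSE
    if flipped > same:
        return other, False
    return seed_direction, (same == 0 and flipped == 0)


def score_pair(
    pattern_counts: Iterable[tuple[float, int]],
    mode: str = "rectified",
) -> float:
    """Aggregate score of a pair from its supporting patterns.

    ``pattern_counts`` holds ``(pattern ranking score, occurrence count)``
    per supporting pattern. Two modes:

    * ``"literal"`` — Σ log(RS_i) · count_i. Since RS ≤ 1 this is ≤ 0 and a
      perfect-precision pattern contributes exactly 0; patterns with RS = 0
      are excluded with a warning (log undefined).
    * ``"rectified"`` (default) — Σ RS_i · log(1 + count_i), strictly
      increasing in both pattern reliability and frequency, matching the
      intent that a reliable pair is one matched by reliable patterns many
      times.
    """
    if mode not in ("literal", "rectified"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    total = 0.0
    for score, count in pattern_counts:
        if count < 0:
            raise ValueError("occurrence count must be non-negative")
        if mode == "literal":
            if score <= 0:
                logger.warning(
                    "pattern with score %g excluded from literal pair score",
                    score,
                )
                continue
            total += math.log(score) * count
        else:
            total += score * math.log1p(count)
    return total


@dataclass
class BootstrapResult:
    """Everything the bootstrap learned: patterns with stats, occurrences."""

    stats: list[PatternStats]
    occurrences: set[PairOccurrence]
    seed_ids: list[str]
    config: BootstrapConfig

    def stats_by_id(self) -> dict[str, PatternStats]:
        return {s.pattern.id: s for s in self.stats}

    def ranked(self, method: str = "f1") -> list[PatternStats]:
        """Patterns sorted by the chosen score, seeds first on ties."""
        keyfn = {
            "precision": lambda s: s.rs_precision,
            "recall": lambda s: s.rs_recall,
            "f1": lambda s: s.rs_f1,
        }[method]
        return sorted(
            self.stats,
            key=lambda s: (-keyfn(s), not s.is_seed, -s.support, s.pattern.id),
        )


def bootstrap(
    index: CorpusIndex, lex: Lexicon, cfg: BootstrapConfig
) -> BootstrapResult:
    """Run the iterative pair/pattern extraction loop and rank the result.

    Each iteration extracts candidate patterns from the cumulative pair
    pool, then extracts pairs with every newly discovered pattern to grow
    the pool. The loop is deterministic: identical inputs give identical
    outputs. Raises if the seed matches nothing (the gold standard would be
    empty and ranking undefined).
    """
    mention_map = np_mention_map(index, lex)
    seeds = [Pattern.from_string(s) for s in cfg.seeds]
    patterns: dict[str, Pattern] = {}
    occs: dict[str, set[PairOccurrence]] = {}

    for seed in seeds:
        patterns[seed.id] = seed
        occs[seed.id] = extract_pairs(index, seed, lex, mention_map)
    seed_occs = set().union(*occs.values())
    if not seed_occs:
        raise ValueError("seed has empty output; ranking undefined")
    seed_ordered = {(o.d1, o.d2) for o in seed_occs}
    seed_ins = _as_unordered(seed_ordered)

    pool: set[frozenset[str]] = set(seed_ins)
    for it in range(cfg.max_iterations):
        candidates = extract_patterns(index, pool, lex, cfg, mention_map)
        new = [p for p, _ in candidates if p.id not in patterns]
        for p in new:
            patterns[p.id] = p
            occs[p.id] = extract_pairs(index, p, lex, mention_map)
            pool |= {frozenset((o.d1, o.d2)) for o in occs[p.id]}
        logger.info("iteration %d: %d new patterns", it + 1, len(new))
        if len(new) < cfg.min_new_fraction * len(patterns):
            break

    stats: list[PatternStats] = []
    seed_id_set = {s.id for s in seeds}
    for pid, pat in patterns.items():
        ordered = frozenset((o.d1, o.d2) for o in occs[pid])
        ins = frozenset(_as_unordered(ordered))
        if not ins:
            logger.warning("pattern %s has empty output; excluded", pid)
            continue
        overlap = len(ins & seed_ins)
        precision = overlap / len(ins)
        recall = overlap / len(seed_ins)
        direction, low_conf = assign_direction(
            ordered, seed_ordered, cfg.seed_direction
        )
        stats.append(
            PatternStats(
                pattern=pat,
                ins=ins,
                ordered=ordered,
                overlap=overlap,
                seed_size=len(seed_ins),
                rs_precision=precision,
                rs_recall=recall,
                rs_f1=_f1(precision, recall),
                direction=direction,
                is_seed=pid in seed_id_set,
                low_confidence=low_conf,
            )
        )
    all_occs = set().union(*occs.values()) if occs else set()
    return BootstrapResult(
        stats=stats,
        occurrences=all_occs,
        seed_ids=sorted(seed_id_set),
        config=cfg,
    )


def seed_robustness(
    index: CorpusIndex,
    lex: Lexicon,
    seeds: Sequence[str],
    reference_patterns: Sequence[str],
    cutoffs: Sequence[int],
    cfg: BootstrapConfig | None = None,
) -> pd.DataFrame:
    """How many reference patterns each seed surfaces among its top-k.

    Runs the full bootstrap independently per seed, ranks by F1, and counts
    reference-pattern appearances at each cutoff. Rows are seeds, columns
    cutoffs — the robustness table showing that risk-specific seeds agree
    with each other while a generic seed ranks the same references lower.
    """
    base = cfg or BootstrapConfig()
    ref_ids = {Pattern.from_string(r).id for r in reference_patterns}
    rows = []
    for seed in seeds:
        run_cfg = BootstrapConfig(
            seeds=(seed,),
            max_iterations=base.max_iterations,
            max_pattern_len=base.max_pattern_len,
            min_pattern_support=base.min_pattern_support,
            pattern_cap=base.pattern_cap,
            min_new_fraction=base.min_new_fraction,
            seed_direction=base.seed_direction,
            rng_seed=base.rng_seed,
        )
        ranked = bootstrap(index, lex, run_cfg).ranked("f1")
        ranked_ids = [s.pattern.id for s in ranked]
        rows.append(
            [sum(1 for pid in ranked_ids[:k] if pid in ref_ids) for k in cutoffs]
        )
    return pd.DataFrame(rows, index=list(seeds), columns=list(cutoffs))
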