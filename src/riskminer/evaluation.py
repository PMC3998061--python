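"""Manual-evaluation protocol as code: sampling, precision, agreement.

Extraction quality is audited by sampling sentences per accepted pattern,
having two annotators label each extracted pair as correct / partial /
incorrect, and computing pair-level precision against the double-annotated
gold standard plus Cohen's kappa for inter-annotator agreement.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_index import CorpusIndex
from .lexicon import Lexicon
from .pattern_learning import Pattern, extract_pairs, np_mention_map

logger = logging.getLogger(__name__)

LABELS = ("correct", "partial", "incorrect")

SHEET_COLUMNS = [
    "sentence_key",
    "doc_id",
    "text",
    "pattern",
    "cause_term",
    "effect_term",
    "label_annotator1",
    "label_annotator2",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """One doubly-annotated extracted pair from one sentence."""

    sentence_key: tuple[str, int]
    pattern: str
    pair: tuple[str, str]
    label_a: str | None
    label_b: str | None


def sample_for_curation(
    index: CorpusIndex,
    lex: Lexicon,
    patterns: Sequence[str],
    n_per_pattern: int,
    rng_seed: int,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Uniform per-pattern sample of extraction occurrences for annotation.

    For each pattern, occurrences are sampled without replacement (all of
    them when fewer than ``n_per_pattern`` exist), reproducibly under
    ``rng_seed``. ``directions`` optionally maps pattern ids to
    "forward"/"reverse" surface orientation (default: reverse, the
    "due to" family, where the left mention is the effect). Returns a
    sheet with empty label columns.
    """
    rng = np.random.default_rng(rng_seed)
    mention_map = np_mention_map(index, lex)
    rows = []
    for pat_str in patterns:
        pattern = Pattern.from_string(pat_str)
        occs = sorted(
            extract_pairs(index, pattern, lex, mention_map),
            key=lambda o: (o.key, o.d1, o.d2),
        )
        k = min(n_per_pattern, len(occs))
        chosen = [occs[i] for i in sorted(rng.choice(len(occs), size=k, replace=False))] if occs else []
        direction = (directions or {}).get(pattern.id, "reverse")
        for occ in chosen:
            rec = index.get(occ.key)
            cause, effect = (
                (occ.d1, occ.d2) if direction == "forward" else (occ.d2, occ.d1)
            )
            rows.append(
                {
                    "sentence_key": f"{occ.key[0]}:{occ.key[1]}",
                    "doc_id": occ.key[0],
                    "text": rec.text,
                    "pattern": pattern.id,
                    "cause_term": lex.name_of(cause),
                    "effect_term": lex.name_of(effect),
                    "label_annotator1": "",
                    "label_annotator2": "",
                }
            )
    return pd.DataFrame(rows, columns=SHEET_COLUMNS)


@dataclass
class PrecisionReport:
    """Pair-level precision, exact and partial, per pattern and overall."""

    per_pattern: pd.DataFrame
    n_pairs: int
    n_exact: int
    n_partial: int

    @property
    def exact_precision(self) -> float:
        return self.n_exact / self.n_pairs if self.n_pairs else float("nan")

    @property
    def partial_precision(self) -> float:
        return self.n_partial / self.n_pairs if self.n_pairs else float("nan")


def precision_from_annotations(
    records: Sequence[AnnotationRecord],
) -> PrecisionReport:
    """Precision of extracted pairs from double annotation.

    The gold standard is the set of distinct extracted pairs labeled
    "correct" by *both* annotators (for partial precision: labeled correct
    or partial by both). Precision is |gold| / |distinct extracted pairs|.
    Rows missing a label are excluded with a warning.
    """
    usable = []
    for rec in records:
        if rec.label_a not in LABELS or rec.label_b not in LABELS:
            logger.warning("record %s missing/bad label; excluded", rec.sentence_key)
            continue
        usable.append(rec)

    def tally(rows: Sequence[AnnotationRecord]) -> tuple[int, int, int]:
        pairs = {r.pair for r in rows}
        exact = {
            r.pair
            for r in rows
            if r.label_a == "correct" and r.label_b == "correct"
        }
        partial = {
            r.pair
            for r in rows
            if r.label_a in ("correct", "partial")
            and r.label_b in ("correct", "partial")
        }
        return len(pairs), len(exact), len(partial)

    by_pattern = {}
    for rec in usable:
        by_pattern.setdefault(rec.pattern, []).append(rec)
    rows = []
    for pattern in sorted(by_pattern):
        n, ex, pa = tally(by_pattern[pattern])
        rows.append(
            {
                "pattern": pattern,
                "n_pairs": n,
                "exact_precision": ex / n if n else float("nan"),
                "partial_precision": pa / n if n else float("nan"),
            }
        )
    n, ex, pa = tally(usable)
    return PrecisionReport(
        per_pattern=pd.DataFrame(
            rows,
            columns=["pattern", "n_pairs", "exact_precision", "partial_precision"],
        ),
        n_pairs=n,
        n_exact=ex,
        n_partial=pa,
    )


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Multi-class Cohen's kappa: (p_o - p_e) / (1 - p_e).

    Chance agreement p_e comes from the product of the two annotators'
    marginal label frequencies. In the degenerate case p_e = 1 (both
    annotators use a single identical label) kappa is defined as 1 when
    observed agreement is perfect and 0 otherwise, with a warning.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if not labels_a:
        raise ValueError("empty label vectors")
    n = len(labels_a)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    freq_a = Counter(labels_a)
    freq_b = Counter(labels_b)
    p_e = sum(freq_a[l] * freq_b.get(l, 0) for l in freq_a) / (n * n)
    if p_e >= 1.0:
        logger.warning("degenerate marginals (p_e = 1); kappa set by convention")
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def records_from_sheet(frame: pd.DataFrame) -> list[AnnotationRecord]:
    """Parse a filled annotation sheet back into records."""
    out = []
    for row in frame.itertuples(index=False):
        doc, idx = str(row.sentence_key).rsplit(":", 1)
        out.append(
            AnnotationRecord(
                sentence_key=(doc, int(idx)),
                pattern=row.pattern,
                pair=(row.cause_term, row.effect_term),
                label_a=row.label_annotator1 or None,
                label_b=row.label_annotator2 or None,
            )
        )
    return out
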