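"""Shared-gene / shared-drug analyses over the risk knowledge base.

Two complementary questions about the extracted cause→effect pairs:

* do a disease and its predisposing disease share associated genes (or
  drug treatments) more often than an arbitrary disease pair does? — the
  direct-pair analysis, compared against the all-combinations baseline;
* do two diseases with *similar risk profiles* (many common in-neighbors,
  i.e. shared predisposing diseases) or similar effect profiles share more
  items as the profile overlap grows? — the overlap-curve analysis.

Association tables are plain two-column TSVs (disease term, item) standing
in for OMIM- / GWAS-catalog- / clinical-trials-style extracts. Disease
names are matched to KB concepts by exact normalized-string comparison
(lowercased, punctuation stripped).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .kb_builder import RiskKB

logger = logging.getLogger(__name__)

_NORM_RE = re.compile(r"[^a-z0-9 ]+")


def normalize_name(name: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(_NORM_RE.sub(" ", name.lower()).split())


@dataclass
class AssociationTable:
    """Disease name (normalized) -> set of associated items."""

    items: dict[str, set[str]]
    source: str

    def __len__(self) -> int:
        return len(self.items)

    def get(self, disease: str) -> set[str]:
        return self.items.get(normalize_name(disease), set())

    @property
    def n_associations(self) -> int:
        return sum(len(v) for v in self.items.values())


def load_associations(path, source: str = "") -> AssociationTable:
    """Load a two-column TSV (disease term, item) into a grouped table."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["disease", "item"],
        dtype=str,
        keep_default_na=False,
    )
    if frame.empty:
        raise ValueError(f"association file {path} is empty")
    table: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        table.setdefault(normalize_name(row.disease), set()).add(row.item)
    logger.info(
        "%s: %d diseases, %d associations", source or path, len(table),
        sum(len(v) for v in table.values()),
    )
    return AssociationTable(items=table, source=source)


def map_diseases(kb: RiskKB, table: AssociationTable) -> set[str]:
    """KB concepts whose normalized preferred name matches a table key."""
    mapped = {
        c
        for c in kb.diseases
        if normalize_name(kb.names.get(c, c)) in table.items
    }
    n = len(kb.diseases)
    if not mapped:
        logger.warning("no KB disease mapped to %s", table.source)
    else:
        logger.info(
            "mapped %d/%d KB diseases (%.1f%%) to %s",
            len(mapped), n, 100 * len(mapped) / n if n else 0.0, table.source,
        )
    return mapped


def _shared(table: AssociationTable, kb: RiskKB, d1: str, d2: str) -> int:
    a = table.items.get(normalize_name(kb.names.get(d1, d1)), set())
    b = table.items.get(normalize_name(kb.names.get(d2, d2)), set())
    return len(a & b)


@dataclass
class SharingReport:
    """Direct-pair item sharing vs the all-combinations baseline."""

    n_pairs: int
    n_sharing: int
    percent_sharing: float
    mean_shared_sharing_only: float
    mean_shared_all_pairs: float
    baseline_mean: float
    n_combinations: int


def direct_pair_sharing(kb: RiskKB, table: AssociationTable) -> SharingReport:
    """Item sharing over mapped KB pairs against all mapped combinations.

    Restricts KB (cause, effect) pairs to diseases mapped into the table,
    counts shared items per pair, and compares to the mean over *all*
    unordered combinations of mapped diseases. The per-pair mean is given
    both conditioned on sharing at least one item and over all mapped
    pairs.
    """
    mapped = map_diseases(kb, table)
    if len(mapped) < 2:
        raise ValueError("need at least 2 mapped diseases")
    pair_shares = [
        _shared(table, kb, c, e)
        for (c, e) in kb.pairs
        if c in mapped and e in mapped
    ]
    sharing = [s for s in pair_shares if s > 0]
    combos = [
        _shared(table, kb, a, b)
        for a, b in itertools.combinations(sorted(mapped), 2)
    ]
    n = len(pair_shares)
    return SharingReport(
        n_pairs=n,
        n_sharing=len(sharing),
        percent_sharing=100.0 * len(sharing) / n if n else 0.0,
        mean_shared_sharing_only=(sum(sharing) / len(sharing)) if sharing else 0.0,
        mean_shared_all_pairs=(sum(pair_shares) / n) if n else 0.0,
        baseline_mean=(sum(combos) / len(combos)) if combos else 0.0,
        n_combinations=len(combos),
    )


def profile_overlap_curve(
    kb: RiskKB,
    table: AssociationTable,
    side: str,
    cutoffs: Sequence[int],
) -> pd.DataFrame:
    """Mean shared items vs shared-neighbor cutoff.

    For every unordered pair of mapped diseases, the profile overlap is the
    number of common KB in-neighbors (``side="risk"``: shared predisposing
    diseases) or out-neighbors (``side="effect"``). For each cutoff ``c``
    the mean number of shared items over pairs with overlap ≥ c is
    reported; cutoff 0 therefore equals the all-combinations baseline.
    Cutoffs with no qualifying pair get NaN (undefined), not 0.
    """
    if side not in ("risk", "effect"):
        raise ValueError(f"side must be 'risk' or 'effect', got {side!r}")
    if list(cutoffs) != sorted(cutoffs) or (cutoffs and cutoffs[0] != 0):
        raise ValueError("cutoffs must be ascending and start at 0")
    mapped = sorted(map_diseases(kb, table))
    neigh = {
        d: (kb.causes_of(d) if side == "risk" else kb.effects_of(d))
        for d in mapped
    }
    rows = []
    overlaps_shares = [
        (len(neigh[a] & neigh[b]), _shared(table, kb, a, b))
        for a, b in itertools.combinations(mapped, 2)
    ]
    for cut in cutoffs:
        qualifying = [s for o, s in overlaps_shares if o >= cut]
        rows.append(
            {
                "side": side,
                "cutoff": cut,
                "n_pairs": len(qualifying),
                "mean_shared": (sum(qualifying) / len(qualifying))
                if qualifying
                else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["side", "cutoff", "n_pairs", "mean_shared"])
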