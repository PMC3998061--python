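# Methods

## The extraction model

`riskminer` treats risk-relationship extraction as bootstrapped surface
pattern learning. A *pattern* is the literal token sequence between two
entity mentions in the frame `D1 pattern D2`; no dependency paths or
syntactic generalization are used, because the target relation is
overwhelmingly realized by a small family of highly conventionalized
connectives ("due to", "caused by", "secondary to", "resulting from",
"causing", "as a cause of", …). The model's assumptions, in decreasing
order of importance:

1. **Redundancy.** Each true (cause, effect) pair is stated many times and
   under several different connectives, so the pair pool extracted by one
   reliable seed pattern is a usable gold standard for ranking every other
   pattern.
2. **The noun-phrase constraint.** A mention only counts if its token span
   is *exactly* the span of an NP-labeled constituent in the sentence's
   constituency parse. Exact-span equality (not containment) is deliberate:
   it both rejects fragment mentions (a bare "infection" inside a longer
   noun phrase) and *accepts* truncated-but-valid mentions ("bowen 's
   disease" inside "bowen 's disease of the vulva") when only the shorter
   term is in the lexicon — yielding a partial pair rather than nothing.
3. **Mention maximality.** Among NP-valid mentions, any mention strictly
   contained in another surviving mention is dropped. This implies the
   longest-match rule at shared endpoints and guarantees no two extracted
   mentions are nested; overlapping non-nested mentions are both kept.

Sentences without a parse tree remain phrase-queryable but are excluded
from pair and pattern extraction, since the NP constraint cannot be
checked for them.

### Ranking

With the seed's output `ins(p0)` as gold standard, each pattern *p* is
scored by precision `|ins(p)∩ins(p0)|/|ins(p)|`, recall
`|ins(p)∩ins(p0)|/|ins(p0)|`, and their harmonic mean. `ins(·)` is a set
of **unordered** concept pairs here: a pattern that states the relation in
the opposite surface order ("D1 causing D2" vs "D1 due to D2") describes
the same pair population and must be allowed to overlap the seed's output.
Orientation is recovered separately: the pattern's *ordered* output is
intersected with the seed's ordered output as-is and flipped, and the
larger overlap wins (ties keep the seed's orientation and are flagged
low-confidence). Ranked lists break score ties by seed-first, then larger
support, then pattern id, so ranking is total and deterministic.

### Pair scoring

The aggregate score of a pair from supporting patterns Pᵢ with occurrence
counts count(Pᵢ, R) is available in two modes:

* **literal**: `Σ log(RS(Pᵢ))·count(Pᵢ, R)`. Because RS ≤ 1, every term is
  ≤ 0: more occurrences of an imperfect pattern *lower* the score, and a
  perfect-precision pattern contributes exactly 0 regardless of count.
  Patterns with RS = 0 are excluded (log undefined) with a warning.
* **rectified** (default): `Σ RS(Pᵢ)·log(1 + count(Pᵢ, R))`, strictly
  increasing in both pattern reliability and frequency — the stated intent
  ("a reliable pair is matched by reliable patterns many times") as a
  monotone formula. The mode used is recorded in KB metadata.

Both modes ship because the literal form is the published definition while
the rectified form is the one that orders pairs usefully; all defaults and
exports use rectified scoring.

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| `max_iterations` | 2 | on redundant corpora the second pattern-extraction round adds little; more iterations mainly admit drift |
| early stop | new patterns < 5% of cumulative | "no significant number of new patterns" made concrete; purely a guard, the iteration cap usually binds first |
| `max_pattern_len` | 8 tokens | risk connectives are short; longer gaps are overwhelmingly non-relational |
| `min_pattern_support` | 1 | filtering is deferred to candidate selection, where `select_candidates(min_support=…)` models the ≥100-distinct-pairs criterion used at corpus scale |
| `pattern_cap` | 10,000 per extraction | bounds pattern blow-up on large corpora; never reached on test-scale data |
| zero-length patterns | extracted, excluded from candidates | bare adjacency "D1 D2" is a real, frequent pattern but carries no relational semantics; `include_adjacency=True` re-admits it |
| `seed_direction` | `reverse` | the canonical seed "D1 due to D2" names the effect first |
| kappa degenerate case | p_e = 1 → κ = 1 if p_o = 1 else 0 | keeps the statistic defined when both annotators use one label |

## What the synthetic corpora emulate — and what they do not

The generator (`synthetic_corpus`) emits sentences of exactly the surface
form the extractor assumes: `<D1> <template> <D2> .` with a flat but valid
bracketed parse in which each disease term spans an NP node. Its defaults
define the standing test conditions: 30 diseases (two-token terms from a
clinical-flavored vocabulary), 40 planted directed pairs, four risk
templates ("due to", "caused by", "secondary to" — effect-first — and
"causing" — cause-first), two sentences per (pair, template), and 120
distractor sentences ("and", "with", "in") of which ~30% reuse planted
pairs (so distractor patterns are discoverable but impure) and the rest
connect random non-planted pairs. A 20% nesting rate gives some diseases a
three-token lexicon variant with the shorter term embedded mid-NP,
reproducing the fragment-mention trap. The full default pipeline runs in
well under a minute on one CPU; all test and acceptance runs use these
sizes.

Association tables mint fresh items per unordered disease pair at Poisson
rates: λ_signal = 3 for planted pairs, λ_background = 0.1 otherwise, plus
λ_profile = 0.8 per shared predisposing or effect disease in the planted
graph. The profile term is what gives the overlap-curve analysis a real
correlation to find; λ_profile = 0.8 is set high enough that conditional
means dominate Poisson noise at the default corpus size. Setting
λ_signal = λ_background and λ_profile = 0 yields a structure-independent
null dataset, used to check that the enrichment statistics do not
manufacture signal.

Passing on these corpora demonstrates the *mechanics* — NP filtering,
maximal match, iteration, ranking arithmetic, direction recovery,
aggregation, enrichment bookkeeping — under conditions where the right
answer is known. It does **not** demonstrate robustness to what real text
adds: parser errors, discontinuous or coordinated mentions ("breast and
ovarian cancer"), anaphora, negation and hedging, near-duplicate patterns
("due to" vs "was due to", which are deliberately not merged), lexicon
gaps, and ambiguous term–concept mappings.

## Numerical and representational choices

* Token spans are 0-based half-open everywhere; matching is case-folded
  with Unicode apostrophes normalized to ASCII (so "Bowen’s disease"
  matches "bowen 's disease" after PTB-style tokenization), and original
  casing is preserved in stored text.
* The PTB reader assigns leaf spans left to right in a single pass and
  reports the character offset of any structural error; the canonical
  serializer (single spaces, no outer whitespace) is its exact inverse on
  machine-produced trees.
* A zero-length phrase query matches at every token boundary, which is
  what adjacency-pattern extraction needs.
* `ins(p)` comparisons, supports, and all ranked orderings are computed on
  sets with explicit deterministic tie-breaks; two runs on the same inputs
  are identical, and the generator writes byte-identical files per seed.
* Concept-level aggregation uses lexicon concept ids, so spelling variants
  mapped to one concept merge in the KB; disease↔association mapping is
  exact normalized-name matching (lowercase, punctuation stripped) — no
  fuzzy matching.
* Enrichment reports the per-pair mean both over sharing pairs only and
  over all mapped pairs (the two readings of an "average shared items"
  column), and undefined curve points (no pair reaches a cutoff) are NaN,
  never 0.
* Annotation precision is |pairs labeled correct by both annotators| /
  |distinct extracted pairs| (partial: correct-or-partial by both). The
  package reports the ratio as computed from the counts; it does not try
  to reproduce any particular published rounding of such ratios.

## Known limitations

* Surface patterns only; a relation split across clauses, stated with
  anaphora, or modified by negation/hedging is missed or extracted wrongly.
* Context sensitivity (e.g. a risk relation holding only "in men" or "in
  diabetic populations") is out of scope; pairs are extracted without
  qualifiers.
* One mention per exact span: a term shared by two concepts cannot be
  represented (the lexicon rejects such entries by design).
* The per-pattern direction model assumes a pattern is consistently
  oriented; genuinely bidirectional connectives get whichever orientation
  dominates their overlap with the seed.
* The in-memory index holds the whole corpus; nothing here is engineered
  for corpus scales that need a real search engine.
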