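"""Deterministic toy corpora with planted risk relations and ground truth.

The generator emulates the corpus regime the extractor assumes: redundant
sentences of the surface form ``<D1 tokens> <template tokens> <D2 tokens> .``
with a bracketed parse in which each disease term spans an NP node. A known
set of directed (cause, effect) pairs is planted through a small family of
*risk* templates ("due to", "caused by", "secondary to", "causing") amid
*distractor* templates ("and", "with", "in") that connect mostly random
disease pairs — so pattern ranking against a risk seed has a known right
answer. A configurable fraction of diseases get a long lexicon variant with
the shorter term embedded inside the same NP (the classic trap where a bare
"infection"-style substring must lose to the full noun phrase).

Association tables pair the same diseases with synthetic gene/drug items so
that planted pairs share ~Poisson(λ_signal) items while arbitrary pairs
share ~Poisson(λ_background); shared items are minted fresh per disease
pair, so empirical sharing rates match the λ's without triangle inflation.

Everything is a pure function of the config's RNG seed: the same config
writes byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_index import parse_ptb
from .pattern_learning import FORWARD, REVERSE

_ADJECTIVES = [
    "chronic", "acute", "severe", "benign", "malignant",
    "congenital", "recurrent", "focal", "diffuse", "systemic",
    "refractory", "idiopathic", "progressive", "transient", "occult",
]
_NOUNS = [
    "nephritis", "carcinoma", "fibrosis", "dermatitis", "anemia",
    "neuropathy", "hepatitis", "arthritis", "melanoma", "stenosis",
    "edema", "sepsis", "ischemia", "myopathy", "glaucoma",
    "lymphoma", "colitis", "asthma", "psoriasis", "pancreatitis",
]
_PREFIXES = ["viral", "bacterial", "juvenile", "familial", "atypical"]


@dataclass
class GeneratorConfig:
    """All the dials of the toy corpus; the seed fixes every random draw.

    Defaults are sized so that a two-iteration bootstrap runs in seconds:
    40 planted directed pairs over 30 diseases, every pair realized twice
    under each of four risk templates, plus 120 distractor sentences of
    which ~30% reuse planted pairs (so distractor templates are
    discoverable but impure).
    """

    n_diseases: int = 30
    n_true_pairs: int = 40
    risk_templates: tuple = (
        ("due to", REVERSE),
        ("caused by", REVERSE),
        ("secondary to", REVERSE),
        ("causing", FORWARD),
    )
    distractor_templates: tuple = ("and", "with", "in")
    sentences_per_pair_template: int = 2
    n_noise_sentences: int = 120
    noise_planted_fraction: float = 0.3
    nesting_rate: float = 0.2
    lambda_signal: float = 3.0
    lambda_background: float = 0.1
    lambda_profile: float = 0.8
    assoc_vocab_overlap: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.n_diseases, self.n_true_pairs, self.n_noise_sentences,
               self.sentences_per_pair_template) < 0:
            raise ValueError("all counts must be >= 0")
        if self.n_diseases < 2:
            raise ValueError("need at least 2 diseases")
        for frac_name in ("noise_planted_fraction", "nesting_rate",
                          "assoc_vocab_overlap"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if self.n_true_pairs > self.n_diseases * (self.n_diseases - 1) // 2:
            raise ValueError("n_true_pairs exceeds available disease pairs")
        if self.nesting_rate > 0 and self.n_diseases > len(_ADJECTIVES) * len(_NOUNS):
            raise ValueError("vocabulary too small to build nested variants")
        if min(self.lambda_signal, self.lambda_background, self.lambda_profile) < 0:
            raise ValueError("Poisson rates must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows about what it emitted."""

    diseases: dict[str, str]              # concept id -> preferred name
    roster: list[str]                     # concepts participating in pairs
    planted_pairs: list[tuple[str, str]]  # directed (cause, effect)
    templates: dict[str, dict]            # template string -> {direction, kind}
    sentences: list[dict]                 # per-sentence provenance
    associations: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def planted_unordered(self) -> set[frozenset[str]]:
        return {frozenset(p) for p in self.planted_pairs}

    def risk_template_strings(self) -> list[str]:
        return [t for t, m in self.templates.items() if m["kind"] == "risk"]

    def distractor_template_strings(self) -> list[str]:
        return [t for t, m in self.templates.items() if m["kind"] == "distractor"]

    def save(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_pairs"] = [list(p) for p in self.planted_pairs]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @staticmethod
    def load(path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["planted_pairs"] = [tuple(p) for p in payload["planted_pairs"]]
        payload["sentences"] = [
            {**s, "pair": tuple(s["pair"]) if s["pair"] else None}
            for s in payload["sentences"]
        ]
        return GroundTruth(**payload)


def _np_subtree(tokens: list[str]) -> str:
    tags = ["JJ"] * (len(tokens) - 1) + ["NN"]
    inner = " ".join(f"({t} {w})" for t, w in zip(tags, tokens))
    return f"(NP {inner})"


def _sentence_tree(left: list[str], template: list[str], right: list[str]) -> str:
    mid = " ".join(f"(IN {w})" for w in template)
    vp = f"(VP {mid} {_np_subtree(right)})" if mid else f"(VP {_np_subtree(right)})"
    return f"(S {_np_subtree(left)} {vp} (. .))"


def generate_corpus(
    cfg: GeneratorConfig, out_dir
) -> tuple[Path, Path, GroundTruth]:
    """Emit corpus.jsonl and lexicon.tsv under ``out_dir``; return paths + truth.

    Every emitted tree is round-tripped through the package's own PTB
    reader as a self-check, and each disease mention's expected span is
    recorded in the ground truth.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.rng_seed, 0])

    # Disease vocabulary: 2-token base terms; a nesting_rate fraction of the
    # roster is replaced by a 3-token long variant whose suffix is the base
    # term (kept in the lexicon as a never-planted decoy concept).
    combos = [(a, n) for a in _ADJECTIVES for n in _NOUNS]
    picks = rng.choice(len(combos), size=cfg.n_diseases, replace=False)
    diseases: dict[str, str] = {}
    lexicon_rows: list[tuple[str, str, str]] = []
    roster: list[str] = []
    next_id = 1

    def new_concept(name: str) -> str:
        nonlocal next_id
        cid = f"C{next_id:04d}"
        next_id += 1
        diseases[cid] = name
        lexicon_rows.append((name, cid, name))
        return cid

    n_nested = int(round(cfg.nesting_rate * cfg.n_diseases))
    nested_slots = set(
        rng.choice(cfg.n_diseases, size=n_nested, replace=False).tolist()
    )
    for slot, pick in enumerate(picks.tolist()):
        adj, noun = combos[pick]
        base_name = f"{adj} {noun}"
        base_id = new_concept(base_name)
        if slot in nested_slots:
            prefix = _PREFIXES[slot % len(_PREFIXES)]
            long_id = new_concept(f"{prefix} {base_name}")
            roster.append(long_id)  # the base term stays as a decoy
        else:
            roster.append(base_id)

    # Planted directed pairs: unordered combinations, random orientation —
    # no pair appears in both directions.
    all_combos = [
        (roster[i], roster[j])
        for i in range(len(roster))
        for j in range(i + 1, len(roster))
    ]
    chosen = rng.choice(len(all_combos), size=cfg.n_true_pairs, replace=False)
    planted: list[tuple[str, str]] = []
    for c in chosen.tolist():
        a, b = all_combos[c]
        planted.append((a, b) if rng.random() < 0.5 else (b, a))

    templates: dict[str, dict] = {}
    for t, direction in cfg.risk_templates:
        templates[t] = {"direction": direction, "kind": "risk"}
    for t in cfg.distractor_templates:
        templates[t] = {"direction": None, "kind": "distractor"}

    sentences: list[dict] = []

    def emit(left_id: str, right_id: str, template: str, kind: str,
             pair: tuple[str, str] | None) -> None:
        left = diseases[left_id].split()
        right = diseases[right_id].split()
        tmpl = template.split()
        tokens = left + tmpl + right + ["."]
        tree = _sentence_tree(left, tmpl, right)
        parsed = parse_ptb(tree)  # generator self-check
        assert parsed.leaves() == tokens
        i = len(sentences)
        sentences.append(
            {
                "doc_id": f"SYN{i // 3:05d}",
                "sent_idx": i % 3,
                "text": " ".join(tokens),
                "tree": tree,
                "template": template,
                "kind": kind,
                "left": left_id,
                "right": right_id,
                "pair": pair,
                "mention_spans": [
                    [left_id, 0, len(left)],
                    [right_id, len(left) + len(tmpl),
                     len(left) + len(tmpl) + len(right)],
                ],
            }
        )

    for cause, effect in planted:
        for template, direction in cfg.risk_templates:
            left_id, right_id = (
                (cause, effect) if direction == FORWARD else (effect, cause)
            )
            for _ in range(cfg.sentences_per_pair_template):
                emit(left_id, right_id, template, "risk", (cause, effect))

    planted_unordered = {frozenset(p) for p in planted}
    for _ in range(cfg.n_noise_sentences):
        template = cfg.distractor_templates[
            int(rng.integers(len(cfg.distractor_templates)))
        ]
        if rng.random() < cfg.noise_planted_fraction:
            cause, effect = planted[int(rng.integers(len(planted)))]
            left_id, right_id = (
                (cause, effect) if rng.random() < 0.5 else (effect, cause)
            )
        else:
            while True:
                i, j = rng.choice(len(roster), size=2, replace=False).tolist()
                if frozenset((roster[i], roster[j])) not in planted_unordered:
                    break
            left_id, right_id = roster[i], roster[j]
        emit(left_id, right_id, template, "distractor", None)

    corpus_path = out_dir / "corpus.jsonl"
    with open(corpus_path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(
                json.dumps(
                    {
                        "doc_id": s["doc_id"],
                        "sent_idx": s["sent_idx"],
                        "text": s["text"],
                        "tree": s["tree"],
                    }
                )
                + "\n"
            )
    lexicon_path = out_dir / "lexicon.tsv"
    with open(lexicon_path, "w", encoding="utf-8") as fh:
        for term, cid, name in lexicon_rows:
            fh.write(f"{term}\t{cid}\t{name}\n")

    truth = GroundTruth(
        diseases=diseases,
        roster=roster,
        planted_pairs=planted,
        templates=templates,
        sentences=sentences,
        config=dataclasses.asdict(cfg),
    )
    return corpus_path, lexicon_path, truth


def generate_associations(
    truth: GroundTruth, cfg: GeneratorConfig, out_dir
) -> tuple[Path, Path]:
    """Emit genes.tsv and drugs.tsv keyed by disease preferred names.

    For every unordered roster pair, mint fresh shared items at a Poisson
    rate of λ_signal if the pair is planted and λ_background otherwise,
    plus λ_profile per common neighbor in the planted graph (shared
    predisposing or effect disease) — so disease pairs with similar risk
    profiles share more items, the correlation the overlap-curve analysis
    probes. Each disease also gets one private item so no mapped disease
    has an empty set. ``assoc_vocab_overlap < 1`` renames the
    complementary fraction of disease keys so they no longer map to KB
    names. Setting λ_signal = λ_background and λ_profile = 0 yields a null
    dataset with items independent of the KB structure.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.rng_seed, 1])
    roster = list(truth.roster)
    planted_unordered = truth.planted_unordered
    causes: dict[str, set[str]] = {d: set() for d in roster}
    effects: dict[str, set[str]] = {d: set() for d in roster}
    for cause, effect in truth.planted_pairs:
        causes[effect].add(cause)
        effects[cause].add(effect)

    n_mapped = int(round(cfg.assoc_vocab_overlap * len(roster)))
    mapped_idx = set(rng.choice(len(roster), size=n_mapped, replace=False).tolist())

    def key_for(i: int) -> str:
        name = truth.diseases[roster[i]]
        return name if i in mapped_idx else f"{name} variant"

    paths = []
    for source, prefix in (("genes", "GENE"), ("drugs", "DRUG")):
        counter = 0
        items: dict[str, set[str]] = {key_for(i): set() for i in range(len(roster))}
        for i in range(len(roster)):
            counter += 1
            items[key_for(i)].add(f"{prefix}{counter:05d}")  # private item
        for i in range(len(roster)):
            for j in range(i + 1, len(roster)):
                a, b = roster[i], roster[j]
                lam = (
                    cfg.lambda_signal
                    if frozenset((a, b)) in planted_unordered
                    else cfg.lambda_background
                ) + cfg.lambda_profile * (
                    len(causes[a] & causes[b]) + len(effects[a] & effects[b])
                )
                for _ in range(int(rng.poisson(lam))):
                    counter += 1
                    item = f"{prefix}{counter:05d}"
                    items[key_for(i)].add(item)
                    items[key_for(j)].add(item)
        path = out_dir / f"{source}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            for disease in items:
                for item in sorted(items[disease]):
                    fh.write(f"{disease}\t{item}\n")
        truth.associations[source] = {
            d: sorted(v) for d, v in items.items()
        }
        paths.append(path)
    return paths[0], paths[1]
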