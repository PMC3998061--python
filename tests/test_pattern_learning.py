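"""Pair/pattern extraction, the bootstrap loop, and the ranking scores."""

import math

import numpy as np
import pytest

from riskminer import (
    BootstrapConfig,
    FORWARD,
    Pattern,
    PatternStats,
    REVERSE,
    assign_direction,
    bootstrap,
    build_index,
    extract_pairs,
    extract_patterns,
    rank_f1,
    rank_precision,
    rank_recall,
    score_pair,
    seed_robustness,
)


def make_stats(ins, seed_ins, pattern="p"):
    ins = {frozenset(p) for p in ins}
    seed = {frozenset(p) for p in seed_ins}
    return PatternStats(
        pattern=Pattern.from_string(pattern),
        ins=frozenset(ins),
        ordered=frozenset(),
        overlap=len(ins & seed),
        seed_size=len(seed),
        rs_precision=0.0,
        rs_recall=0.0,
        rs_f1=0.0,
        direction=REVERSE,
    )


# ---------------------------------------------------------------------------
# ranking scores: direct evaluation against set arithmetic

def test_seed_scores_one_against_itself():
    ins = [("a", "b"), ("c", "d")]
    s = make_stats(ins, ins)
    assert rank_precision(s) == 1.0
    assert rank_recall(s) == 1.0
    assert rank_f1(s) == 1.0


def test_precision_is_overlap_over_own_output():
    s = make_stats(
        [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")],
        [("a", "b"), ("c", "d"), ("x", "y"), ("u", "v"), ("m", "n"),
         ("o", "p"), ("q", "r"), ("s", "t")],
    )
    assert rank_precision(s) == pytest.approx(2 / 4)
    assert rank_recall(s) == pytest.approx(2 / 8)
    assert rank_f1(s) == pytest.approx(1 / 3)


def test_disjoint_outputs_score_zero():
    s = make_stats([("a", "b")], [("c", "d")])
    assert rank_precision(s) == 0.0
    assert rank_recall(s) == 0.0
    assert rank_f1(s) == 0.0


def test_scores_match_brute_force_on_random_instances():
    rng = np.random.default_rng(11)
    concepts = [f"C{i}" for i in range(30)]
    for _ in range(200):
        def draw():
            n = int(rng.integers(1, 40))
            return {
                frozenset(rng.choice(concepts, size=2, replace=False))
                for _ in range(n)
            }
        ins, seed = draw(), draw()
        s = make_stats(ins, seed)
        inter = len(ins & seed)
        p, r = inter / len(ins), inter / len(seed)
        assert rank_precision(s) == pytest.approx(p)
        assert rank_recall(s) == pytest.approx(r)
        expected_f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        assert rank_f1(s) == pytest.approx(expected_f1)
        assert (rank_f1(s) == 0) == (inter == 0)


# ---------------------------------------------------------------------------
# extraction against hand-built sentences and generator ground truth

def test_np_rule_extracts_long_herpes_pair(herpes_record, clinical_lexicon):
    idx = build_index([herpes_record])
    pattern = Pattern.from_string("is a risk factor for")
    occs = extract_pairs(idx, pattern, clinical_lexicon)
    assert {(o.d1, o.d2) for o in occs} == {("C_HSV2", "C_HTN")}


def test_bowen_partial_pair_extracted(bowen_record, clinical_lexicon):
    idx = build_index([bowen_record])
    occs = extract_pairs(idx, Pattern.from_string("arising from"), clinical_lexicon)
    assert {(o.d1, o.d2) for o in occs} == {("C_SEB", "C_BOW")}


def test_absent_pattern_extracts_nothing(synth):
    occs = extract_pairs(
        synth.index, Pattern.from_string("is never present"), synth.lexicon
    )
    assert occs == set()


def test_seed_recovers_exactly_the_planted_pairs(synth):
    occs = extract_pairs(synth.index, Pattern.from_string("due to"), synth.lexicon)
    # "due to" is effect-first: surface (d1, d2) = (effect, cause)
    assert {(o.d2, o.d1) for o in occs} == set(synth.truth.planted_pairs)


def test_extract_patterns_recovers_templates_with_supports(synth):
    cfg = BootstrapConfig()
    planted = synth.truth.planted_unordered
    found = dict(extract_patterns(synth.index, planted, synth.lexicon, cfg))
    for template, meta in synth.truth.templates.items():
        pat = Pattern.from_string(template)
        if meta["kind"] == "risk":
            # every planted pair is realized under every risk template
            assert found[pat] == len(planted)
        else:
            assert pat in found


def test_extract_patterns_requires_pairs(synth):
    with pytest.raises(ValueError):
        extract_patterns(synth.index, set(), synth.lexicon, BootstrapConfig())


def test_adjacency_pattern_recovered_from_abutting_mentions(clinical_lexicon):
    from riskminer import SentenceRecord, parse_ptb

    tree = parse_ptb(
        "(S (NP (NN hypertension)) (NP (NN infection)) (. .))"
    )
    rec = SentenceRecord("d", 0, "hypertension infection .", tree.leaves(), tree)
    idx = build_index([rec])
    found = extract_patterns(
        idx,
        {frozenset(("C_HTN", "C_INF"))},
        clinical_lexicon,
        BootstrapConfig(),
    )
    patterns = {p.id: n for p, n in found}
    assert patterns.get("D1 D2") == 1
    occs = extract_pairs(idx, Pattern(()), clinical_lexicon)
    assert {(o.d1, o.d2) for o in occs} == {("C_HTN", "C_INF")}


def test_pattern_gap_may_not_contain_a_mention(clinical_lexicon):
    from riskminer import SentenceRecord, parse_ptb

    # "hypertension due to infection after hypertension": the long gap
    # "due to infection after" contains a lexicon term and is rejected.
    tree = parse_ptb(
        "(S (NP (NN hypertension)) (PP (IN due) (IN to) "
        "(NP (NN infection)) (IN after) (NP (NN hypertension))))"
    )
    rec = SentenceRecord("d", 1, "", tree.leaves(), tree)
    idx = build_index([rec])
    found = extract_patterns(
        idx,
        {frozenset(("C_HTN", "C_INF"))},
        clinical_lexicon,
        BootstrapConfig(),
    )
    ids = {p.id for p, _ in found}
    assert "D1 due to D2" in ids
    assert all("infection" not in pid for pid in ids)


# ---------------------------------------------------------------------------
# bootstrap loop

def test_bootstrap_discovers_all_planted_templates(synth, synth_bootstrap):
    ids = {s.pattern.id for s in synth_bootstrap.stats}
    for template in synth.truth.templates:
        assert Pattern.from_string(template).id in ids


def test_bootstrap_empty_seed_errors(synth):
    with pytest.raises(ValueError, match="seed has empty output"):
        bootstrap(
            synth.index, synth.lexicon, BootstrapConfig(seeds=("nonexistent seed",))
        )


def test_single_iteration_equals_one_pattern_extraction_pass(synth):
    cfg = BootstrapConfig(seeds=("due to",), max_iterations=1)
    res = bootstrap(synth.index, synth.lexicon, cfg)
    seed_occs = extract_pairs(
        synth.index, Pattern.from_string("due to"), synth.lexicon
    )
    expected = {
        p.id
        for p, _ in extract_patterns(
            synth.index,
            {(o.d1, o.d2) for o in seed_occs},
            synth.lexicon,
            cfg,
        )
    } | {"D1 due to D2"}
    assert {s.pattern.id for s in res.stats} == expected


def test_bootstrap_is_deterministic(synth):
    cfg = BootstrapConfig(seeds=("due to",))
    a = bootstrap(synth.index, synth.lexicon, cfg)
    b = bootstrap(synth.index, synth.lexicon, cfg)
    assert [(s.pattern.id, s.rs_f1) for s in a.ranked()] == [
        (s.pattern.id, s.rs_f1) for s in b.ranked()
    ]
    assert a.occurrences == b.occurrences


# ---------------------------------------------------------------------------
# direction assignment

def test_seed_keeps_its_own_direction():
    pairs = {("e1", "c1"), ("e2", "c2")}
    direction, low = assign_direction(pairs, pairs, seed_direction=REVERSE)
    assert direction == REVERSE and not low


def test_opposite_surface_order_flips_direction():
    seed = {("e1", "c1"), ("e2", "c2")}
    flipped = {("c1", "e1"), ("c2", "e2")}
    direction, low = assign_direction(flipped, seed, seed_direction=REVERSE)
    assert direction == FORWARD and not low


def test_zero_overlap_ties_to_seed_and_flags_low_confidence():
    direction, low = assign_direction(
        {("x", "y")}, {("a", "b")}, seed_direction=REVERSE
    )
    assert direction == REVERSE and low


def test_generator_directions_recovered(synth, synth_bootstrap):
    by_id = synth_bootstrap.stats_by_id()
    for template, meta in synth.truth.templates.items():
        if meta["kind"] != "risk":
            continue
        stats = by_id[Pattern.from_string(template).id]
        assert stats.direction == meta["direction"]


# ---------------------------------------------------------------------------
# pair scoring

def test_literal_mode_gives_zero_for_perfect_pattern():
    assert score_pair([(1.0, 5)], mode="literal") == 0.0


def test_rectified_single_pattern_closed_form():
    assert score_pair([(1.0, 1)], mode="rectified") == pytest.approx(math.log(2))


def test_literal_mode_excludes_zero_scores():
    assert score_pair([(0.0, 3)], mode="literal") == 0.0  # excluded, not -inf


def test_rectified_monotone_in_counts_and_scores():
    rng = np.random.default_rng(5)
    for _ in range(1000):
        n = int(rng.integers(1, 6))
        scores = rng.uniform(0.05, 1.0, size=n)
        counts = rng.integers(1, 50, size=n)
        base = score_pair(list(zip(scores, counts)))
        i = int(rng.integers(n))
        bumped_counts = counts.copy()
        bumped_counts[i] += 1
        assert score_pair(list(zip(scores, bumped_counts))) > base
        bumped_scores = scores.copy()
        bumped_scores[i] = min(1.0, bumped_scores[i] + 0.05)
        assert score_pair(list(zip(bumped_scores, counts))) >= base


# ---------------------------------------------------------------------------
# seed robustness

def test_identical_seeds_give_identical_rows(synth):
    refs = synth.truth.risk_template_strings()
    table = seed_robustness(
        synth.index, synth.lexicon, ["due to", "due to"], refs, [5, 10]
    )
    assert list(table.iloc[0]) == list(table.iloc[1])


def test_risk_seed_beats_distractor_seed_at_top_ranks(synth):
    refs = synth.truth.risk_template_strings()
    k = len(refs)
    table = seed_robustness(
        synth.index, synth.lexicon, ["due to", "and"], refs, [k, 100]
    )
    assert table.loc["due to", k] >= table.loc["and", k]
    assert table.loc["due to", k] == k
    # a cutoff beyond the pattern count returns every reference found at all
    assert table.loc["due to", 100] == k
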