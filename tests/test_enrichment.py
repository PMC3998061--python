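"""Shared-gene/drug analyses: mapping, direct sharing, overlap curves."""

import math

import numpy as np
import pytest

from riskminer import (
    AssociationTable,
    GeneratorConfig,
    direct_pair_sharing,
    generate_associations,
    generate_corpus,
    load_associations,
    map_diseases,
    profile_overlap_curve,
)
from riskminer.enrichment import normalize_name
from riskminer.kb_builder import RiskKB, RiskPair


def kb_from_pairs(pairs, names=None):
    """Minimal KB straight from directed concept pairs."""
    kb_pairs = {
        (c, e): RiskPair(c, e, {"D1 due to D2": 1}, 1.0, (("d", 0),))
        for c, e in pairs
    }
    all_names = {}
    for c, e in pairs:
        all_names[c] = (names or {}).get(c, c)
        all_names[e] = (names or {}).get(e, e)
    return RiskKB(pairs=kb_pairs, names=all_names)


def table_from(mapping, source="test"):
    return AssociationTable(
        items={normalize_name(k): set(v) for k, v in mapping.items()},
        source=source,
    )


# ---------------------------------------------------------------------------
# loading and mapping

def test_load_associations_groups_and_dedupes(tmp_path):
    p = tmp_path / "assoc.tsv"
    p.write_text(
        "obesity\tFTO\nobesity\tMC4R\nobesity\tFTO\n"
        "stroke\tAPOE\nstroke\tNOTCH3\nhypertension\tAGT\n"
    )
    table = load_associations(p, "omim-like")
    assert len(table) == 3
    assert table.n_associations == 5
    assert table.get("Obesity") == {"FTO", "MC4R"}
    assert table.get("unknown disease") == set()


def test_empty_association_file_errors(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    with pytest.raises(ValueError):
        load_associations(p)


def test_identical_vocabularies_map_fully():
    kb = kb_from_pairs([("a", "b"), ("b", "c")])
    table = table_from({"a": ["g1"], "b": ["g2"], "c": ["g3"]})
    assert map_diseases(kb, table) == {"a", "b", "c"}


def test_disjoint_vocabularies_map_nothing():
    kb = kb_from_pairs([("a", "b")])
    table = table_from({"x": ["g1"]})
    assert map_diseases(kb, table) == set()


def test_partial_vocabulary_overlap_fraction(tmp_path):
    cfg = GeneratorConfig(rng_seed=2, assoc_vocab_overlap=0.7)
    _, _, truth = generate_corpus(cfg, tmp_path)
    genes_path, _ = generate_associations(truth, cfg, tmp_path)
    table = load_associations(genes_path, "genes")
    kb = kb_from_pairs(
        truth.planted_pairs, names=truth.diseases
    )
    mapped = map_diseases(kb, table)
    kb_n = len(kb.diseases)
    expected = round(0.7 * len(truth.roster))
    # every KB disease is on the roster; the mapped count is the overlap
    # sample restricted to diseases that actually appear in planted pairs
    assert len(mapped) <= expected
    assert len(mapped) / kb_n == pytest.approx(0.7, abs=0.15)


# ---------------------------------------------------------------------------
# direct pair sharing

def test_single_pair_sharing_three_items():
    kb = kb_from_pairs([("a", "b")])
    table = table_from({"a": ["g1", "g2", "g3", "g4"], "b": ["g1", "g2", "g3"]})
    rep = direct_pair_sharing(kb, table)
    assert rep.percent_sharing == 100.0
    assert rep.mean_shared_sharing_only == 3
    assert rep.mean_shared_all_pairs == 3
    assert rep.n_combinations == 1


def test_no_shared_items_anywhere():
    kb = kb_from_pairs([("a", "b"), ("b", "c")])
    table = table_from({"a": ["g1"], "b": ["g2"], "c": ["g3"]})
    rep = direct_pair_sharing(kb, table)
    assert rep.percent_sharing == 0.0
    assert rep.mean_shared_sharing_only == 0.0
    assert rep.baseline_mean == 0.0


def test_share_counts_are_symmetric():
    table = table_from({"a": ["g1", "g2"], "b": ["g2", "g3"]})
    fwd = direct_pair_sharing(kb_from_pairs([("a", "b")]), table)
    rev = direct_pair_sharing(kb_from_pairs([("b", "a")]), table)
    assert fwd.mean_shared_all_pairs == rev.mean_shared_all_pairs


def test_planted_signal_exceeds_baseline(synth):
    kb = kb_from_pairs(synth.truth.planted_pairs, names=synth.truth.diseases)
    table = load_associations(synth.genes_path, "genes")
    rep = direct_pair_sharing(kb, table)
    assert rep.mean_shared_all_pairs > rep.baseline_mean
    assert rep.percent_sharing > 0


def test_null_association_data_shows_no_signal(tmp_path):
    """With equal Poisson rates the risk-pair mean matches the baseline."""
    diffs = []
    for seed in range(20):
        cfg = GeneratorConfig(
            rng_seed=100 + seed,
            lambda_signal=0.5,
            lambda_background=0.5,
            lambda_profile=0.0,
        )
        _, _, truth = generate_corpus(cfg, tmp_path / str(seed))
        genes_path, _ = generate_associations(truth, cfg, tmp_path / str(seed))
        table = load_associations(genes_path, "genes")
        kb = kb_from_pairs(truth.planted_pairs, names=truth.diseases)
        rep = direct_pair_sharing(kb, table)
        diffs.append(rep.mean_shared_all_pairs - rep.baseline_mean)
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / math.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se + 1e-12


# ---------------------------------------------------------------------------
# profile overlap curves

def test_cutoff_zero_equals_all_combinations_baseline(synth):
    kb = kb_from_pairs(synth.truth.planted_pairs, names=synth.truth.diseases)
    table = load_associations(synth.genes_path, "genes")
    rep = direct_pair_sharing(kb, table)
    curve = profile_overlap_curve(kb, table, "risk", [0, 1, 2])
    assert curve.loc[curve.cutoff == 0, "mean_shared"].iloc[0] == pytest.approx(
        rep.baseline_mean
    )
    assert curve.loc[curve.cutoff == 0, "n_pairs"].iloc[0] == rep.n_combinations


def test_curve_nondecreasing_when_overlap_predicts_sharing():
    # risk profiles and shared items built to correlate: diseases a and b
    # share two causes and two genes; c and d share nothing
    pairs = [("x", "a"), ("x", "b"), ("y", "a"), ("y", "b"), ("z", "c")]
    kb = kb_from_pairs(pairs)
    table = table_from(
        {
            "a": ["g1", "g2"],
            "b": ["g1", "g2"],
            "c": ["g3"],
            "d": ["g4"],
            "x": ["g5"],
            "y": ["g6"],
            "z": ["g7"],
        }
    )
    curve = profile_overlap_curve(kb, table, "risk", [0, 1, 2])
    values = curve["mean_shared"].tolist()
    assert values == sorted(values)
    assert values[-1] == 2.0  # only (a, b) shares >= 2 risk diseases


def test_unreached_cutoffs_are_undefined_not_zero():
    kb = kb_from_pairs([("x", "a"), ("y", "b")])  # no shared neighbors
    table = table_from({"a": ["g1"], "b": ["g1"], "x": [], "y": []})
    curve = profile_overlap_curve(kb, table, "risk", [0, 1])
    assert math.isnan(curve.loc[curve.cutoff == 1, "mean_shared"].iloc[0])
    assert curve.loc[curve.cutoff == 1, "n_pairs"].iloc[0] == 0


def test_effect_side_uses_out_neighbors():
    pairs = [("a", "x"), ("b", "x"), ("a", "y"), ("b", "y")]
    kb = kb_from_pairs(pairs)
    table = table_from({"a": ["g1"], "b": ["g1"], "x": [], "y": []})
    curve = profile_overlap_curve(kb, table, "effect", [0, 1, 2])
    # a and b share two effect diseases and one gene
    assert curve.loc[curve.cutoff == 2, "mean_shared"].iloc[0] == 1.0


def test_bad_cutoff_lists_rejected(synth):
    kb = kb_from_pairs(synth.truth.planted_pairs, names=synth.truth.diseases)
    table = load_associations(synth.genes_path, "genes")
    with pytest.raises(ValueError):
        profile_overlap_curve(kb, table, "risk", [1, 2])
    with pytest.raises(ValueError):
        profile_overlap_curve(kb, table, "sideways", [0, 1])
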