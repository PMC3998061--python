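"""Shared fixtures: hand-built clinical sentences and a synthetic corpus."""

import pytest

from riskminer import (
    BootstrapConfig,
    GeneratorConfig,
    Lexicon,
    SentenceRecord,
    bootstrap,
    build_index,
    generate_associations,
    generate_corpus,
    load_corpus,
    load_lexicon,
    parse_ptb,
)

# The classic NP-constraint trap: the bare "infection" token sits inside a
# six-token noun phrase and must lose to the full mention.
HERPES_TREE = (
    "(S (NP (NN herpes) (NN simplex) (NN virus) (NN type) (CD 2) (NN infection)) "
    "(VP (VBZ is) (NP (NP (DT a) (NN risk) (NN factor)) "
    "(PP (IN for) (NP (NN hypertension))))))"
)

# Partial-pair behavior: "bowen 's disease" is itself an NP inside the larger
# phrase "bowen 's disease of the vulva", and only the short form is in the
# lexicon, so the truncated pair is extracted.
BOWEN_TREE = (
    "(ROOT (NP (NP (JJ sebaceous) (NN carcinoma)) (VP (VBG arising) "
    "(PP (IN from) (NP (NP (NP (NN bowen) (POS 's)) (NN disease)) "
    "(PP (IN of) (NP (DT the) (NN vulva))))))))"
)


@pytest.fixture
def herpes_record():
    tree = parse_ptb(HERPES_TREE)
    return SentenceRecord(
        doc_id="15492472",
        sent_idx=0,
        text="Herpes simplex virus type 2 infection is a risk factor for hypertension",
        tokens=tree.leaves(),
        tree=tree,
    )


@pytest.fixture
def bowen_record():
    tree = parse_ptb(BOWEN_TREE)
    return SentenceRecord(
        doc_id="3767405",
        sent_idx=0,
        text="Sebaceous carcinoma arising from Bowen’s disease of the vulva",
        tokens=tree.leaves(),
        tree=tree,
    )


@pytest.fixture
def clinical_lexicon():
    lex = Lexicon()
    lex.add("infection", "C_INF", "Infection")
    lex.add(
        "herpes simplex virus type 2 infection",
        "C_HSV2",
        "Herpes simplex virus type 2 infection",
    )
    lex.add("hypertension", "C_HTN", "Hypertension")
    lex.add("sebaceous carcinoma", "C_SEB", "Sebaceous carcinoma")
    lex.add("Bowen’s disease", "C_BOW", "Bowen's disease")  # curly apostrophe
    return lex


class SynthWorld:
    """A generated corpus with its index, lexicon, and ground truth."""

    def __init__(self, root, cfg):
        self.cfg = cfg
        self.corpus_path, self.lexicon_path, self.truth = generate_corpus(cfg, root)
        self.genes_path, self.drugs_path = generate_associations(
            self.truth, cfg, root
        )
        records, self.n_skipped = load_corpus(self.corpus_path)
        self.records = records
        self.lexicon = load_lexicon(self.lexicon_path)
        self.index = build_index(records)


@pytest.fixture(scope="session")
def synth(tmp_path_factory):
    """Default-condition synthetic world (fixed seed)."""
    return SynthWorld(tmp_path_factory.mktemp("synth"), GeneratorConfig(rng_seed=0))


@pytest.fixture(scope="session")
def synth_bootstrap(synth):
    """Two-iteration bootstrap from the canonical risk seed."""
    return bootstrap(synth.index, synth.lexicon, BootstrapConfig(seeds=("due to",)))
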