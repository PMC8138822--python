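import pandas as pd
import pytest

from fibroscreen.kb import (
    CompoundRecord,
    DiseaseRecord,
    EvidenceLink,
    KnowledgeBase,
    LinkType,
    TargetRecord,
)


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    """3 compounds, 2 targets, 1 disease; a handful of evidence links."""
    compounds = {
        "C1": CompoundRecord("C1", "ethanol", "CCO", True, frozenset({"drugbank"})),
        "C2": CompoundRecord("C2", "benzene", "c1ccccc1", False, frozenset({"literature"})),
        "C3": CompoundRecord("C3", "no-structure", None, False, frozenset({"trial"})),
    }
    targets = {
        "T1": TargetRecord("T1", symbol="tgfb1", entrez="7040"),
        "T2": TargetRecord("T2", symbol="SMAD3"),
    }
    diseases = {"D1": DiseaseRecord("D1", "pulmonary fibrosis")}
    links = [
        EvidenceLink("C1", "T1", LinkType.COMPOUND_TARGET, "literature", "PMID:1"),
        EvidenceLink("C1", "T2", LinkType.COMPOUND_TARGET, "ctd", "CTD:x"),
        EvidenceLink("C1", "D1", LinkType.COMPOUND_DISEASE, "trial", "NCT1"),
        EvidenceLink("C2", "T1", LinkType.COMPOUND_TARGET, "literature", "PMID:2"),
        EvidenceLink("T1", "D1", LinkType.TARGET_DISEASE, "ctd", "CTD:y"),
    ]
    return KnowledgeBase(compounds, targets, diseases, links)


@pytest.fixture
def tiny_kb_tables(tmp_path, tiny_kb):
    """The tiny KB written to its four TSV tables."""
    from fibroscreen.kb import write_kb

    return write_kb(tiny_kb, tmp_path / "kb")


@pytest.fixture(scope="session")
def small_structural_corpus():
    """Small planted-signal fingerprint corpus shared across tests."""
    from fibroscreen.synthetic import SynthConfig, generate_structural_corpus

    return generate_structural_corpus(
        SynthConfig(n_pos=120, n_neg=120, n_informative=5, effect_size=0.5, seed=7)
    )


@pytest.fixture(scope="session")
def small_biological_corpus():
    from fibroscreen.synthetic import SynthConfig, generate_biological_corpus

    return generate_biological_corpus(
        SynthConfig(
            n_pos=80, n_neg=80, n_features=120, n_informative=10,
            effect_size=1.0, seed=11,
        )
    )
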