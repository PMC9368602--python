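"""Shared fixtures: a tiny hand-built knowledge network and helpers."""

import numpy as np
import pytest

from knrank import (
    FindingCategory,
    KnowledgeNetwork,
    Lexicon,
    scheme_from_label,
)


@pytest.fixture
def scheme137():
    return scheme_from_label("<137>")


@pytest.fixture
def tiny_kn(scheme137):
    """Two diseases, three findings.

    F1 (common)    -> D1
    F2 (common)    -> D1, D2
    F3 (auxiliary) -> D2   (exclusive: support ratio 1 for D2)
    """
    kn = KnowledgeNetwork()
    kn.add_disease("D1", "gastritis")
    kn.add_disease("D2", "reflux")
    kn.add_finding("F1", "epigastric pain")
    kn.add_finding("F2", "nausea")
    kn.add_finding("F3", "endoscopy positive")
    kn.add_edge("F1", "D1", FindingCategory.COMMON, scheme=scheme137)
    kn.add_edge("F2", "D1", FindingCategory.COMMON, scheme=scheme137)
    kn.add_edge("F2", "D2", FindingCategory.COMMON, scheme=scheme137)
    kn.add_edge("F3", "D2", FindingCategory.AUXILIARY, scheme=scheme137)
    return kn


@pytest.fixture
def tiny_lexicon(tiny_kn):
    return Lexicon(
        entries=[
            ("epigastric pain", "F1"),
            ("nausea", "F2"),
            ("endoscopy positive", "F3"),
        ],
        negation_cues=["no", "denies", "without"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_kn(rng, n_diseases=5, n_findings=8, p_edge=0.5) -> KnowledgeNetwork:
    """Random valid KN for round-trip and property tests."""
    kn = KnowledgeNetwork()
    cats = list(FindingCategory)
    for i in range(n_diseases):
        kn.add_disease(f"d{i}", f"disease {i}")
    for j in range(n_findings):
        kn.add_finding(f"f{j}", f"finding {j}")
    for j in range(n_findings):
        targets = [i for i in range(n_diseases) if rng.random() < p_edge]
        if not targets:
            targets = [int(rng.integers(n_diseases))]
        for i in targets:
            cat = cats[int(rng.integers(3))]
            weight = float(rng.integers(1, 10)) / 2.0
            kn.add_edge(f"f{j}", f"d{i}", cat, weight)
    return kn
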