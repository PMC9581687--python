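import numpy as np
import pytest

from kbrnn.kg import KIND_ADD, KIND_MAIN, KIND_SYN, Entity, KnowledgeGraph, RelationTriple


@pytest.fixture
def worked_kg() -> KnowledgeGraph:
    """Small diagnosis graph around the worked SYN2/SYN3 example.

    SYN2 links main {SYM3, SYM4, SYM5} and additional {SYM2, SYM7}; SYN3
    shares SYM4/SYM2/SYM7, so the sentence <SYM4 | SYM2, SYM7> labeled SYN3
    is the classic misrecognition hazard for SYN2's seeded rule.
    """
    mains = {
        0: ("tremor", ["tremor"]),
        1: ("stiff", ["stiff"]),
        3: ("stiff neck", ["stiff neck"]),
        4: ("delayed motor development", ["delayed motor development", "motor delay"]),
        5: ("limb spasm", ["limb spasm", "spasm"]),
    }
    adds = {
        2: ("night crying", ["night crying"]),
        6: ("poor appetite", ["poor appetite"]),
        7: ("restless sleep", ["restless sleep"]),
    }
    return KnowledgeGraph(
        main_symptoms=[Entity(i, KIND_MAIN, n, tuple(a)) for i, (n, a) in mains.items()],
        additional_symptoms=[Entity(i, KIND_ADD, n, tuple(a)) for i, (n, a) in adds.items()],
        syndromes=[Entity(i, KIND_SYN, f"SYN{i}", (f"SYN{i}",)) for i in range(4)],
        triples=(
            [RelationTriple(2, s, KIND_MAIN) for s in (3, 4, 5)]
            + [RelationTriple(2, s, KIND_ADD) for s in (2, 7)]
            + [RelationTriple(3, s, KIND_MAIN) for s in (0, 4)]
            + [RelationTriple(3, s, KIND_ADD) for s in (2, 7)]
            + [RelationTriple(0, 0, KIND_MAIN), RelationTriple(0, 6, KIND_ADD),
               RelationTriple(1, 1, KIND_MAIN), RelationTriple(1, 6, KIND_ADD)]
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
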