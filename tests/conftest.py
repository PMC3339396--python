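import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from contextabc.corpus import Abstract, Corpus, split_corpus
from contextabc.dictionaries import Role
from contextabc.dictionaries import dictionary_from_rows


@pytest.fixture
def interaction_dict():
    """Small drug/gene/disease dictionary with a synonym pair."""
    return dictionary_from_rows(
        [
            ("donepezil", "D1", "drug"),
            ("aricept", "D1", "drug"),  # synonym of donepezil
            ("ache", "G1", "gene"),
            ("acetylcholinesterase", "G1", "gene"),
            ("tau", "G2", "gene"),
            ("alzheimer disease", "Z1", "disease"),
            ("dementia", "Z2", "disease"),
        ],
        Role.INTERACTION,
    )


@pytest.fixture
def context_dict():
    """Context dictionary over single-token terms a/b/c plus a multiword term."""
    return dictionary_from_rows(
        [
            ("amyloid", "a", "symptom"),
            ("plaques", "b", "symptom"),
            ("cognition", "c", "symptom"),
            ("memory loss", "m", "symptom"),
        ],
        Role.CONTEXT,
    )


def make_corpus(*texts: str, split: bool = True) -> Corpus:
    c = Corpus([Abstract(id=str(i + 1), text=t) for i, t in enumerate(texts)])
    return split_corpus(c) if split else c


@pytest.fixture
def worked_example(interaction_dict, context_dict):
    """Two-abstract worked example mirroring the averaged-context-vector figure.

    Abstract 1 holds the drug–gene interaction D1–G1 with context terms
    a, b, a; abstract 2 holds the gene–disease interaction G1–Z1 with
    context terms a, c, c.
    """
    corpus = make_corpus(
        "Donepezil inhibits ACHE. Amyloid deposits with plaques and amyloid.",
        "ACHE is linked to Alzheimer disease. Amyloid affects cognition and cognition.",
    )
    return corpus, interaction_dict, context_dict
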