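import numpy as np
import pytest
from hypothesis import settings

from circloc import LabeledRecord, RnaSequence, SequenceSet
from circloc.seqio import AnnotationRow

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def seq(id_: str, residues: str) -> RnaSequence:
    return RnaSequence(id=id_, residues=residues)


# Frozen 40-mer sequences with a verified identity structure:
# S6 is a 5-substitution copy of S1 (global identity 0.875 >= 0.8); every
# other pair sits well below 0.8 (0.35-0.45).
TOY_SEQUENCES = {
    "S1": "UGGUGUUAACCUUACUAUACUCCCGCUCCGGGGUUUGGCU",
    "S2": "CAUAUGAACAAGUCUUUGCGCCCAUAAAUGUAGCCAGUGA",
    "S3": "GCUUAGUUGGAGCAAGGGGUGCGGAAGCGCAACUCCGUCG",
    "S4": "CGCGGGUAGCCAACUACUUAAGACCUAGGAUUCUGUUGCA",
    "S6": "UGGUGUUUAUCUUACUAUACCCCCGCUCGGGGGUUUCGCU",
}


@pytest.fixture
def toy_workflow_input():
    """Six-record input exercising all three cleaning rules.

    One multi-locality row (dropped first), one exact cross-tissue duplicate
    (collapsed), one cross-class near-duplicate (removed by the redundancy
    reducer): stage survivor counts must be 6 -> 5 -> 4 -> 3.
    """
    t = TOY_SEQUENCES
    sequences = [
        seq("S1", t["S1"]),
        seq("S2", t["S2"]),
        seq("S3", t["S3"]),
        seq("S4", t["S4"]),
        seq("S5", t["S1"]),  # exact duplicate of S1, other tissue
        seq("S6", t["S6"]),  # near-duplicate of S1 labeled into another class
    ]
    rows = [
        AnnotationRow("S1", frozenset({"Exosome"}), "K562"),
        AnnotationRow("S2", frozenset({"Exosome"}), "HepG2"),
        AnnotationRow("S3", frozenset({"Cytosol"}), "Blood"),
        AnnotationRow("S4", frozenset({"Exosome", "Nucleus"}), "HeLa-S3"),
        AnnotationRow("S5", frozenset({"Exosome"}), "Serum"),
        AnnotationRow("S6", frozenset({"Cytosol"}), "K562"),
    ]
    return SequenceSet(sequences), rows


@pytest.fixture
def tiny_records(rng):
    """A small two-class labeled set with an obvious compositional signal."""
    records = []
    for i in range(12):
        a_rich = "".join("A" if u < 0.7 else "CGU"[rng.integers(3)] for u in rng.random(60))
        g_rich = "".join("G" if u < 0.7 else "ACU"[rng.integers(3)] for u in rng.random(60))
        records.append(LabeledRecord(seq(f"a{i}", a_rich), "Exosome", "K562"))
        records.append(LabeledRecord(seq(f"g{i}", g_rich), "Cytosol", "HepG2"))
    return records
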