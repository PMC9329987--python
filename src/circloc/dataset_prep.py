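"""Benchmark-dataset preparation: multi-locality filtering, cross-tissue
deduplication and greedy cross-class redundancy reduction.

The workflow mirrors how sub-cellular localization benchmarks are assembled
from locality databases: sequences annotated to more than one compartment are
discarded, exact duplicates across tissues are collapsed (or dropped when
their labels conflict), and sequences of one compartment that are highly
similar (identity >= 0.8 by default) to retained sequences of a larger
compartment are excluded, CD-HIT-2D style. Classes are visited in descending
size order (ties broken by schema order) and removal always hits the smaller
class; within-class similarity is never grounds for removal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from .seqio import (
    AnnotationRow,
    RnaSequence,
    SequenceSet,
    read_annotations,
    read_fasta,
)

logger = logging.getLogger(__name__)

#: The eight-compartment locality schema, in benchmark order.
DEFAULT_SCHEMA: tuple[str, ...] = (
    "Exosome",
    "Cytosol",
    "Nucleus",
    "Membrane",
    "Nucleolus",
    "Nucleoplasm",
    "Chromatin",
    "Insoluble Cytoplasm",
)

#: Tissues/cell lines carried through as provenance tags.
TISSUES: tuple[str, ...] = ("K562", "HepG2", "Blood", "HeLa-S3", "Serum")


class SchemaError(ValueError):
    """A locality label outside the configured schema."""


@dataclass(frozen=True)
class LabeledRecord:
    """A sequence with its single locality label and tissue tag."""

    sequence: RnaSequence
    locality: str
    tissue: str


@dataclass
class PreparedDataset:
    """Cleaned records plus a provenance log of per-stage survivor counts."""

    records: list[LabeledRecord]
    provenance: dict[str, int] = field(default_factory=dict)
    schema: tuple[str, ...] = DEFAULT_SCHEMA

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequences(self) -> list[RnaSequence]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.locality for r in self.records]

    def class_sizes(self) -> dict[str, int]:
        counts = Counter(self.labels)
        return {label: counts[label] for label in self.schema if counts[label]}


RawRecord = tuple[RnaSequence, frozenset[str], str]


def validate_schema(labels: Iterable[str], schema: Sequence[str] = DEFAULT_SCHEMA) -> None:
    unknown = sorted(set(labels) - set(schema))
    if unknown:
        raise SchemaError(f"locality label(s) outside the schema: {unknown}")


def filter_multilocal(raw: Sequence[RawRecord]) -> tuple[list[LabeledRecord], int]:
    """Drop rows annotated to more than one locality; return survivors and count removed."""
    kept: list[LabeledRecord] = []
    removed = 0
    for sequence, localities, tissue in raw:
        if not localities:
            raise ValueError(f"empty locality set for sequence {sequence.id!r}")
        if len(localities) > 1:
            removed += 1
            continue
        (locality,) = localities
        kept.append(LabeledRecord(sequence, locality, tissue))
    if removed:
        logger.info("filter_multilocal: removed %d multi-locality rows", removed)
    return kept, removed


def deduplicate(records: Sequence[LabeledRecord]) -> tuple[list[LabeledRecord], int]:
    """Collapse exact-duplicate sequences across tissues.

    Duplicates agreeing on locality keep one representative (the first seen);
    identical sequences with conflicting localities are dropped entirely.
    """
    groups: dict[str, list[LabeledRecord]] = {}
    order: list[str] = []
    for record in records:
        key = record.sequence.residues
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(record)
    kept: list[LabeledRecord] = []
    removed = 0
    for key in order:
        group = groups[key]
        labels = {r.locality for r in group}
        if len(labels) == 1:
            kept.append(group[0])
            removed += len(group) - 1
        else:  # conflicting labels: ambiguous, drop all copies
            removed += len(group)
    if removed:
        logger.info("deduplicate: removed %d duplicate/conflicting rows", removed)
    return kept, removed


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: RnaSequence, b: RnaSequence) -> float:
    """Global-alignment identity: identical aligned residues / shorter length.

    Alignment scoring is match +1, mismatch 0, unit gap penalty; the gap
    penalty shapes the alignment only and does not enter the identity value.
    """
    if not a.residues or not b.residues:
        raise ValueError("pairwise_identity requires non-empty sequences")
    alignment = _ALIGNER.align(a.residues, b.residues)[0]
    identities = alignment.counts().identities
    return identities / min(a.length, b.length)


_PREFILTER_K = 4


def _kmer_counter(residues: str, k: int = _PREFILTER_K) -> Counter:
    return Counter(residues[i : i + k] for i in range(len(residues) - k + 1))


def _prefilter_can_reach(
    counter_a: Counter, counter_b: Counter, shorter: int, threshold: float
) -> bool:
    """Safe k-mer-sharing bound: True unless identity provably < threshold.

    If the identity is >= t, at most (1-t)*Ls aligned columns of the shorter
    sequence are mismatched or gapped, and each such column destroys at most k
    of its Ls-k+1 k-mer windows, so the sequences must share at least
    Ls-k+1 - k*(1-t)*Ls window k-mers (counted with multiplicity). The k-mer
    multiset intersection upper-bounds the shared windows, so falling below
    the bound rules the pair out.
    """
    required = (shorter - _PREFILTER_K + 1) - _PREFILTER_K * (1.0 - threshold) * shorter
    if required <= 0:
        return True
    shared = sum((counter_a & counter_b).values())
    return shared >= required


def reduce_redundancy(
    records: Sequence[LabeledRecord],
    threshold: float = 0.8,
    schema: Sequence[str] = DEFAULT_SCHEMA,
) -> tuple[list[LabeledRecord], dict[str, int]]:
    """Greedy cross-class redundancy reduction at the given identity threshold.

    Classes are processed in descending size order (schema order breaks ties);
    a record is removed when its identity to any retained record of an earlier
    class reaches the threshold. Returns survivors (input order preserved) and
    per-class removal counts.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    validate_schema((r.locality for r in records), schema)
    sizes = Counter(r.locality for r in records)
    class_order = sorted(
        sizes, key=lambda label: (-sizes[label], schema.index(label))
    )
    by_class: dict[str, list[LabeledRecord]] = {label: [] for label in class_order}
    for record in records:
        by_class[record.locality].append(record)

    retained_prev: list[tuple[LabeledRecord, Counter]] = []
    removed_per_class: dict[str, int] = {}
    surviving: set[int] = set()
    for label in class_order:
        removed = 0
        survivors_here: list[tuple[LabeledRecord, Counter]] = []
        for record in by_class[label]:
            counter = _kmer_counter(record.sequence.residues)
            redundant = False
            for earlier, earlier_counter in retained_prev:
                shorter = min(record.sequence.length, earlier.sequence.length)
                if not _prefilter_can_reach(counter, earlier_counter, shorter, threshold):
                    continue
                if pairwise_identity(record.sequence, earlier.sequence) >= threshold:
                    redundant = True
                    break
            if redundant:
                removed += 1
            else:
                survivors_here.append((record, counter))
                surviving.add(id(record))
        retained_prev.extend(survivors_here)
        removed_per_class[label] = removed
        if removed:
            logger.info("reduce_redundancy: removed %d from %s", removed, label)
    kept = [r for r in records if id(r) in surviving]
    return kept, removed_per_class


def prepare_dataset(
    seqset: SequenceSet,
    annotations: Sequence[AnnotationRow],
    threshold: float = 0.8,
    schema: Sequence[str] = DEFAULT_SCHEMA,
) -> PreparedDataset:
    """Run the full cleaning pipeline on in-memory inputs.

    Provenance records the survivor count after each stage:
    input -> single_locality -> deduplicated -> nonredundant.
    """
    raw: list[RawRecord] = []
    for row in annotations:
        try:
            sequence = seqset[row.id]
        except KeyError:
            raise ValueError(
                f"annotation id {row.id!r} absent from the sequence set"
            ) from None
        raw.append((sequence, row.localities, row.tissue))
    validate_schema(
        (label for row in annotations for label in row.localities), schema
    )
    single, _ = filter_multilocal(raw)
    unique, _ = deduplicate(single)
    kept, _ = reduce_redundancy(unique, threshold=threshold, schema=schema)
    provenance = {
        "input": len(raw),
        "single_locality": len(single),
        "deduplicated": len(unique),
        "nonredundant": len(kept),
    }
    return PreparedDataset(records=kept, provenance=provenance, schema=tuple(schema))


def build_dataset(
    fasta_path: str | Path,
    annotations_path: str | Path,
    threshold: float = 0.8,
    schema: Sequence[str] = DEFAULT_SCHEMA,
) -> PreparedDataset:
    """File-based entry point: parse FASTA + annotation table, then clean."""
    seqset = read_fasta(fasta_path)
    annotations = read_annotations(annotations_path)
    return prepare_dataset(seqset, annotations, threshold=threshold, schema=schema)
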