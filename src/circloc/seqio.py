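"""Reading, normalizing and validating RNA sequences and annotation tables.

The internal alphabet is RNA: input is uppercased and T is mapped to U
unconditionally, so DNA-style FASTA files are accepted transparently.
Sequence ids are the FASTA header token before the first whitespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"

#: IUPAC nucleotide ambiguity codes (removed under the ``drop-ambiguous`` policy)
IUPAC_AMBIGUITY = set("NRYSWKMBDHV")

POLICIES = ("strict", "drop-ambiguous")


class SequenceError(ValueError):
    """Malformed FASTA input or an invalid residue string."""


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence over the alphabet {A, C, G, U}.

    Residues are expected to be pre-normalized (see :func:`normalize_residues`);
    construction validates the alphabet so every downstream consumer can rely
    on it.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(RNA_ALPHABET)
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-ACGU residues: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of :class:`RnaSequence` with unique ids."""

    sequences: list[RnaSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.id in seen:
                raise SequenceError(f"duplicate sequence id {seq.id!r}")
            seen.add(seq.id)

    def __iter__(self) -> Iterator[RnaSequence]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, key: int | str) -> RnaSequence:
        if isinstance(key, str):
            for seq in self.sequences:
                if seq.id == key:
                    return seq
            raise KeyError(key)
        return self.sequences[key]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


class NormalizedResidues(NamedTuple):
    residues: str
    n_dropped: int


_T_TO_U = str.maketrans("Tt", "Uu")


def normalize_residues(raw: str, policy: str = "drop-ambiguous") -> NormalizedResidues:
    """Uppercase, map T->U and resolve non-ACGU characters.

    Under ``strict`` any remaining non-ACGU character is an error naming its
    position; under ``drop-ambiguous`` IUPAC ambiguity codes are removed and
    the removal count reported. Whitespace is always stripped. The operation
    is idempotent.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown normalization policy {policy!r}")
    if not raw:
        raise SequenceError("cannot normalize an empty residue string")
    upper = "".join(raw.split()).translate(_T_TO_U).upper()
    kept: list[str] = []
    dropped = 0
    for pos, char in enumerate(upper, start=1):
        if char in RNA_ALPHABET:
            kept.append(char)
        elif policy == "strict":
            raise SequenceError(
                f"invalid residue {char!r} at position {pos} under strict policy"
            )
        elif char in IUPAC_AMBIGUITY:
            dropped += 1
        else:
            raise SequenceError(
                f"character {char!r} at position {pos} is not a nucleotide or "
                "IUPAC ambiguity code"
            )
    if not kept:
        raise SequenceError("residue string empty after dropping ambiguous characters")
    return NormalizedResidues("".join(kept), dropped)


def read_fasta(path: str | Path, policy: str = "drop-ambiguous") -> SequenceSet:
    """Parse a FASTA file into a :class:`SequenceSet`, record order preserved.

    Raises :class:`SequenceError` for sequence data before the first header
    (naming the line number) and for duplicate ids.
    """
    path = Path(path)
    with open(path) as handle:
        # SimpleFastaParser silently skips leading junk; surface it as an error.
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SequenceError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            break
        handle.seek(0)
        sequences: list[RnaSequence] = []
        seen: set[str] = set()
        total_dropped = 0
        for title, body in SimpleFastaParser(handle):
            seq_id = title.split()[0] if title.split() else title
            if seq_id in seen:
                raise SequenceError(f"{path}: duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            residues, n_dropped = normalize_residues(body, policy=policy)
            total_dropped += n_dropped
            sequences.append(RnaSequence(id=seq_id, residues=residues))
    if total_dropped:
        logger.info("read_fasta(%s): dropped %d ambiguous residues", path, total_dropped)
    return SequenceSet(sequences)


def write_fasta(seqset: Iterable[RnaSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences in FASTA format with wrapped lines."""
    path = Path(path)
    with open(path, "w") as handle:
        for seq in seqset:
            handle.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), width):
                handle.write(seq.residues[start : start + width] + "\n")


class AnnotationRow(NamedTuple):
    """One (sequence id, tissue) annotation with its locality label set."""

    id: str
    localities: frozenset[str]
    tissue: str


REQUIRED_ANNOTATION_COLUMNS = ("id", "locality", "tissue")
MULTI_LOCALITY_SEPARATOR = ";"


def read_annotations(path: str | Path) -> list[AnnotationRow]:
    """Read a TSV/CSV annotation table with columns id, locality, tissue.

    Multi-locality cells are ';'-separated. The delimiter is sniffed, so both
    tab- and comma-separated tables are accepted.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True, dtype=str)
    table.columns = [str(c).strip() for c in table.columns]
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {missing}")
    unknown = [c for c in table.columns if c not in REQUIRED_ANNOTATION_COLUMNS]
    if unknown:
        raise ValueError(f"{path}: unknown annotation column(s) {unknown}")
    rows: list[AnnotationRow] = []
    for record in table.itertuples(index=False):
        labels = frozenset(
            part.strip()
            for part in str(record.locality).split(MULTI_LOCALITY_SEPARATOR)
            if part.strip()
        )
        if not labels:
            raise ValueError(f"{path}: empty locality set for id {record.id!r}")
        rows.append(AnnotationRow(str(record.id).strip(), labels, str(record.tissue).strip()))
    return rows


def write_annotations(rows: Iterable[AnnotationRow], path: str | Path) -> None:
    """Write annotation rows as a TSV with the canonical header."""
    frame = pd.DataFrame(
        [
            {
                "id": row.id,
                "locality": MULTI_LOCALITY_SEPARATOR.join(sorted(row.localities)),
                "tissue": row.tissue,
            }
            for row in rows
        ],
        columns=list(REQUIRED_ANNOTATION_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)
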