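"""Seven fixed-length statistical descriptors for RNA sequences.

Each encoder maps an :class:`~circloc.seqio.RnaSequence` to a deterministic,
named real vector:

``kmer``
    Normalized stride-1 k-mer composition, dimension 4^k.
``rckmer``
    Reverse-complement canonical k-mer composition: each k-mer is identified
    with its reverse complement (A<->U, C<->G) and represented by the
    lexicographic minimum of the pair.
``pseudoknc``
    Cumulative K-tuple nucleotide composition: the concatenation of the
    normalized i-tuple blocks for i = 1..K (dimension sum of 4^i). This is the
    cumulative form used by common pseudo-KNC implementations, which keeps it
    distinct from the plain k-mer descriptor.
``zcurve``
    The three signed whole-sequence base-balance counts
    x = (A+G)-(C+U), y = (A+C)-(G+U), z = (A+U)-(G+C) (raw counts, not
    length-normalized).
``eiip``
    Trinucleotide electron-ion interaction pseudopotential: for each of the 64
    trinucleotides, the sum of the per-residue EIIP constants times the
    normalized trinucleotide frequency.
``dimonokgap`` / ``trimonokgap``
    Gapped compositions: a di-(tri-)nucleotide at positions i..i+1 (i..i+2)
    followed, after g skipped positions, by a single nucleotide. A config with
    gap = G emits concatenated blocks for g = 1..G (cumulative mode, default)
    or the single g = G block.

Windows never wrap around the circle: circRNA sequences are treated as linear.
All frequency blocks are normalized by the number of valid windows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import RNA_ALPHABET, RnaSequence

DESCRIPTOR_IDS = (
    "kmer",
    "rckmer",
    "pseudoknc",
    "zcurve",
    "eiip",
    "dimonokgap",
    "trimonokgap",
)

_K_DESCRIPTORS = {"kmer", "rckmer", "pseudoknc"}
_GAP_DESCRIPTORS = {"dimonokgap", "trimonokgap"}

#: Electron-ion interaction pseudopotential per residue.
EIIP_TABLE: dict[str, float] = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}


class DescriptorError(ValueError):
    """Invalid descriptor configuration or a sequence violating a precondition."""


@dataclass(frozen=True)
class DescriptorConfig:
    """Configuration of one descriptor.

    ``k`` applies to kmer/rckmer/pseudoknc, ``gap`` to the kgap descriptors;
    parameters irrelevant to the descriptor are normalized to None.
    ``cumulative_gap`` selects concatenated g = 1..gap blocks (default) versus
    the single g = gap block.
    """

    descriptor_id: str
    k: int | None = None
    gap: int | None = None
    cumulative_gap: bool = True

    def __post_init__(self) -> None:
        if self.descriptor_id not in DESCRIPTOR_IDS:
            raise DescriptorError(f"unknown descriptor {self.descriptor_id!r}")
        if self.descriptor_id in _K_DESCRIPTORS:
            if self.k is None:
                raise DescriptorError(f"{self.descriptor_id} requires k")
            if not 1 <= self.k <= 8:
                raise DescriptorError(f"k={self.k} outside the hard cap [1, 8]")
            object.__setattr__(self, "gap", None)
        elif self.descriptor_id in _GAP_DESCRIPTORS:
            if self.gap is None:
                raise DescriptorError(f"{self.descriptor_id} requires gap")
            if not 1 <= self.gap <= 8:
                raise DescriptorError(f"gap={self.gap} outside the hard cap [1, 8]")
            object.__setattr__(self, "k", None)
        else:  # zcurve, eiip: parameter-free
            object.__setattr__(self, "k", None)
            object.__setattr__(self, "gap", None)

    def label(self) -> str:
        """Short human-readable tag, e.g. ``kmer(k=3)``."""
        if self.descriptor_id in _K_DESCRIPTORS:
            return f"{self.descriptor_id}(k={self.k})"
        if self.descriptor_id in _GAP_DESCRIPTORS:
            mode = "" if self.cumulative_gap else ",single"
            return f"{self.descriptor_id}(gap={self.gap}{mode})"
        return self.descriptor_id


@dataclass(frozen=True)
class FeatureVector:
    """An ordered real-valued vector with a parallel feature-name registry."""

    values: np.ndarray
    names: tuple[str, ...]
    config: DescriptorConfig | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.names):
            raise DescriptorError("values and names must be 1-D and equal length")
        if len(set(self.names)) != len(self.names):
            raise DescriptorError("feature names must be unique")
        if not np.all(np.isfinite(values)):
            raise DescriptorError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


# --- integer encoding helpers -------------------------------------------------

_BYTE_TO_IDX = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(RNA_ALPHABET):
    _BYTE_TO_IDX[ord(_c)] = _i


def _as_indices(seq: RnaSequence) -> np.ndarray:
    return _BYTE_TO_IDX[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]


@lru_cache(maxsize=None)
def _powers(k: int) -> np.ndarray:
    return 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)


def _window_codes(idx: np.ndarray, k: int) -> np.ndarray:
    return sliding_window_view(idx, k) @ _powers(k)


@lru_cache(maxsize=None)
def _kmer_names(k: int) -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k))


@lru_cache(maxsize=None)
def _canonical_table(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(code -> canonical code, sorted unique canonical codes) for length k."""
    codes = np.arange(4**k, dtype=np.int64)
    digits = (codes[:, None] // _powers(k)) % 4
    rc_codes = (3 - digits)[:, ::-1] @ _powers(k)
    canonical = np.minimum(codes, rc_codes)
    return canonical, np.unique(canonical)


def canonical_kmer_names(k: int) -> tuple[str, ...]:
    """Sorted canonical (reverse-complement collapsed) k-mer names."""
    _, unique = _canonical_table(k)
    all_names = _kmer_names(k)
    return tuple(all_names[c] for c in unique)


def _require_length(seq: RnaSequence, minimum: int, what: str) -> None:
    if seq.length < minimum:
        raise DescriptorError(
            f"sequence {seq.id!r} (length {seq.length}) too short for {what} "
            f"(needs >= {minimum})"
        )


# --- encoders -----------------------------------------------------------------

def encode_kmer(seq: RnaSequence, k: int) -> FeatureVector:
    """Normalized k-mer composition over stride-1 windows (dimension 4^k)."""
    config = DescriptorConfig("kmer", k=k)
    _require_length(seq, k, f"k-mer with k={k}")
    codes = _window_codes(_as_indices(seq), k)
    counts = np.bincount(codes, minlength=4**k).astype(float)
    return FeatureVector(counts / len(codes), _kmer_names(k), config)


def encode_rckmer(seq: RnaSequence, k: int) -> FeatureVector:
    """Reverse-complement canonical k-mer composition.

    Each window k-mer is replaced by the lexicographic minimum of itself and
    its reverse complement before counting; normalization is by the window
    count, as for plain k-mers.
    """
    config = DescriptorConfig("rckmer", k=k)
    _require_length(seq, k, f"rc-kmer with k={k}")
    canonical_map, unique = _canonical_table(k)
    codes = canonical_map[_window_codes(_as_indices(seq), k)]
    counts = np.bincount(codes, minlength=4**k).astype(float)[unique]
    return FeatureVector(counts / len(codes), canonical_kmer_names(k), config)


def encode_pseudoknc(seq: RnaSequence, K: int) -> FeatureVector:
    """Cumulative K-tuple composition: i-tuple blocks for i = 1..K concatenated."""
    config = DescriptorConfig("pseudoknc", k=K)
    _require_length(seq, K, f"pseudo-KNC with K={K}")
    blocks = [encode_kmer(seq, i) for i in range(1, K + 1)]
    values = np.concatenate([b.values for b in blocks])
    names = tuple(itertools.chain.from_iterable(b.names for b in blocks))
    return FeatureVector(values, names, config)


ZCURVE_NAMES = ("x", "y", "z")


def encode_zcurve(seq: RnaSequence) -> FeatureVector:
    """Signed whole-sequence base-balance counts (purine/pyrimidine,
    amino/keto, weak/strong hydrogen bonding)."""
    config = DescriptorConfig("zcurve")
    counts = np.bincount(_as_indices(seq), minlength=4)
    a, c, g, u = (int(n) for n in counts)
    x = (a + g) - (c + u)
    y = (a + c) - (g + u)
    z = (a + u) - (g + c)
    return FeatureVector(np.array([x, y, z], dtype=float), ZCURVE_NAMES, config)


@lru_cache(maxsize=None)
def _eiip_sums() -> np.ndarray:
    per_residue = np.array([EIIP_TABLE[c] for c in RNA_ALPHABET])
    codes = np.arange(64)
    digits = (codes[:, None] // _powers(3)) % 4
    return per_residue[digits].sum(axis=1)


def encode_eiip(seq: RnaSequence) -> FeatureVector:
    """Trinucleotide EIIP: summed residue pseudopotential x trinucleotide
    frequency for each of the 64 trinucleotides."""
    config = DescriptorConfig("eiip")
    _require_length(seq, 3, "trinucleotide EIIP")
    freq = encode_kmer(seq, 3).values
    return FeatureVector(_eiip_sums() * freq, _kmer_names(3), config)


def _kgap_block(idx: np.ndarray, head: int, g: int) -> np.ndarray:
    """Normalized counts of (head-mer, gap g, mononucleotide) patterns.

    The window spans ``head + g + 1`` positions; a g with no valid window
    yields an all-zero block.
    """
    dim = 4**head * 4
    span = head + g + 1
    n_windows = len(idx) - span + 1
    if n_windows <= 0:
        return np.zeros(dim)
    heads = sliding_window_view(idx[: n_windows + head - 1], head) @ _powers(head)
    tails = idx[head + g : head + g + n_windows]
    counts = np.bincount(heads * 4 + tails, minlength=dim).astype(float)
    return counts / n_windows


def _kgap_names(head: int, gaps: Iterable[int]) -> tuple[str, ...]:
    head_names = _kmer_names(head)
    return tuple(
        f"{h}_g{g}_{t}"
        for g in gaps
        for h in head_names
        for t in RNA_ALPHABET
    )


def _gap_values(gap: int, cumulative: bool) -> range:
    return range(1, gap + 1) if cumulative else range(gap, gap + 1)


def encode_dimonokgap(seq: RnaSequence, gap: int, cumulative: bool = True) -> FeatureVector:
    """Gapped dinucleotide-mononucleotide composition (64 features per gap value)."""
    config = DescriptorConfig("dimonokgap", gap=gap, cumulative_gap=cumulative)
    _require_length(seq, 4, "di-mono-kgap (g=1 window)")
    idx = _as_indices(seq)
    gaps = _gap_values(gap, cumulative)
    values = np.concatenate([_kgap_block(idx, 2, g) for g in gaps])
    return FeatureVector(values, _kgap_names(2, gaps), config)


def encode_trimonokgap(seq: RnaSequence, gap: int, cumulative: bool = True) -> FeatureVector:
    """Gapped trinucleotide-mononucleotide composition (256 features per gap value)."""
    config = DescriptorConfig("trimonokgap", gap=gap, cumulative_gap=cumulative)
    _require_length(seq, 5, "tri-mono-kgap (g=1 window)")
    idx = _as_indices(seq)
    gaps = _gap_values(gap, cumulative)
    values = np.concatenate([_kgap_block(idx, 3, g) for g in gaps])
    return FeatureVector(values, _kgap_names(3, gaps), config)


def encode(seq: RnaSequence, config: DescriptorConfig) -> FeatureVector:
    """Encode ``seq`` with the descriptor selected by ``config``."""
    did = config.descriptor_id
    if did == "kmer":
        return encode_kmer(seq, config.k)
    if did == "rckmer":
        return encode_rckmer(seq, config.k)
    if did == "pseudoknc":
        return encode_pseudoknc(seq, config.k)
    if did == "zcurve":
        return encode_zcurve(seq)
    if did == "eiip":
        return encode_eiip(seq)
    if did == "dimonokgap":
        return encode_dimonokgap(seq, config.gap, config.cumulative_gap)
    if did == "trimonokgap":
        return encode_trimonokgap(seq, config.gap, config.cumulative_gap)
    raise DescriptorError(f"unknown descriptor {did!r}")  # pragma: no cover


def feature_names(config: DescriptorConfig) -> tuple[str, ...]:
    """The deterministic feature-name list of a descriptor, without a sequence."""
    did = config.descriptor_id
    if did == "kmer":
        return _kmer_names(config.k)
    if did == "rckmer":
        return canonical_kmer_names(config.k)
    if did == "pseudoknc":
        return tuple(
            itertools.chain.from_iterable(_kmer_names(i) for i in range(1, config.k + 1))
        )
    if did == "zcurve":
        return ZCURVE_NAMES
    if did == "eiip":
        return _kmer_names(3)
    if did == "dimonokgap":
        return _kgap_names(2, _gap_values(config.gap, config.cumulative_gap))
    if did == "trimonokgap":
        return _kgap_names(3, _gap_values(config.gap, config.cumulative_gap))
    raise DescriptorError(f"unknown descriptor {did!r}")  # pragma: no cover


def encode_many(
    seqs: Sequence[RnaSequence], config: "DescriptorConfig | object"
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode a batch of sequences into a (n_sequences, n_features) matrix.

    Accepts a :class:`DescriptorConfig` or anything exposing
    ``encode(seq) -> FeatureVector`` plus ``feature_names()`` (a FusionSpec).
    """
    if isinstance(config, DescriptorConfig):
        names = feature_names(config)
        rows = [encode(s, config).values for s in seqs]
    else:
        names = config.feature_names()
        rows = [config.encode(s).values for s in seqs]
    matrix = np.vstack(rows) if rows else np.empty((0, len(names)))
    return matrix, names
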