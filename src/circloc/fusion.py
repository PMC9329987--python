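"""K-order descriptor fusion: concatenating distinct descriptors' vectors.

A fusion of order K concatenates the feature vectors of K distinct
descriptors; component order is canonical (sorted by descriptor id) so that
the same set of components always yields the same vector, and feature names
are prefixed with the descriptor id to stay globally unique. Fusion is plain
concatenation — no rescaling — with an optional per-block standardization
hook left to the caller (tree models are scale-invariant; SVM users may
standardize the resulting matrix).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .descriptors import (
    DESCRIPTOR_IDS,
    DescriptorConfig,
    DescriptorError,
    FeatureVector,
    encode,
    feature_names,
)
from .seqio import RnaSequence

#: Per-descriptor configurations used by default when fusing: each component
#: carries its best standalone hyperparameters (k=5 for the k-mer family,
#: gap=5 for tri-mono-kgap, gap=2 for di-mono-kgap).
DEFAULT_CONFIGS: dict[str, DescriptorConfig] = {
    "kmer": DescriptorConfig("kmer", k=5),
    "rckmer": DescriptorConfig("rckmer", k=5),
    "pseudoknc": DescriptorConfig("pseudoknc", k=5),
    "zcurve": DescriptorConfig("zcurve"),
    "eiip": DescriptorConfig("eiip"),
    "dimonokgap": DescriptorConfig("dimonokgap", gap=2),
    "trimonokgap": DescriptorConfig("trimonokgap", gap=5),
}


@dataclass(frozen=True)
class FusionSpec:
    """An ordered set of descriptor configurations with pairwise-distinct ids."""

    components: tuple[DescriptorConfig, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= len(DESCRIPTOR_IDS):
            raise DescriptorError(
                f"fusion order must be in [1, {len(DESCRIPTOR_IDS)}]"
            )
        ids = [c.descriptor_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise DescriptorError(f"duplicate descriptor ids in fusion: {ids}")
        # canonical component order for reproducibility
        ordered = tuple(sorted(self.components, key=lambda c: c.descriptor_id))
        object.__setattr__(self, "components", ordered)

    @property
    def order(self) -> int:
        return len(self.components)

    def label(self) -> str:
        return "+".join(c.label() for c in self.components)

    def feature_names(self) -> tuple[str, ...]:
        return tuple(
            f"{c.descriptor_id}:{name}"
            for c in self.components
            for name in feature_names(c)
        )

    def encode(self, seq: RnaSequence) -> FeatureVector:
        return fuse(seq, self)


def fuse(seq: RnaSequence, spec: FusionSpec) -> FeatureVector:
    """Concatenate the component descriptors' vectors in canonical order."""
    parts = []
    for component in spec.components:
        try:
            parts.append(encode(seq, component))
        except DescriptorError as exc:
            raise DescriptorError(
                f"fusion component {component.label()}: {exc}"
            ) from exc
    values = np.concatenate([p.values for p in parts]) if parts else np.empty(0)
    return FeatureVector(values, spec.feature_names())


def enumerate_fusions(
    order: int, configs: Mapping[str, DescriptorConfig] | None = None
) -> list[FusionSpec]:
    """All size-``order`` subsets of the seven descriptors as canonical specs.

    The list is sorted lexicographically by descriptor-id tuple; its length is
    C(7, order).
    """
    configs = dict(DEFAULT_CONFIGS) if configs is None else dict(configs)
    available = sorted(configs)
    if not 2 <= order <= len(available):
        raise DescriptorError(
            f"fusion order {order} outside [2, {len(available)}]"
        )
    return [
        FusionSpec(tuple(configs[i] for i in combo))
        for combo in itertools.combinations(available, order)
    ]


def enumerate_all_fusions(
    orders: Sequence[int] = range(2, 8),
    configs: Mapping[str, DescriptorConfig] | None = None,
) -> list[FusionSpec]:
    """Fusions for every requested order, concatenated in ascending order."""
    specs: list[FusionSpec] = []
    for order in orders:
        specs.extend(enumerate_fusions(order, configs))
    return specs
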