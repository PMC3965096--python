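"""Inter-chain contact classification under the strict 8 Å rule.

Two chains of a biological unit are called non-interacting when the
minimum distance between their representative atoms (Cβ, Cα for glycine)
exceeds the threshold *strictly*: a pair at exactly 8.0 Å counts as
interacting, the conservative reading for a negative reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import BioUnit, ChainModel

__all__ = [
    "ContactConfig",
    "ChainPairResult",
    "min_interchain_distance",
    "classify_chain_pair",
    "enumerate_chain_pairs",
]

DEFAULT_THRESHOLD = 8.0  # Å


@dataclass(frozen=True)
class ContactConfig:
    """Distance threshold (Å) for the strict-greater non-interaction rule."""

    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class ChainPairResult:
    """Minimum representative-atom distance between two chain copies."""

    chain_a: tuple[str, int]
    chain_b: tuple[str, int]
    min_distance: float
    non_interacting: bool


def min_interchain_distance(a: ChainModel, b: ChainModel) -> float:
    """Minimum Euclidean distance between representative atoms of two chains.

    Implemented with a k-d tree over the larger chain; contractually equal
    to the exhaustive pairwise minimum.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"chain without representative points: "
            f"{a.key if len(a) == 0 else b.key}"
        )
    pa, pb = a.coords(), b.coords()
    if len(pa) > len(pb):
        pa, pb = pb, pa
    tree = cKDTree(pb)
    dists, _ = tree.query(pa, k=1)
    return float(np.min(dists))


def classify_chain_pair(
    a: ChainModel, b: ChainModel, cfg: ContactConfig = ContactConfig()
) -> ChainPairResult:
    """Classify one chain-copy pair; non-interacting iff strictly > threshold."""
    d = min_interchain_distance(a, b)
    return ChainPairResult(
        chain_a=a.key,
        chain_b=b.key,
        min_distance=d,
        non_interacting=d > cfg.threshold,
    )


def enumerate_chain_pairs(
    unit: BioUnit, cfg: ContactConfig = ContactConfig()
) -> list[ChainPairResult]:
    """Classify every unordered chain-copy pair of a biological unit.

    A unit with fewer than two chains yields an empty list.  Chain order
    follows the file; each pair appears exactly once.
    """
    return [
        classify_chain_pair(a, b, cfg) for a, b in combinations(unit.chains, 2)
    ]
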