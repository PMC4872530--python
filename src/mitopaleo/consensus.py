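"""Per-site pileup construction and consensus calling.

The consensus is a plurality call per site, subject to a minimum depth and a
minimum support fraction; sites failing either threshold are emitted as N.
Ties are broken toward the reference allele first (making reference bias
explicit rather than accidental), then alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reference import BASES, MT_LENGTH, decode, encode, load_reference
from .simulate import SimulatedRead


@dataclass
class Pileup:
    """Per-site base counts over the circular reference frame.

    ``counts`` has shape (reference_length, 5) with columns A, C, G, T, N.
    """

    counts: np.ndarray
    reference_length: int = MT_LENGTH

    @property
    def depth(self) -> np.ndarray:
        """Reads overlapping each site (N bases included)."""
        return self.counts.sum(axis=1)

    def site_counts(self, position: int) -> dict[str, int]:
        """Base counts at a 1-based position."""
        row = self.counts[position - 1]
        return {b: int(row[i]) for i, b in enumerate(BASES)}


@dataclass
class ConsensusSequence:
    """A called consensus with per-site support fractions.

    ``support[i]`` is the fraction of non-N bases at site ``i`` agreeing
    with the call (0 where the call is N for lack of data).
    """

    sequence: str
    support: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.support):
            raise ValueError("sequence/support length mismatch")


def build_pileup(
    reads: Sequence[SimulatedRead], reference_length: int = MT_LENGTH
) -> Pileup:
    """Tally bases per site from aligned reads (circular coordinates)."""
    counts = np.zeros((reference_length, 5), dtype=np.int64)
    for read in reads:
        idx = (read.start + np.arange(read.length)) % reference_length
        np.add.at(counts, (idx, encode(read.bases)), 1)
    return Pileup(counts=counts, reference_length=reference_length)


def mean_coverage(pileup: Pileup) -> float:
    """Average read depth over the molecule (sum of depths / length)."""
    return float(pileup.depth.sum() / pileup.reference_length)


def call_consensus(
    pileup: Pileup,
    min_depth: int = 3,
    min_support: float = 0.6,
    reference: str | None = None,
) -> ConsensusSequence:
    """Plurality consensus with depth/support thresholds.

    A site is called only when at least ``min_depth`` non-N bases cover it
    and the plurality base reaches ``min_support`` of them; otherwise N.
    Equal counts are resolved toward the reference allele, then by
    alphabetical base order, so the call is fully deterministic.
    """
    if min_depth < 0 or not 0.0 <= min_support <= 1.0:
        raise ValueError("min_depth >= 0 and min_support in [0, 1] required")
    ref = encode(reference if reference is not None else load_reference())
    acgt = pileup.counts[:, :4].astype(float)
    depth = acgt.sum(axis=1)

    # Tie-break: add a small reference bonus and a decreasing alphabetical
    # epsilon, both far below one count, then take argmax.
    eps = 1e-6 * np.arange(4, 0, -1)  # A > C > G > T preference on exact ties
    keyed = acgt + eps
    if len(ref) == pileup.reference_length:
        keyed[np.arange(pileup.reference_length), ref] += 1e-3
    call = keyed.argmax(axis=1).astype(np.uint8)

    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(
            depth > 0, acgt[np.arange(len(acgt)), call] / np.maximum(depth, 1), 0.0
        )
    ok = (depth >= max(min_depth, 1)) & (support >= min_support)
    call = np.where(ok, call, 4).astype(np.uint8)  # 4 == N
    support = np.where(ok, support, 0.0)
    return ConsensusSequence(sequence=decode(call), support=support)
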