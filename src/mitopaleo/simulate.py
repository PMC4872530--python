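"""Simulation of ancient-style mitochondrial sequencing reads.

Emulates the read data underlying an ancient mitogenome experiment: short
fragments sampled uniformly from a circular source haplotype, post-mortem
cytosine-deamination damage concentrated at fragment ends, a constant
per-base sequencing error, and an optional admixture of reads from a modern
contaminant haplotype at fraction ``c``.  Every downstream stage of the
package (consensus, damage authentication, contamination estimation,
haplotyping) is testable against the known simulation truth.

Damage model
------------
A C->T misincorporation occurs at molecule 5'-relative position ``i`` with
probability ``delta0 * lam**i`` (geometric positional decay), and
symmetrically G->A at the 3' end.  This is the standard two-parameter
description of terminal deamination in double-stranded ancient DNA
libraries.  Reads are stored in reference orientation; for a minus-strand
read the molecule's 5' end is the right-hand end of the stored bases, which
the damage routine accounts for.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .reference import MT_LENGTH, decode, encode, load_reference
from .variants import MtVariant, apply_variants, diff_vs_reference

_A, _C, _G, _T = 0, 1, 2, 3

#: complement lookup for encoded bases (N -> N)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

ENDOGENOUS = "endogenous"
CONTAMINANT = "contaminant"


@dataclass(frozen=True)
class SourceHaplotype:
    """A complete mitogenome haplotype: sequence, label and its variant list.

    The invariant ``apply_variants(reference, variants) == sequence`` is
    checked at construction when built through :meth:`from_variants`.
    """

    sequence: str
    label: str
    variants: tuple[MtVariant, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_LENGTH:
            raise ValueError(
                f"haplotype length {len(self.sequence)} != {MT_LENGTH}"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("haplotype alphabet must be within ACGTN")

    @classmethod
    def from_variants(
        cls,
        variants: Sequence[MtVariant],
        label: str,
        reference: str | None = None,
    ) -> "SourceHaplotype":
        ref_seq = reference if reference is not None else load_reference()
        seq = apply_variants(ref_seq, list(variants))
        return cls(sequence=seq, label=label, variants=tuple(sorted(variants)))

    @classmethod
    def from_sequence(
        cls, sequence: str, label: str, reference: str | None = None
    ) -> "SourceHaplotype":
        variants, _ = diff_vs_reference(sequence, reference)
        return cls(sequence=sequence, label=label, variants=tuple(variants))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated sequencing experiment.

    Defaults describe a deeply sequenced Paleolithic mitogenome from a
    non-UDG-treated double-stranded library: 33x mean depth, ~60-bp
    fragments, 30% terminal C->T deamination decaying geometrically into
    the read, and an Illumina-like 0.2% per-base error rate.
    """

    target_mean_depth: float = 33.0
    fragment_length_mean: float = 60.0
    fragment_length_sd: float = 15.0
    fragment_length_min: int = 20
    deamination_rate: float = 0.30  # delta0: terminal C->T probability
    deamination_decay: float = 0.60  # lam: per-position geometric factor
    seq_error: float = 0.002
    contamination_fraction: float = 0.0
    contaminant: SourceHaplotype | None = None
    damage_contaminant: bool = False  # modern contaminant: undamaged
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deamination_rate", "seq_error", "contamination_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.deamination_decay <= 1.0:
            raise ValueError("deamination_decay must be in (0, 1]")
        if self.target_mean_depth <= 0:
            raise ValueError("target_mean_depth must be positive")
        if self.fragment_length_mean < 1 or self.fragment_length_min < 1:
            raise ValueError("fragment lengths must be >= 1")
        if self.contamination_fraction > 0 and self.contaminant is None:
            raise ValueError(
                "contamination_fraction > 0 requires a contaminant haplotype"
            )


@dataclass
class SimulatedRead:
    """One aligned read: bases stored in reference orientation.

    ``source`` is a truth label retained for validation only; estimators
    must never consume it.
    """

    start: int  # 0-based offset on the circular reference
    length: int
    strand: str  # '+' or '-'
    bases: str
    source: str = ENDOGENOUS

    def __post_init__(self) -> None:
        if not 1 <= self.length <= MT_LENGTH:
            raise ValueError(f"read length {self.length} outside 1..{MT_LENGTH}")
        if len(self.bases) != self.length:
            raise ValueError("bases length != read length")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def positions(self) -> np.ndarray:
        """0-based reference positions covered, in reference orientation."""
        return (self.start + np.arange(self.length)) % MT_LENGTH


def _damage_codes(
    codes: np.ndarray, delta0: float, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Deaminate an encoded molecule given 5'->3' in index order."""
    n = codes.size
    out = codes.copy()
    idx5 = np.arange(n)
    idx3 = idx5[::-1]
    p5 = delta0 * lam**idx5
    p3 = delta0 * lam**idx3
    hit5 = (out == _C) & (rng.random(n) < p5)
    hit3 = (out == _G) & (rng.random(n) < p3)
    out[hit5] = _T
    out[hit3] = _A
    return out


def apply_damage(
    read: SimulatedRead,
    delta0: float,
    lam: float,
    rng: np.random.Generator | int | None = None,
) -> SimulatedRead:
    """Apply terminal deamination to a read; other bases are untouched.

    C->T at molecule 5'-relative position ``i`` with probability
    ``delta0 * lam**i``, symmetric G->A at the 3' end.  For minus-strand
    reads the stored (reference-orientation) bases are reverse-complemented
    into molecule orientation, damaged, and flipped back.
    """
    if not 0.0 <= delta0 <= 1.0 or not 0.0 < lam <= 1.0:
        raise ValueError("delta0 in [0,1] and lam in (0,1] required")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    codes = encode(read.bases)
    if read.strand == "-":
        codes = _COMPLEMENT[codes[::-1]]
    codes = _damage_codes(codes, delta0, lam, rng)
    if read.strand == "-":
        codes = _COMPLEMENT[codes[::-1]]
    return replace(read, bases=decode(codes))


def _sequencing_error(
    codes: np.ndarray, error: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each base with probability ``error`` to a uniform other base."""
    if error <= 0:
        return codes
    out = codes.copy()
    hit = rng.random(codes.size) < error
    if hit.any():
        # shift by 1..3 within ACGT: uniform over the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_reads(
    source: SourceHaplotype, config: SimConfig
) -> list[SimulatedRead]:
    """Simulate an aligned ancient read set from a source haplotype.

    The number of reads is ``round(depth * L / fragment_length_mean)`` so the
    realized mean depth matches the target in expectation.  Each read is
    drawn from the contaminant with probability ``c`` (independent Bernoulli
    per read); endogenous reads are deaminated before sequencing error is
    applied, contaminant reads only if ``damage_contaminant`` is set.
    Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n_reads = int(round(config.target_mean_depth * MT_LENGTH / config.fragment_length_mean))

    a = (config.fragment_length_min - config.fragment_length_mean) / config.fragment_length_sd
    lengths = stats.truncnorm.rvs(
        a,
        np.inf,
        loc=config.fragment_length_mean,
        scale=config.fragment_length_sd,
        size=n_reads,
        random_state=rng,
    )
    lengths = np.minimum(np.round(lengths).astype(int), MT_LENGTH)
    starts = rng.integers(0, MT_LENGTH, size=n_reads)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    is_contam = rng.random(n_reads) < config.contamination_fraction

    src = encode(source.sequence)
    contam = (
        encode(config.contaminant.sequence)
        if config.contaminant is not None
        else None
    )

    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        start, length, strand = int(starts[i]), int(lengths[i]), str(strands[i])
        idx = (start + np.arange(length)) % MT_LENGTH
        template = contam if is_contam[i] else src
        codes = template[idx]
        damage_this = (not is_contam[i]) or config.damage_contaminant
        if damage_this and config.deamination_rate > 0:
            if strand == "-":
                codes = _COMPLEMENT[codes[::-1]]
            codes = _damage_codes(
                codes, config.deamination_rate, config.deamination_decay, rng
            )
            if strand == "-":
                codes = _COMPLEMENT[codes[::-1]]
        codes = _sequencing_error(codes, config.seq_error, rng)
        reads.append(
            SimulatedRead(
                start=start,
                length=length,
                strand=strand,
                bases=decode(codes),
                source=CONTAMINANT if is_contam[i] else ENDOGENOUS,
            )
        )
    return reads


def strip_truth_labels(reads: Sequence[SimulatedRead]) -> list[SimulatedRead]:
    """Copies of the reads with the truth label reset (blindness checks)."""
    return [replace(r, source=ENDOGENOUS) for r in reads]


def write_reads(reads: Sequence[SimulatedRead], path, format: str = "sam") -> None:
    """Write reads as SAM or FASTQ; round-trips through the matching reader."""
    from . import io  # deferred: io imports this module's types

    if format.lower() == "sam":
        io.write_sam(reads, path)
    elif format.lower() == "fastq":
        io.write_fastq(reads, path)
    else:
        raise ValueError(f"unsupported read format {format!r}")
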