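"""Mitochondrial substitution variants relative to the reference.

Variants are single-base substitutions named with the conventional
``<ref><position><alt>`` grammar (e.g. ``T10517A``): the reference allele,
the 1-based position on the mitochondrial reference frame, and the observed
allele.  Indels and length polymorphisms are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .reference import MT_LENGTH, load_reference

_LABEL_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


@dataclass(frozen=True, order=True)
class MtVariant:
    """A single substitution against the mitochondrial reference.

    Attributes
    ----------
    position : int
        1-based position on the reference frame.
    ref : str
        Reference allele; must equal the reference base at ``position``.
    alt : str
        Observed allele, different from ``ref``.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise ValueError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"alleles must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.position}")

    @property
    def label(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"

    @property
    def is_transition(self) -> bool:
        return {self.ref, self.alt} in ({"A", "G"}, {"C", "T"})

    @classmethod
    def from_label(cls, label: str) -> "MtVariant":
        m = _LABEL_RE.match(label.strip().upper())
        if m is None:
            raise ValueError(f"cannot parse variant label {label!r}")
        return cls(position=int(m.group(2)), ref=m.group(1), alt=m.group(3))


def validate_against_reference(
    variants: Iterable[MtVariant], reference: str | None = None
) -> None:
    """Raise if any variant's ref allele disagrees with the reference base."""
    ref_seq = reference if reference is not None else load_reference()
    for v in variants:
        base = ref_seq[v.position - 1]
        if v.ref != base:
            raise ValueError(
                f"variant {v.label}: reference carries {base} at {v.position}"
            )


def apply_variants(
    reference: str, variants: Sequence[MtVariant], validate: bool = True
) -> str:
    """Apply substitutions to a reference sequence, returning the haplotype."""
    if validate:
        validate_against_reference(variants, reference)
    positions = [v.position for v in variants]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate positions in variant list")
    seq = list(reference)
    for v in variants:
        seq[v.position - 1] = v.alt
    return "".join(seq)


def diff_vs_reference(
    sequence: str, reference: str | None = None
) -> tuple[list[MtVariant], list[int]]:
    """All substitutions of ``sequence`` relative to the reference.

    Returns the variant list (sorted by position) and the 1-based positions
    where ``sequence`` is N (excluded from the variant list and reported
    separately so callers can distinguish "no call" from "reference allele").
    """
    ref_seq = reference if reference is not None else load_reference()
    if len(sequence) != len(ref_seq):
        raise ValueError(
            f"sequence length {len(sequence)} != reference length {len(ref_seq)}"
        )
    variants: list[MtVariant] = []
    n_sites: list[int] = []
    for i, (s, r) in enumerate(zip(sequence, ref_seq)):
        if s == r:
            continue
        if s == "N":
            n_sites.append(i + 1)
        else:
            variants.append(MtVariant(position=i + 1, ref=r, alt=s))
    return variants, n_sites


def format_variants(variants: Iterable[MtVariant]) -> list[str]:
    return [v.label for v in sorted(variants)]


def parse_variants(labels: Iterable[str]) -> list[MtVariant]:
    return sorted(MtVariant.from_label(s) for s in labels)
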