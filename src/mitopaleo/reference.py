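"""Mitochondrial reference coordinate frame and a synthetic reference sequence.

All coordinates in this package are 1-based positions on the 16,569-bp
circular human mitochondrial reference frame (rCRS numbering) in user-facing
interfaces, and 0-based internally.

The packaged reference *sequence* is synthetic: a deterministic pseudo-random
sequence with human-mtDNA-like base composition, generated from a fixed seed
and verified against a frozen checksum at load time.  It stands in for the
actual reference sequence, which is not redistributed here; every analysis in
the package is defined relative to whatever reference sequence it is given,
so swapping in the real sequence is a one-argument change.  A handful of
bases are pinned so that the packaged haplotype fixtures carry their
canonical variant labels.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache

import numpy as np

MT_LENGTH = 16569

#: Base alphabet used throughout; integer codes index into this string.
BASES = "ACGTN"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

# Approximate base composition of the human mitochondrial L-strand.
_COMPOSITION = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}

_SEED = 104729  # fixed generation seed; changing it invalidates the checksum

# Bases pinned at specific 1-based positions (fixture variant labels depend
# on the reference allele at these sites).
_PINNED = {10517: "T"}

_REFERENCE_MD5 = "a715cb62ac530ff2488f5ee3b51085a0"


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = chr(arr[out == 255][0])
        raise ValueError(f"invalid nucleotide {bad!r}; alphabet is {BASES}")
    return out


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


@lru_cache(maxsize=1)
def load_reference() -> str:
    """Return the synthetic 16,569-bp reference sequence (checksum-verified).

    The sequence is regenerated deterministically on first use and compared
    against a frozen MD5 digest, so any drift in the generator or the random
    number stream is caught immediately rather than silently shifting every
    downstream fixture.
    """
    rng = np.random.default_rng(_SEED)
    bases = np.array(list("ACGT"))
    probs = np.array([_COMPOSITION[b] for b in "ACGT"])
    probs = probs / probs.sum()
    seq = rng.choice(bases, size=MT_LENGTH, p=probs)
    for pos, base in _PINNED.items():
        seq[pos - 1] = base
    text = "".join(seq)
    digest = hashlib.md5(text.encode("ascii")).hexdigest()
    if digest != _REFERENCE_MD5:
        raise RuntimeError(
            "synthetic reference checksum mismatch: "
            f"expected {_REFERENCE_MD5}, got {digest}"
        )
    return text


@lru_cache(maxsize=1)
def load_reference_array() -> np.ndarray:
    """Encoded (uint8) form of :func:`load_reference`; treat as read-only."""
    arr = encode(load_reference())
    arr.setflags(write=False)
    return arr


def reference_base(position: int) -> str:
    """Reference base at a 1-based position."""
    if not 1 <= position <= MT_LENGTH:
        raise ValueError(f"position {position} outside 1..{MT_LENGTH}")
    return load_reference()[position - 1]


TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def transition_of(base: str) -> str:
    """The transition partner of a base (A<->G, C<->T)."""
    return TRANSITIONS[base]
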