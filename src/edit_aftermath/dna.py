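"""Small DNA helpers shared across modules.

All sequences are plain upper-case strings over A/C/G/T (genomes may in
principle contain other letters; comparison helpers treat any non-ACGT
base conservatively, i.e. it never matches a guide base).
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

#: IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware via Biopython)."""
    return str(Seq(seq).reverse_complement())


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return arr.tobytes().decode("ascii")


def iupac_matches(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` position by position.

    Lengths must be equal.  A non-ACGT base in ``seq`` only matches a
    pattern position that explicitly lists it (so it never matches, for
    the standard codes, except trivially identical letters).
    """
    if len(pattern) != len(seq):
        raise ValueError("pattern and sequence lengths differ")
    return all(s in IUPAC.get(p, p) for p, s in zip(pattern, seq))


def iupac_mask(pattern: str, length: int | None = None) -> np.ndarray:
    """Boolean lookup table of shape (len(pattern), 256).

    ``mask[i, code]`` is True when ASCII ``code`` satisfies pattern
    position ``i``.  Used to vectorise PAM matching.
    """
    mask = np.zeros((len(pattern), 256), dtype=bool)
    for i, p in enumerate(pattern):
        for b in IUPAC.get(p, p):
            mask[i, ord(b)] = True
    return mask


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return decode(rng.choice(_BASES, size=n))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))
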