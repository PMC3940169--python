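"""Low-level sequence helpers: alphabets, IUPAC matching, Hamming distances.

All matching in this package is substitution-only (Hamming); indel-tolerant
alignment is deliberately not offered because every in-line element (index,
spacer, primer) sits at a fixed, sample-determined offset.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

#: IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_acgt(seq: str) -> bool:
    return not set(seq.upper()) - set(BASES) if seq else True


def hamming(a: str, b: str) -> int:
    """Plain Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def iupac_mismatches(primer: str, observed: str) -> int:
    """Mismatches between a degenerate primer and an observed sequence.

    A primer position matches when the observed base is in the IUPAC
    expansion of the primer code; an N in the read matches nothing except
    a primer N.
    """
    if len(primer) != len(observed):
        raise ValueError("iupac_mismatches: unequal lengths")
    mm = 0
    for p, o in zip(primer.upper(), observed.upper()):
        if o not in IUPAC.get(p, p):
            mm += 1
    return mm


def expand_iupac(seq: str, rng: np.random.Generator) -> str:
    """Replace each degenerate code with one concrete base, drawn uniformly."""
    out = []
    for c in seq.upper():
        choices = IUPAC.get(c)
        if choices is None:
            raise ValueError(f"not an IUPAC nucleotide code: {c!r}")
        out.append(choices if len(choices) == 1 else choices[rng.integers(len(choices))])
    return "".join(out)


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
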