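"""Small DNA-string helpers shared across the pipeline.

Sequences are plain upper-case Python strings over {A,C,G,T}; IUPAC
ambiguity codes are permitted in primers only (degenerate matching is
one-directional: a primer code matches a set of concrete template bases).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

# IUPAC code -> set of concrete bases it matches
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement; preserves case, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return all(c in IUPAC for c in seq.upper())


def is_concrete(seq: str) -> bool:
    return all(c in "ACGT" for c in seq.upper())


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` to a different base."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        code = {65: 0, 67: 1, 71: 2, 84: 3}
        lut = np.zeros(256, dtype=np.uint8)
        for byte, idx in code.items():
            lut[byte] = idx
        ascii_of = np.frombuffer(b"ACGT", dtype=np.uint8)
        cur = lut[arr[hit]]
        new = (cur + rng.integers(1, 4, size=cur.size)) % 4
        arr[hit] = ascii_of[new]
    return arr.tobytes().decode()


def mismatches(primer: str, window: str) -> int:
    """Number of primer positions whose IUPAC set excludes the template base.

    ``primer`` may contain ambiguity codes; ``window`` is compared
    case-insensitively and any non-ACGT template base counts as a mismatch
    (degenerate codes are resolved on the primer side only).
    """
    n = 0
    for p, t in zip(primer.upper(), window.upper()):
        if t not in IUPAC[p]:
            n += 1
    return n
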