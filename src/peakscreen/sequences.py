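"""DNA string utilities: reverse complement, IUPAC degeneracy, encoding."""
from __future__ import annotations

import numpy as np

from .errors import SequenceError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")

#: IUPAC nucleotide codes -> set of concrete bases
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    An involution: ``revcomp(revcomp(s)) == s``.
    """
    s = seq.upper()
    if not VALID_BASES.issuperset(s):
        bad = sorted(set(s) - VALID_BASES)
        raise SequenceError(f"invalid DNA characters: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC consensus pattern."""
    p = pattern.upper()
    if not set(IUPAC_CODES).issuperset(p):
        bad = sorted(set(p) - set(IUPAC_CODES))
        raise SequenceError(f"invalid IUPAC codes: {bad}")
    return p.translate(_IUPAC_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 indices (A=0, C=1, G=2, T=3)."""
    s = seq.upper()
    try:
        return np.array([_BASE_INDEX[b] for b in s], dtype=np.int8)
    except KeyError as exc:
        raise SequenceError(f"invalid base {exc.args[0]!r}") from exc


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[int(c)] for c in codes)
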