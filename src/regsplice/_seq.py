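"""Shared nucleotide alphabet helpers: IUPAC classes, encoding, reverse complement."""

from __future__ import annotations

import numpy as np

# IUPAC nucleotide codes -> the set of unambiguous bases each stands for.
IUPAC_CLASSES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

# byte-level lookup: A/C/G/T -> 0..3, anything else -> 4 (never matches a class)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("U")] = BASE_INDEX["T"]
_ENCODE[ord("u")] = BASE_INDEX["T"]


def normalize(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4).

    Ambiguity codes in the *subject* sequence deliberately encode to 4 so they
    never satisfy a pattern position.
    """
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def class_indices(symbol: str) -> tuple[int, ...]:
    """Base indices allowed at one IUPAC pattern position."""
    try:
        return tuple(BASE_INDEX[b] for b in IUPAC_CLASSES[symbol])
    except KeyError:
        raise ValueError(f"invalid IUPAC symbol: {symbol!r}") from None
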