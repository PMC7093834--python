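"""Small shared nucleotide/protein helpers used across the package."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# integer encoding used by the numba alignment kernels and the mutator:
# A=0 C=1 G=2 T=3; anything else (N, IUPAC ambiguity) -> 4, never matches.
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(DNA_ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# IUPAC codes for consensus ambiguity at ties (sorted base tuple -> code)
IUPAC = {
    ("A",): "A", ("C",): "C", ("G",): "G", ("T",): "T",
    ("A", "C"): "M", ("A", "G"): "R", ("A", "T"): "W",
    ("C", "G"): "S", ("C", "T"): "Y", ("G", "T"): "K",
    ("A", "C", "G"): "V", ("A", "C", "T"): "H",
    ("A", "G", "T"): "D", ("C", "G", "T"): "B",
    ("A", "C", "G", "T"): "N",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A0 C1 G2 T3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 ordinals (exact-match scoring)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).astype(np.int8)
    return arr


def translate(seq: str) -> str:
    """Translate a nucleotide string (standard code, '*' for stops)."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def random_dna(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.int8))


def gc_check(seq: str) -> bool:
    """True iff seq is strictly A/C/G/T."""
    return bool(np.all(encode(seq) < 4)) and len(seq) > 0
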