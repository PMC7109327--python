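"""Low-level DNA helpers shared across modules.

Sequences are uppercase strings over {A, C, G, T, N}. The numeric
encoding (A=0, C=1, G=2, T=3, N=4) is used by the aligner and the
simulator's vectorised error model.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGTN"

_COMP = str.maketrans("ACGTN", "TGCAN")

# byte -> code lookup; everything unknown maps to 4 (N)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0,C=1,G=2,T=3,N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def is_valid_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= set(DNA_ALPHABET)


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random sequence over {A,C,G,T}."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8).astype(np.uint8))


def phred_to_error(q) -> np.ndarray:
    """Phred score(s) -> base-call error probability."""
    return np.power(10.0, -np.asarray(q, dtype=float) / 10.0)


def error_to_phred(p) -> np.ndarray:
    """Error probability -> Phred score."""
    return -10.0 * np.log10(np.asarray(p, dtype=float))
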