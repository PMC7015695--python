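"""Small DNA-string utilities shared across modules."""

from __future__ import annotations

import numpy as np

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"

#: byte codes used by the numba kernels (A,C,G,T -> 0..3)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, name: str = "sequence") -> str:
    """Validate an uppercase A/C/G/T string; no silent coercion."""
    if not seq:
        raise InputError(f"{name} is empty")
    if any(c not in "ACGT" for c in seq):
        raise InputError(f"{name} contains characters outside uppercase ACGT")
    return seq


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes 0..3 (other characters -> 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform-composition random DNA."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
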