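"""Small sequence utilities shared across modules.

Sequences are plain Python strings over {A,C,G,T} (uppercase); for numeric
work they are encoded as int8 arrays with A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# lookup table: byte value -> code, 255 for non-ACGT
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T(/N) string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0,C=1,G=2,T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr.astype(np.int8)


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(BASES[i] for i in arr)


def encode_revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement in encoded space (3 - code, reversed)."""
    return (3 - arr[::-1]).astype(np.int8)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def base_composition(seqs) -> np.ndarray:
    """Pooled A/C/G/T frequencies of an iterable of sequences."""
    counts = np.zeros(4, dtype=float)
    for s in seqs:
        arr = s if isinstance(s, np.ndarray) else encode(s)
        counts += np.bincount(arr, minlength=4)[:4]
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total
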