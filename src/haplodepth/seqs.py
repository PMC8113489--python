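"""Byte-level sequence utilities shared by the simulator and the read placer.

Sequences are held internally as ``numpy`` ``uint8`` arrays of ASCII codes
(``A C G T``), which makes per-base comparison, reverse complement and GC
counting vectorisable.  Strings appear only at I/O boundaries.
"""

from __future__ import annotations

import numpy as np

#: the four nucleotide byte codes in 2-bit encoding order
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII -> 2-bit code; invalid bytes map to 255
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i

# ASCII -> complement ASCII; anything else maps to 'N'
_COMPLEMENT = np.full(256, ord("N"), dtype=np.uint8)
for _x, _y in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMPLEMENT[_x] = _y


def to_array(seq: str | bytes | np.ndarray) -> np.ndarray:
    """Coerce a sequence to an upper-case uint8 ASCII array."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = np.frombuffer(seq.upper(), dtype=np.uint8).copy()
    return arr


def to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def encode2bit(arr: np.ndarray) -> np.ndarray:
    """Map ASCII bases to 0..3 (255 for non-ACGT)."""
    return _ENCODE[arr]


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr][::-1]


def revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement every row of a 2-D read matrix."""
    return _COMPLEMENT[mat][:, ::-1]


def gc_fraction(arr: np.ndarray) -> float:
    code = encode2bit(arr)
    return float(np.count_nonzero((code == 1) | (code == 2)) / code.size)


def random_sequence(length: int, gc_content: float, rng: np.random.Generator) -> np.ndarray:
    """Random ACGT sequence with the given expected GC fraction."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content must lie in (0, 1), got {gc_content}")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return rng.choice(BASES, size=length, p=[at, gc, gc, at])


def write_fasta(path, sequences: dict[str, np.ndarray], width: int = 60) -> None:
    """Write named sequences as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, arr in sequences.items():
            fh.write(f">{name}\n")
            s = to_str(to_array(arr))
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    """Load a FASTA file into name -> uint8 array (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    out = {name: to_array(str(fa[name][:])) for name in fa.keys()}
    fa.close()
    return out
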