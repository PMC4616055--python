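"""Shared nucleotide encoding helpers.

Bases are stored internally as uint8 codes 0..3 (A, C, G, T); 4 encodes N
where N is tolerated (input FASTA only — the simulators never emit it).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("N")] = N_CODE
_ENC[ord("n")] = N_CODE

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str, allow_n: bool = False) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes; raises on anything
    outside A/C/G/T (plus N when ``allow_n``)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    limit = N_CODE if allow_n else N_CODE - 1
    if codes.size and codes.max() > limit:
        bad = int(np.argmax(codes > limit))
        raise ValueError(f"invalid base {seq[bad]!r} at position {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of an A/C/G/T code array (no N)."""
    return (3 - codes[::-1]).astype(np.uint8)


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
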