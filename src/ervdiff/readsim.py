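"""Paired-end short-read simulation (wgsim-style, substitution errors only).

Fragments of a fixed total insert size are drawn uniformly from uniformly
chosen templates; mate 1 is the fragment's 5' end read forward, mate 2 is
the reverse complement of the fragment's 3' end (FR orientation). Base-call
errors are injected as independent per-base substitutions to one of the
three alternative bases; no indels, no quality model — the downstream
analysis is mismatch-based and never consults qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._seq import decode, encode
from .evolve import SequenceSet

__all__ = ["ReadSimParams", "ReadPair", "simulate_read_pairs", "inject_errors",
           "interleaved_reads"]


@dataclass(frozen=True)
class ReadSimParams:
    """Read-simulation settings.

    ``insert_size`` is the total fragment span, so the inner gap between the
    two mates is ``insert_size - 2 * read_length`` (300 bp at the 100/500
    defaults)."""

    n_pairs: int
    read_length: int = 100
    insert_size: int = 500
    error_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.insert_size < 2 * self.read_length:
            raise ValueError("insert_size must be >= 2 * read_length")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")

    @property
    def inner_gap(self) -> int:
        return self.insert_size - 2 * self.read_length


@dataclass(frozen=True)
class ReadPair:
    """One simulated fragment with its ground truth.

    ``mate1``/``mate2`` are as sequenced (mate2 already reverse
    complemented). ``fragment_start`` is the 0-based leftmost coordinate of
    the fragment on its template; mate2's leftmost template coordinate is
    ``fragment_start + insert_size - read_length``. ``errors1``/``errors2``
    list injected-error offsets within each sequenced mate."""

    mate1: str
    mate2: str
    template_index: int
    fragment_start: int
    orientation: str = "FR"
    errors1: tuple[int, ...] = ()
    errors2: tuple[int, ...] = ()


def inject_errors(
    read: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Substitute each base independently with probability ``error_rate``
    (always to a different base); returns the read and the true error
    offsets."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    codes = encode(read)
    if error_rate <= 0.0:
        return read, ()
    hit = np.flatnonzero(rng.random(codes.size) < error_rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return decode(codes), tuple(int(i) for i in hit)


def simulate_read_pairs(
    seqset: SequenceSet, params: ReadSimParams
) -> list[ReadPair]:
    """Draw ``n_pairs`` fragments and return their mates with truth fields."""
    templates = seqset.as_codes()
    n_templates, length = templates.shape
    if length < params.insert_size:
        raise ValueError(
            f"template length {length} shorter than insert size "
            f"{params.insert_size}"
        )
    rng = np.random.default_rng(params.seed)
    n, rl = params.n_pairs, params.read_length
    tidx = rng.integers(0, n_templates, size=n)
    starts = rng.integers(0, length - params.insert_size + 1, size=n)
    offsets = np.arange(rl)
    m1 = templates[tidx[:, None], starts[:, None] + offsets]
    m2_fwd = templates[
        tidx[:, None], (starts + params.insert_size - rl)[:, None] + offsets
    ]
    m2 = (3 - m2_fwd[:, ::-1]).astype(np.uint8)  # reverse complement

    err1: list[tuple[int, ...]] = [()] * n
    err2: list[tuple[int, ...]] = [()] * n
    if params.error_rate > 0.0 and n:
        for mat, store in ((m1, err1), (m2, err2)):
            mask = rng.random(mat.shape) < params.error_rate
            rows, cols = np.nonzero(mask)
            if rows.size:
                shift = rng.integers(1, 4, size=rows.size, dtype=np.uint8)
                mat[rows, cols] = (mat[rows, cols] + shift) % 4
                for r in np.unique(rows):
                    store[r] = tuple(int(c) for c in cols[rows == r])

    return [
        ReadPair(
            mate1=decode(m1[i]),
            mate2=decode(m2[i]),
            template_index=int(tidx[i]),
            fragment_start=int(starts[i]),
            errors1=err1[i],
            errors2=err2[i],
        )
        for i in range(n)
    ]


def interleaved_reads(pairs: list[ReadPair]) -> list[str]:
    """Flat read list (mate1, mate2, mate1, ...) for assembly and mapping;
    mates are treated as independent observations downstream."""
    out: list[str] = []
    for p in pairs:
        out.append(p.mate1)
        out.append(p.mate2)
    return out
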