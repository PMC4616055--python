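"""Ungapped read mapping under a mismatch budget, and pileup construction.

A read (or its reverse complement) is placed end-to-end at every feasible
contig offset; the minimum-mismatch placement is kept if its mismatch count
is within ``floor(max_mismatch_frac * read_length)`` — 4 mismatches for a
100 nt read at the 0.04 default. Ties between co-optimal placements are
broken by a seeded uniform draw. Candidate offsets come from exact seed
matches of length ``read_length // (budget + 1)``; by the pigeonhole
principle every placement within budget contains at least one exact seed,
so the seeded search returns exactly what an exhaustive scan would.

The pileup counts only read bases: the contig's own consensus base
contributes no count, and mates of a pair are counted independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from ._seq import encode, revcomp_codes

__all__ = [
    "Placement",
    "Pileup",
    "ReadMapper",
    "map_read",
    "map_reads",
    "build_pileup",
    "coverage_summary",
]


@dataclass(frozen=True)
class Placement:
    """A mapped read: leftmost 0-based contig offset, strand, and the
    mismatching sites as (contig position, aligned read base code)."""

    read_id: int
    pos: int
    strand: str  # '+' or '-'
    n_mismatch: int
    mismatches: tuple[tuple[int, int], ...]  # (contig_pos, read base code)


@dataclass
class Pileup:
    """Per-position allele counts over a contig.

    ``counts`` has shape (4, N) ordered A/C/G/T; ``ref_codes`` holds the
    contig base per position (4 = N)."""

    counts: np.ndarray
    ref_codes: np.ndarray
    name: str = "contig"

    @property
    def n_positions(self) -> int:
        return self.counts.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _contig_sequence(contig: Union[str, object]) -> str:
    return getattr(contig, "sequence", contig)  # accepts Contig or str


class ReadMapper:
    """Reusable mapper for one contig (seed indexes are cached)."""

    def __init__(
        self,
        contig: Union[str, object],
        max_mismatch_frac: float = 0.04,
        seed: Optional[int] = 0,
    ) -> None:
        if not 0.0 <= max_mismatch_frac < 1.0:
            raise ValueError("max_mismatch_frac must be in [0, 1)")
        self.sequence = _contig_sequence(contig)
        self.codes = encode(self.sequence, allow_n=True)
        self.max_mismatch_frac = max_mismatch_frac
        self.rng = np.random.default_rng(seed)
        self._indexes: dict[int, dict[int, np.ndarray]] = {}

    # -- seed index ----------------------------------------------------
    def _index(self, s: int) -> dict[int, np.ndarray]:
        idx = self._indexes.get(s)
        if idx is None:
            idx = {}
            c = self.codes
            n = c.size - s + 1
            if n > 0:
                km = np.zeros(n, dtype=np.int64)
                ok = np.ones(n, dtype=bool)
                for i in range(s):
                    col = c[i : i + n]
                    km = (km << 2) | (col & 3)
                    ok &= col < 4
                order = np.argsort(km[ok], kind="stable")
                keys = km[ok][order]
                positions = np.flatnonzero(ok)[order]
                bounds = np.flatnonzero(np.diff(keys)) + 1
                for lo, hi in zip(
                    np.concatenate(([0], bounds)),
                    np.concatenate((bounds, [keys.size])),
                ):
                    idx[int(keys[lo])] = positions[lo:hi]
            self._indexes[s] = idx
        return idx

    def _candidates(self, codes: np.ndarray, s: int) -> set[int]:
        index = self._index(s)
        cands: set[int] = set()
        L = codes.size
        limit = self.codes.size - L
        n_seeds = L // s
        for i in range(n_seeds):
            key = 0
            for b in codes[i * s : (i + 1) * s]:
                key = (key << 2) | int(b)
            hits = index.get(key)
            if hits is not None:
                for p in hits:
                    cand = int(p) - i * s
                    if 0 <= cand <= limit:
                        cands.add(cand)
        return cands

    # -- mapping -------------------------------------------------------
    def _place(
        self,
        read_id: int,
        fwd: np.ndarray,
        rc: np.ndarray,
        cand_fwd: Iterable[int],
        cand_rev: Iterable[int],
        budget: int,
    ) -> Optional[Placement]:
        L = fwd.size
        best_mm = budget + 1
        best: list[tuple[int, str]] = []
        for strand, codes, cands in (("+", fwd, cand_fwd), ("-", rc, cand_rev)):
            for cand in cands:
                mm = int(
                    np.count_nonzero(self.codes[cand : cand + L] != codes)
                )
                if mm < best_mm:
                    best_mm = mm
                    best = [(cand, strand)]
                elif mm == best_mm:
                    best.append((cand, strand))
        if best_mm > budget:
            return None
        pick = int(self.rng.integers(0, len(best))) if len(best) > 1 else 0
        pos, strand = best[pick]
        aligned = fwd if strand == "+" else rc
        diff = self.codes[pos : pos + L] != aligned
        sites = tuple(
            (pos + int(j), int(aligned[j])) for j in np.flatnonzero(diff)
        )
        return Placement(
            read_id=read_id,
            pos=pos,
            strand=strand,
            n_mismatch=best_mm,
            mismatches=sites,
        )

    def map(self, read: str, read_id: int = 0) -> Optional[Placement]:
        """Best placement of ``read`` or its reverse complement, or None."""
        codes = encode(read)
        L = codes.size
        if L > self.codes.size:
            return None
        budget = int(np.floor(self.max_mismatch_frac * L))
        s = min(max(1, L // (budget + 1)), 31)  # 31 bases cap: keys fit int64
        rc = revcomp_codes(codes)
        return self._place(
            read_id,
            codes,
            rc,
            sorted(self._candidates(codes, s)),
            sorted(self._candidates(rc, s)),
            budget,
        )

    def map_all(self, reads: Sequence[str]) -> list[Optional[Placement]]:
        """Map many reads; reads of one common length share vectorised seed
        extraction (results identical to per-read mapping)."""
        if not reads:
            return []
        lengths = {len(r) for r in reads}
        if len(lengths) != 1:
            return [self.map(r, i) for i, r in enumerate(reads)]
        L = lengths.pop()
        if L == 0 or L > self.codes.size:
            return [None] * len(reads)
        budget = int(np.floor(self.max_mismatch_frac * L))
        s = min(max(1, L // (budget + 1)), 31)  # 31 bases cap: keys fit int64
        n_seeds = L // s
        index = self._index(s)
        n = len(reads)
        mat = encode("".join(reads)).reshape(n, L)
        rc = (3 - mat[:, ::-1]).astype(np.uint8)
        pw = (4 ** np.arange(s - 1, -1, -1)).astype(np.int64)
        limit = self.codes.size - L

        def seed_keys(m: np.ndarray) -> np.ndarray:
            out = np.empty((n, n_seeds), dtype=np.int64)
            for i in range(n_seeds):
                out[:, i] = m[:, i * s : (i + 1) * s].astype(np.int64) @ pw
            return out

        keys_f, keys_r = seed_keys(mat), seed_keys(rc)

        def cands(keys_row: np.ndarray) -> list[int]:
            found: set[int] = set()
            for i in range(n_seeds):
                hits = index.get(int(keys_row[i]))
                if hits is not None:
                    off = i * s
                    for p in hits:
                        c = int(p) - off
                        if 0 <= c <= limit:
                            found.add(c)
            return sorted(found)

        return [
            self._place(r, mat[r], rc[r], cands(keys_f[r]), cands(keys_r[r]), budget)
            for r in range(n)
        ]


def map_read(
    read: str,
    contig: Union[str, object],
    max_mismatch_frac: float = 0.04,
    seed: Optional[int] = 0,
) -> Optional[Placement]:
    return ReadMapper(contig, max_mismatch_frac, seed).map(read)


def map_reads(
    reads: Sequence[str],
    contig: Union[str, object],
    max_mismatch_frac: float = 0.04,
    seed: Optional[int] = 0,
) -> list[Optional[Placement]]:
    return ReadMapper(contig, max_mismatch_frac, seed).map_all(reads)


def build_pileup(
    placements: Iterable[Optional[Placement]],
    reads: Sequence[str],
    contig: Union[str, object],
    name: str = "contig",
) -> Pileup:
    """Allele counts from mapped reads; unmapped entries (None) are skipped.

    Each aligned read base increments one cell of ``counts``; the consensus
    itself adds nothing."""
    ref = encode(_contig_sequence(contig), allow_n=True)
    counts = np.zeros((4, ref.size), dtype=np.int32)
    pos_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []
    for pl in placements:
        if pl is None:
            continue
        codes = encode(reads[pl.read_id])
        if pl.strand == "-":
            codes = revcomp_codes(codes)
        if pl.pos < 0 or pl.pos + codes.size > ref.size:
            raise AssertionError("placement outside contig bounds")
        pos_chunks.append(np.arange(pl.pos, pl.pos + codes.size))
        code_chunks.append(codes)
    if pos_chunks:
        np.add.at(
            counts,
            (np.concatenate(code_chunks), np.concatenate(pos_chunks)),
            1,
        )
    return Pileup(counts=counts, ref_codes=ref, name=name)


def coverage_summary(pileup: Pileup, min_cov: int = 5) -> tuple[float, int]:
    """Mean coverage over all positions and the number of positions with
    coverage at least ``min_cov``."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    cov = pileup.coverage
    if cov.size == 0:
        return 0.0, 0
    return float(cov.mean()), int(np.count_nonzero(cov >= min_cov))
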