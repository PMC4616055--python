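"""Diversity measures on pileups and the substitution-linkage statistic.

Per-site nucleotide diversity is the unbiased pairwise-difference rate:
with allele counts C_i at a position of coverage n, the fraction of
mismatching unordered read-base pairs, algebraically
``(n / (n - 1)) * (1 - sum_i (C_i / n)**2)``. The three genome-wide
measures — nucleotide diversity, mean combined minor-allele frequency and
the proportion of variable sites — average over positions whose coverage
meets a floor (default 5 reads); positions with an N reference base are
excluded. On a full parental alignment every column has the family size as
coverage and no floor applies.

A *substitution* is a (position, alternative base) pair observed in reads
at a covered position. For two substitutions A and B, the linkage over the
reads covering both positions is

    both / (A_only + B_only + both)

where a read "has" a substitution iff its aligned base equals that exact
alternative. Pairs with a zero denominator are excluded; ``mean_linkage``
averages the rest. Mates of a pair are independent observations, so
co-coverage requires both positions within one mate's span. Two clades of
haplotypes elevate this statistic because their diagnostic substitutions
co-occur on the same reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from ._seq import BASES
from .evolve import SequenceSet
from .mapper import Pileup, Placement

__all__ = [
    "DiversityResult",
    "Substitution",
    "LinkageTable",
    "site_diversity",
    "nucleotide_diversity",
    "minor_allele_frequency",
    "proportion_variable_sites",
    "diversity_measures",
    "true_diversity",
    "call_substitutions",
    "pairwise_linkage",
]


@dataclass(frozen=True)
class DiversityResult:
    """The three diversity measures plus the coverage filter that produced
    them. Measures are None when no position qualified."""

    pi: Optional[float]
    maf: Optional[float]
    pvar: Optional[float]
    n_positions_used: int
    min_cov: int

    @property
    def defined(self) -> bool:
        return self.pi is not None


@dataclass(frozen=True)
class Substitution:
    position: int  # 0-based contig coordinate
    alt_base: str


def _as_counts(counts: Union[Mapping[str, int], Sequence[int]]) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.zeros(4, dtype=np.int64)
        for base, c in counts.items():
            arr[BASES.index(base)] = c
        return arr
    return np.asarray(counts, dtype=np.int64)


def site_diversity(counts: Union[Mapping[str, int], Sequence[int]]) -> float:
    """Unbiased per-site pairwise-difference rate for one position."""
    arr = _as_counts(counts)
    n = int(arr.sum())
    if n < 2:
        raise ValueError("site diversity needs coverage >= 2")
    p = arr / n
    return float(n / (n - 1) * (1.0 - np.square(p).sum()))


def _qualifying(pileup: Pileup, min_cov: int) -> np.ndarray:
    cov = pileup.coverage
    return (cov >= min_cov) & (pileup.ref_codes < 4)


def _column_pi(counts: np.ndarray) -> np.ndarray:
    n = counts.sum(axis=0).astype(float)
    p2 = np.square(counts / n).sum(axis=0)
    return n / (n - 1) * (1.0 - p2)


def nucleotide_diversity(pileup: Pileup, min_cov: int = 5) -> Optional[float]:
    """Mean per-site diversity over positions with coverage >= min_cov."""
    if min_cov < 2:
        raise ValueError("min_cov must be >= 2 for nucleotide diversity")
    use = _qualifying(pileup, min_cov)
    if not use.any():
        return None
    return float(_column_pi(pileup.counts[:, use]).mean())


def minor_allele_frequency(pileup: Pileup, min_cov: int = 5) -> Optional[float]:
    """Mean combined non-major allele frequency over qualifying positions
    (major-allele ties break to the lexicographically smallest base)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    use = _qualifying(pileup, min_cov)
    if not use.any():
        return None
    counts = pileup.counts[:, use]
    n = counts.sum(axis=0).astype(float)
    major = counts.max(axis=0)  # argmax ties are moot: only the count matters
    return float((1.0 - major / n).mean())


def proportion_variable_sites(pileup: Pileup, min_cov: int = 5) -> Optional[float]:
    """Fraction of qualifying positions showing more than one allele."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    use = _qualifying(pileup, min_cov)
    if not use.any():
        return None
    counts = pileup.counts[:, use]
    return float(((counts > 0).sum(axis=0) > 1).mean())


def diversity_measures(pileup: Pileup, min_cov: int = 5) -> DiversityResult:
    use = _qualifying(pileup, min_cov)
    n_used = int(use.sum())
    if n_used == 0:
        return DiversityResult(None, None, None, 0, min_cov)
    return DiversityResult(
        pi=nucleotide_diversity(pileup, min_cov),
        maf=minor_allele_frequency(pileup, min_cov),
        pvar=proportion_variable_sites(pileup, min_cov),
        n_positions_used=n_used,
        min_cov=min_cov,
    )


def true_diversity(seqset: SequenceSet) -> DiversityResult:
    """The three measures on the full parental alignment (every column has
    the family size as coverage; no floor)."""
    if len(seqset) < 2:
        raise ValueError("true diversity needs at least 2 sequences")
    mat = seqset.as_codes()
    n_seq, length = mat.shape
    counts = np.zeros((4, length), dtype=np.int64)
    for b in range(4):
        counts[b] = (mat == b).sum(axis=0)
    pi = float(_column_pi(counts).mean())
    n = counts.sum(axis=0).astype(float)
    maf = float((1.0 - counts.max(axis=0) / n).mean())
    pvar = float(((counts > 0).sum(axis=0) > 1).mean())
    return DiversityResult(pi, maf, pvar, length, 0)


def call_substitutions(pileup: Pileup, min_cov: int = 5) -> list[Substitution]:
    """All (position, alt base) pairs with at least one supporting read at
    positions meeting the coverage floor; the reference base itself is not
    a substitution. Sorted by (position, base)."""
    use = _qualifying(pileup, min_cov)
    subs: list[Substitution] = []
    base_rows, pos_cols = np.nonzero(pileup.counts > 0)
    for b, j in zip(base_rows, pos_cols):
        if use[j] and b != pileup.ref_codes[j]:
            subs.append(Substitution(int(j), BASES[b]))
    subs.sort(key=lambda s: (s.position, s.alt_base))
    return subs


@dataclass
class LinkageTable:
    """Aggregated co-occurrence counts for all substitution pairs.

    ``mean_linkage`` is None when fewer than two substitutions exist or
    every pair has a zero denominator."""

    substitutions: list[Substitution]
    mean_linkage: Optional[float]
    n_pairs_defined: int
    _both: sp.csr_matrix = field(repr=False, default=None)
    _carry_cover: sp.csr_matrix = field(repr=False, default=None)
    _read_starts: np.ndarray = field(repr=False, default=None)
    _read_ends: np.ndarray = field(repr=False, default=None)

    def pair_counts(self, a: int, b: int) -> tuple[int, int, int]:
        """(count_both, count_A_only, count_B_only) for substitution
        indices a, b."""
        both = int(self._both[a, b])
        a_only = int(self._carry_cover[a, b]) - both
        b_only = int(self._carry_cover[b, a]) - both
        return both, a_only, b_only

    def count_cocovering(self, a: int, b: int) -> int:
        """Reads covering both positions of the pair."""
        lo = min(self.substitutions[a].position, self.substitutions[b].position)
        hi = max(self.substitutions[a].position, self.substitutions[b].position)
        return int(
            np.count_nonzero((self._read_starts <= lo) & (self._read_ends > hi))
        )

    def pair_linkage(self, a: int, b: int) -> Optional[float]:
        both, a_only, b_only = self.pair_counts(a, b)
        denom = both + a_only + b_only
        if denom == 0:
            return None
        return both / denom


def pairwise_linkage(
    placements: Sequence[Optional[Placement]],
    reads: Sequence[str],
    substitutions: Sequence[Substitution],
) -> LinkageTable:
    """Classify every read against every substitution pair it covers and
    average the per-pair linkage; reads are the mapper's input (used only
    for their lengths)."""
    subs = sorted(substitutions, key=lambda s: (s.position, s.alt_base))
    S = len(subs)
    mapped = [pl for pl in placements if pl is not None]
    starts = np.array([pl.pos for pl in mapped], dtype=np.int64)
    lengths = np.array([len(reads[pl.read_id]) for pl in mapped], dtype=np.int64)
    ends = starts + lengths
    if S < 2 or not mapped:
        return LinkageTable(subs, None, 0, _read_starts=starts, _read_ends=ends)

    sub_index = {(s.position, s.alt_base): i for i, s in enumerate(subs)}
    positions = np.array([s.position for s in subs], dtype=np.int64)

    rows: list[int] = []
    cols: list[int] = []
    for r, pl in enumerate(mapped):
        for pos, base_code in pl.mismatches:
            j = sub_index.get((pos, BASES[base_code]))
            if j is not None:
                rows.append(r)
                cols.append(j)
    R = len(mapped)
    M = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)), shape=(R, S)
    )

    # coverage is a contiguous slice of the position-sorted substitutions
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="left")
    span = hi - lo
    indptr = np.concatenate(([0], np.cumsum(span)))
    # indices = concat(arange(lo_r, hi_r) for r)
    idx = np.repeat(lo, span) + (
        np.arange(indptr[-1]) - np.repeat(indptr[:-1], span)
    )
    C = sp.csr_matrix(
        (np.ones(idx.size, dtype=np.int32), idx, indptr), shape=(R, S)
    )

    both = (M.T @ M).tocsr()
    carry_cover = (M.T @ C).tocsr()

    D = (carry_cover + carry_cover.T - both).tocoo()
    valid = (
        (D.row < D.col) & (positions[D.row] != positions[D.col]) & (D.data > 0)
    )
    n_defined = int(np.count_nonzero(valid))
    mean: Optional[float] = None
    if n_defined:
        # ratio sum only needs pairs where both > 0 (others contribute 0)
        B = sp.triu(both, k=1).tocoo()
        bmask = (positions[B.row] != positions[B.col]) & (B.data > 0)
        total = 0.0
        if bmask.any():
            br, bc, bv = B.row[bmask], B.col[bmask], B.data[bmask]
            pattern = sp.coo_matrix(
                (np.ones(br.size), (br, bc)), shape=both.shape
            ).tocsr()
            Dm = (
                (carry_cover + carry_cover.T - both).multiply(pattern).tocsr()
            )
            Dm.sort_indices()
            Bv = sp.coo_matrix((bv, (br, bc)), shape=both.shape).tocsr()
            Bv.sort_indices()
            total = float((Bv.data / Dm.data).sum())
        mean = total / n_defined
    return LinkageTable(
        subs,
        mean,
        n_defined,
        _both=both,
        _carry_cover=carry_cover,
        _read_starts=starts,
        _read_ends=ends,
    )
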