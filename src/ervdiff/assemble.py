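"""Minimal de Bruijn assembly with bubble resolution.

Reads (both mates; strand handled by canonical k-mers) are decomposed into
k-mers; k-mers below an abundance floor are dropped, and contigs are the
maximal non-branching paths of the remaining graph after iterative bubble
resolution. A *bubble* is a pair of short parallel unitigs joining the same
two junction ends — the signature of an isolated polymorphic site or a
sequencing-error survivor. The lower-coverage arm is deleted and the graph
recompacted, inside-out, until a fixed point; the surviving contig follows
the locally dominant allele, i.e. approximates the consensus. Parallel
paths longer than ``max_bubble_len`` are *not* merged: when two templates
diverge so much that their k-mer paths stay separate for long stretches,
the graph remains branched and assembly fragments — the behaviour that
makes co-infection at intermediate divergence visible as short contigs.

Everything is deterministic for a fixed input ordering: k-mers are
processed in sorted order, and ties (equal-coverage bubble arms, equal
contig lengths) break lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._seq import decode, encode
from .evolve import SequenceSet
from .mapper import ReadMapper

__all__ = ["Contig", "assemble_contigs", "longest_contig", "attribute_contig"]


@dataclass(frozen=True)
class Contig:
    """An assembled consensus sequence.

    ``read_support`` counts reads sharing at least one k-mer with the
    contig; ``mean_kmer_coverage`` is the average abundance of its k-mers.
    """

    sequence: str
    read_support: int
    kmer_size: int
    mean_kmer_coverage: float = 0.0

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# k-mer extraction


def _rc_kmers(km: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of 2-bit packed k-mers."""
    x = km.copy()
    r = np.zeros_like(km)
    for _ in range(k):
        r = (r << 2) | (3 - (x & 3))
        x >>= 2
    return r


def _kmer_stream(reads: Sequence[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mers of all reads as packed ints, with the source read id per
    k-mer instance. Reads shorter than k contribute nothing."""
    if not reads:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    # one join + one encode; N doubles as the record separator and masks
    # any N windows inside reads as well
    big = encode("N".join(reads) + "N", allow_n=True)
    lengths = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    starts = np.concatenate(([0], np.cumsum(lengths + 1)))
    n_win = big.size - k + 1
    if n_win <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    km = np.zeros(n_win, dtype=np.int64)
    ok = np.ones(n_win, dtype=bool)
    for i in range(k):
        col = big[i : i + n_win].astype(np.int64)
        km = (km << 2) | (col & 3)
        ok &= col < 4
    win_pos = np.flatnonzero(ok)
    read_ids = np.searchsorted(starts, win_pos, side="right") - 1
    return km[ok], read_ids


# ---------------------------------------------------------------------------
# compacted graph


class _Graph:
    """Sorted canonical k-mer set with vectorised adjacency tables."""

    def __init__(self, kmers: np.ndarray, counts: np.ndarray, k: int) -> None:
        self.K = kmers  # sorted canonical
        self.counts = counts
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        self.R = _rc_kmers(kmers, k)
        self._build_tables()

    def _build_tables(self) -> None:
        n = self.K.size
        hi_shift = 2 * (self.k - 1)
        outdeg = np.zeros((n, 2), dtype=np.int8)
        nidx = np.full((n, 2), -1, dtype=np.int64)
        nori = np.zeros((n, 2), dtype=np.int8)
        for o, (X, XR) in enumerate(((self.K, self.R), (self.R, self.K))):
            base = (X << 2) & self.mask
            rc_base = XR >> 2
            for b in range(4):
                y = base | b
                ry = rc_base | ((3 - b) << hi_shift)
                cy = np.minimum(y, ry)
                pos = np.searchsorted(self.K, cy)
                safe = np.minimum(pos, max(n - 1, 0))
                hit = (pos < n) & (self.K[safe] == cy) if n else np.zeros(0, bool)
                outdeg[:, o] += hit
                nidx[hit, o] = pos[hit]
                nori[hit, o] = (y != cy)[hit]
        self.outdeg = outdeg
        self.next_idx = nidx
        self.next_ori = nori
        # a step (i,o)->(j,o') is unitig-internal iff outdeg(i,o)==1 and
        # the successor's in-degree (= outdeg of its flipped orientation)
        # is also 1
        linked = outdeg == 1
        for o in (0, 1):
            rows = np.flatnonzero(linked[:, o])
            if rows.size:
                j = nidx[rows, o]
                jo = 1 - nori[rows, o]
                linked[rows, o] &= outdeg[j, jo] == 1
        self.linked = linked

    def oriented_value(self, i: int, o: int) -> int:
        return int(self.K[i] if o == 0 else self.R[i])

    def oriented_rc(self, i: int, o: int) -> int:
        return int(self.R[i] if o == 0 else self.K[i])

    def unitigs(self) -> list[list[tuple[int, int]]]:
        """Maximal non-branching chains as lists of (kmer index,
        orientation); deterministic order."""
        n = self.K.size
        visited = np.zeros(n, dtype=bool)
        out: list[list[tuple[int, int]]] = []
        for start in range(n):
            for o in (0, 1):
                if visited[start] or self.linked[start, 1 - o]:
                    continue
                chain = []
                i, co = start, o
                while True:
                    visited[i] = True
                    chain.append((i, co))
                    if not self.linked[i, co]:
                        break
                    j = int(self.next_idx[i, co])
                    if visited[j]:
                        break
                    co = int(self.next_ori[i, co])
                    i = j
                out.append(chain)
                break
        for start in range(n):  # leftover cycles
            if visited[start]:
                continue
            chain = []
            i, co = start, 0
            while not visited[i]:
                visited[i] = True
                chain.append((i, co))
                if not self.linked[i, co]:
                    break
                j = int(self.next_idx[i, co])
                co = int(self.next_ori[i, co])
                i = j
            out.append(chain)
        return out

    def chain_sequence(self, chain: list[tuple[int, int]]) -> str:
        k = self.k
        first = self.oriented_value(*chain[0])
        codes = np.empty(k + len(chain) - 1, dtype=np.uint8)
        for j in range(k):
            codes[k - 1 - j] = (first >> (2 * j)) & 3
        for idx, (i, o) in enumerate(chain[1:], start=1):
            codes[k - 1 + idx] = self.oriented_value(i, o) & 3
        return decode(codes)


def _pop_bubbles(
    graph: _Graph, max_bubble_len: int
) -> tuple[Optional[np.ndarray], list[list[tuple[int, int]]]]:
    """One bulge-removal round.

    A candidate is a short unitig with exactly one neighbour at each end.
    It is deleted when the two junction ends it joins are also connected by
    an alternative path of bounded length whose every unitig carries at
    least half the candidate's coverage — i.e. the candidate is a minority
    allele (or error survivor) detouring around a better-supported path.
    Candidates are processed in ascending coverage order and a deleted arm
    can no longer serve as someone else's alternative path, so the two arms
    of an evenly balanced bubble can never both disappear. Returns (keep
    mask or None when nothing was deleted, the current unitig chains)."""
    chains = graph.unitigs()
    k = graph.k
    pos = {int(v): i for i, v in enumerate(graph.K)}
    hi_shift = 2 * (k - 1)

    end_map: dict[tuple[int, int], tuple[int, str]] = {}
    for uid, chain in enumerate(chains):
        i0, o0 = chain[0]
        iL, oL = chain[-1]
        end_map[(i0, o0)] = (uid, "h")
        end_map[(iL, 1 - oL)] = (uid, "t")

    def neighbours(val: int, rc_val: int) -> Optional[list[tuple[int, str]]]:
        found = []
        for b in range(4):
            y = ((val << 2) & graph.mask) | b
            ry = (rc_val >> 2) | ((3 - b) << hi_shift)
            cy = min(y, ry)
            idx = pos.get(cy)
            if idx is None:
                continue
            token = end_map.get((idx, 0 if y == cy else 1))
            if token is None:
                return None  # cycle-guard artefact; skip this end
            found.append(token)
        return found

    n_units = len(chains)
    cov = np.empty(n_units)
    n_kmers = np.empty(n_units, dtype=np.int64)
    head_targets: list[Optional[list[tuple[int, str]]]] = []
    tail_targets: list[Optional[list[tuple[int, str]]]] = []
    for uid, chain in enumerate(chains):
        idxs = [i for i, _ in chain]
        cov[uid] = float(graph.counts[idxs].mean())
        n_kmers[uid] = len(chain)
        head_targets.append(
            neighbours(
                graph.oriented_rc(*chain[0]), graph.oriented_value(*chain[0])
            )
        )
        tail_targets.append(
            neighbours(
                graph.oriented_value(*chain[-1]), graph.oriented_rc(*chain[-1])
            )
        )

    def targets_at(token: tuple[int, str]) -> Optional[list[tuple[int, str]]]:
        uid, end = token
        return head_targets[uid] if end == "h" else tail_targets[uid]

    def exits_of(token: tuple[int, str]) -> Optional[list[tuple[int, str]]]:
        # entering a unitig at `end` and traversing it leaves via the
        # opposite end
        uid, end = token
        return tail_targets[uid] if end == "h" else head_targets[uid]

    def alt_path_exists(
        start: list[tuple[int, str]],
        goal: tuple[int, str],
        skip: set[int],
        min_cov: float,
        max_kmers: int,
    ) -> bool:
        if goal in start:
            return True  # the junctions are also directly adjacent
        stack = [(tok, 0) for tok in start]
        seen: set[tuple[int, str]] = set()
        while stack:
            token, used = stack.pop()
            uid = token[0]
            if token in seen or uid in skip or cov[uid] < min_cov:
                continue
            seen.add(token)
            length = used + int(n_kmers[uid])
            if length > max_kmers:
                continue
            nxt = exits_of(token)
            if nxt is None:
                continue
            if goal in nxt:
                return True
            stack.extend((t, length) for t in nxt)
        return False

    deleted: set[int] = set()

    # phase 0: tips — short dead-end stubs (error k-mers that recur at
    # high coverage and truncate before rejoining) are clipped when a far
    # better-covered branch continues from the same junction; genuine
    # template ends survive via the length or coverage guard
    tip_max_len = 2 * k
    for uid in range(n_units):
        ht, tl = head_targets[uid], tail_targets[uid]
        if ht is None or tl is None:
            continue
        dead_head, dead_tail = len(ht) == 0, len(tl) == 0
        if dead_head == dead_tail:
            continue
        if k + int(n_kmers[uid]) - 1 > tip_max_len:
            continue
        attach = tl if dead_head else ht
        competitor = 0.0
        for tok in attach:
            alts = targets_at(tok)
            if alts is None:
                continue
            for vid, _ in alts:
                if vid != uid:
                    competitor = max(competitor, cov[vid])
        if competitor > 0.0 and cov[uid] < 0.25 * competitor:
            deleted.add(uid)

    # phase 1: exactly parallel arms — identical attachment-token sets at
    # both ends (orientation-normalised); keep the best-covered one
    groups: dict[tuple, list[int]] = {}
    for uid in range(n_units):
        ht, tl = head_targets[uid], tail_targets[uid]
        if ht is None or tl is None or not ht or not tl:
            continue
        if any(t[0] == uid for t in ht + tl):
            continue
        key = tuple(sorted((tuple(sorted(ht)), tuple(sorted(tl)))))
        groups.setdefault(key, []).append(uid)
    for members in groups.values():
        if len(members) < 2:
            continue
        ordered = sorted(
            members,
            key=lambda u: (-cov[u], int(graph.K[chains[u][0][0]])),
        )
        for uid in ordered[1:]:
            if k + int(n_kmers[uid]) - 1 <= max_bubble_len:
                deleted.add(uid)

    # phase 2: minority detours around a better-supported composite path
    candidates = [
        uid
        for uid in range(n_units)
        if uid not in deleted
        and head_targets[uid] is not None
        and tail_targets[uid] is not None
        and len(head_targets[uid]) == 1
        and len(tail_targets[uid]) == 1
        and head_targets[uid][0][0] != uid
        and tail_targets[uid][0][0] != uid
        and k + int(n_kmers[uid]) - 1 <= max_bubble_len
    ]
    # ties break on the first canonical k-mer: deterministic and cheap
    candidates.sort(key=lambda u: (cov[u], int(graph.K[chains[u][0][0]])))

    for uid in candidates:
        if uid in deleted:
            continue
        upstream = head_targets[uid][0]
        goal = tail_targets[uid][0]
        start = targets_at(upstream)
        if start is None:
            continue
        start = [t for t in start if t != (uid, "h") and t[0] not in deleted]
        if not start:
            continue
        if alt_path_exists(
            start,
            goal,
            deleted | {uid},
            min_cov=0.5 * cov[uid],
            max_kmers=int(n_kmers[uid]) + 2 * k,
        ):
            deleted.add(uid)

    if not deleted:
        return None, chains
    keep = np.ones(graph.K.size, dtype=bool)
    for uid in deleted:
        for i, _ in chains[uid]:
            keep[i] = False
    return keep, chains


# ---------------------------------------------------------------------------
# public API


def assemble_contigs(
    reads: Sequence[str],
    k: int = 31,
    min_count: int = 2,
    rel_min_frac: float = 0.05,
    max_bubble_len: Optional[int] = None,
    max_rounds: int = 64,
) -> list[Contig]:
    """Assemble reads into contigs; sorted by length descending (ties by
    sequence).

    The abundance floor is ``max(min_count, rel_min_frac * m)`` where m is
    the median k-mer abundance over k-mer instances (i.e. the typical
    backbone coverage): at high depth recurring sequencing errors exceed
    any fixed count but stay far below a few percent of coverage, while
    genuine minority haplotypes (>= 1 template of 32) stay above it.
    ``max_bubble_len`` bounds the length of a bubble arm that may be
    merged (default 4*k)."""
    if k < 15 or k % 2 == 0:
        raise ValueError("k must be odd and >= 15")
    if max_bubble_len is None:
        max_bubble_len = 4 * k
    km, read_ids = _kmer_stream(reads, k)
    if km.size == 0:
        return []
    canon = np.minimum(km, _rc_kmers(km, k))
    uniq, counts = np.unique(canon, return_counts=True)
    floor = min_count
    if rel_min_frac > 0.0:
        # backbone coverage estimate: 80th percentile of abundance over
        # k-mer instances — robust to error and minority-haplotype k-mers
        # holding a large share of the distinct-k-mer table
        order = np.argsort(counts)
        cum = np.cumsum(counts[order])
        scale = counts[order][np.searchsorted(cum, 0.8 * cum[-1])]
        floor = max(min_count, int(np.ceil(rel_min_frac * scale)))
    keep = counts >= floor
    kmers, counts = uniq[keep], counts[keep]
    if kmers.size == 0:
        return []

    graph = _Graph(kmers, counts, k)
    for _ in range(max_rounds):
        keep_mask, chains = _pop_bubbles(graph, max_bubble_len)
        if keep_mask is None:
            break
        graph = _Graph(graph.K[keep_mask], graph.counts[keep_mask], k)
    else:
        chains = graph.unitigs()

    # read support: distinct reads sharing >= 1 surviving k-mer per contig
    uid_of_kmer = np.empty(graph.K.size, dtype=np.int64)
    mean_cov = np.empty(len(chains))
    for uid, chain in enumerate(chains):
        idxs = [i for i, _ in chain]
        uid_of_kmer[idxs] = uid
        mean_cov[uid] = float(graph.counts[idxs].mean())
    pos = np.searchsorted(graph.K, canon)
    safe = np.minimum(pos, graph.K.size - 1)
    present = graph.K[safe] == canon
    pair_keys = read_ids[present] * len(chains) + uid_of_kmer[safe[present]]
    support = np.zeros(len(chains), dtype=np.int64)
    if pair_keys.size:
        uniq_pairs = np.unique(pair_keys)
        np.add.at(support, uniq_pairs % len(chains), 1)

    contigs = [
        Contig(
            sequence=graph.chain_sequence(chain),
            read_support=int(support[uid]),
            kmer_size=k,
            mean_kmer_coverage=float(mean_cov[uid]),
        )
        for uid, chain in enumerate(chains)
    ]
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


def longest_contig(contigs: Sequence[Contig]) -> Optional[Contig]:
    """Maximum-length contig; ties go to the lexicographically smaller
    sequence; None when the list is empty."""
    if not contigs:
        return None
    return min(contigs, key=lambda c: (-len(c.sequence), c.sequence))


def attribute_contig(
    contig: Contig,
    seqset: SequenceSet,
    min_identity: float = 0.9,
    window: int = 200,
) -> str:
    """Assign a contig to the clade(s) of the parental sequences it derives
    from.

    The contig is cut into non-overlapping windows; each window is aligned
    (ungapped, both strands) against every parental sequence and assigned
    to the clade of its best match when identity >= ``min_identity``.
    Returns a clade label when >= 90% of assignable windows agree, "both"
    when two clades each claim >= 10%, and "none" when no window is
    assignable."""
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")
    seq = contig.sequence
    if not seq:
        raise ValueError("empty contig")
    pieces = [seq[i : i + window] for i in range(0, len(seq) - window + 1, window)]
    if not pieces:
        pieces = [seq]
    mappers = [
        ReadMapper(parent, max_mismatch_frac=min(1.0 - min_identity, 0.999))
        for parent in seqset.sequences
    ]
    votes: dict[str, int] = {}
    assignable = 0
    for piece in pieces:
        best_identity = -1.0
        best_label: Optional[str] = None
        for parent_i, mapper in enumerate(mappers):
            pl = mapper.map(piece)
            if pl is None:
                continue
            identity = 1.0 - pl.n_mismatch / len(piece)
            if identity > best_identity:
                best_identity = identity
                best_label = seqset.clade_labels[parent_i]
        if best_label is None or best_identity < min_identity:
            continue
        assignable += 1
        votes[best_label] = votes.get(best_label, 0) + 1
    if assignable == 0:
        return "none"
    fracs = {label: n / assignable for label, n in votes.items()}
    if sum(1 for f in fracs.values() if f >= 0.10) >= 2:
        return "both"
    top = max(fracs, key=lambda lbl: fracs[lbl])
    if fracs[top] >= 0.90:
        return top
    return "both"
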