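"""Diversity measures and the substitution-linkage statistic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ervdiff import (
    Placement,
    Pileup,
    Substitution,
    call_substitutions,
    diversity_measures,
    minor_allele_frequency,
    nucleotide_diversity,
    pairwise_linkage,
    proportion_variable_sites,
    site_diversity,
    true_diversity,
)
from ervdiff.evolve import SequenceSet


def brute_force_site_diversity(counts: dict[str, int]) -> float:
    """Fraction of mismatching unordered base pairs, by enumeration."""
    bases = [b for b, c in counts.items() for _ in range(c)]
    pairs = list(itertools.combinations(bases, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def make_pileup(columns, ref="A"):
    """columns: list of dicts base->count; ref: base or string."""
    counts = np.zeros((4, len(columns)), dtype=np.int32)
    for j, col in enumerate(columns):
        for base, c in col.items():
            counts["ACGT".index(base), j] = c
    refs = ref * len(columns) if len(ref) == 1 else ref
    ref_codes = np.array(["ACGTN".index(b) for b in refs], dtype=np.uint8)
    return Pileup(counts=counts, ref_codes=ref_codes)


class TestSiteDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 3, "C": 2}, 0.6),
            ({"A": 5}, 0.0),
            ({"A": 1, "C": 1}, 1.0),
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert site_diversity(counts) == pytest.approx(expected)

    def test_rejects_low_coverage(self):
        with pytest.raises(ValueError):
            site_diversity({"A": 1})

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=4, max_size=4)
        .filter(lambda v: sum(v) >= 2)
    )
    def test_matches_pair_enumeration(self, vec):
        counts = dict(zip("ACGT", vec))
        assert site_diversity(counts) == pytest.approx(
            brute_force_site_diversity(counts)
        )


class TestPileupMeasures:
    def test_nucleotide_diversity_average(self):
        p = make_pileup([{"A": 3, "C": 2}, {"G": 5}])
        assert nucleotide_diversity(p, 5) == pytest.approx(0.3)

    def test_low_coverage_positions_excluded(self):
        p = make_pileup([{"A": 3, "C": 2}, {"A": 2, "C": 2}])  # second is 4x
        assert nucleotide_diversity(p, 5) == pytest.approx(0.6)
        assert diversity_measures(p, 5).n_positions_used == 1

    def test_no_qualifying_positions_undefined(self):
        p = make_pileup([{"A": 2}])
        assert nucleotide_diversity(p, 5) is None
        res = diversity_measures(p, 5)
        assert not res.defined

    def test_monomorphic_zero(self):
        p = make_pileup([{"A": 9}, {"C": 7}], ref="AC")
        assert nucleotide_diversity(p, 5) == 0.0
        assert proportion_variable_sites(p, 5) == 0.0

    def test_minor_allele_frequency(self):
        p = make_pileup([{"A": 3, "C": 2}, {"G": 5}])
        assert minor_allele_frequency(p, 5) == pytest.approx(0.2)

    def test_maf_tie_uses_major_count_only(self):
        p = make_pileup([{"A": 2, "C": 2, "G": 1}])
        assert minor_allele_frequency(p, 5) == pytest.approx(0.6)

    def test_proportion_variable(self):
        p = make_pileup([{"A": 3, "C": 2}, {"G": 5}])
        assert proportion_variable_sites(p, 5) == pytest.approx(0.5)

    def test_n_reference_positions_excluded(self):
        p = make_pileup([{"A": 3, "C": 2}, {"A": 6}], ref="NA")
        assert nucleotide_diversity(p, 5) == 0.0
        assert diversity_measures(p, 5).n_positions_used == 1


class TestTrueDiversity:
    def test_identical_sequences_zero(self):
        s = SequenceSet(["ACGT" * 25] * 8, ["clade1"] * 8, "ACGT" * 25)
        res = true_diversity(s)
        assert res.pi == 0.0 and res.maf == 0.0 and res.pvar == 0.0

    def test_single_difference(self):
        a = "A" * 100
        b = "C" + "A" * 99
        res = true_diversity(SequenceSet([a, b], ["x", "x"], a))
        assert res.pi == pytest.approx(0.01)

    def test_matches_pairwise_hamming_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(20):
            n, length = int(rng.integers(2, 9)), 60
            seqs = [
                "".join(rng.choice(list("ACGT"), length)) for _ in range(n)
            ]
            res = true_diversity(SequenceSet(seqs, ["x"] * n, seqs[0]))
            dists = [
                sum(a != b for a, b in zip(s1, s2)) / length
                for s1, s2 in itertools.combinations(seqs, 2)
            ]
            assert res.pi == pytest.approx(np.mean(dists))

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            true_diversity(SequenceSet(["ACGT"], ["x"], "ACGT"))


class TestCallSubstitutions:
    def test_alt_with_single_read_called(self):
        p = make_pileup([{"A": 4, "C": 1}], ref="A")
        subs = call_substitutions(p, 5)
        assert subs == [Substitution(0, "C")]

    def test_reference_only_empty(self):
        p = make_pileup([{"A": 9}, {"C": 8}], ref="AC")
        assert call_substitutions(p, 5) == []

    def test_low_coverage_position_excluded(self):
        p = make_pileup([{"A": 3, "C": 1}], ref="A")  # 4x < 5
        assert call_substitutions(p, 5) == []

    def test_two_alts_at_one_position_are_distinct(self):
        p = make_pileup([{"A": 4, "C": 1, "G": 1}], ref="A")
        assert call_substitutions(p, 5) == [
            Substitution(0, "C"),
            Substitution(0, "G"),
        ]


def placement(read_id, pos, mismatches):
    return Placement(
        read_id=read_id,
        pos=pos,
        strand="+",
        n_mismatch=len(mismatches),
        mismatches=tuple(
            (p, "ACGT".index(b)) for p, b in mismatches
        ),
    )


class TestPairwiseLinkage:
    def test_hand_worked_pair(self):
        # reads covering both sites: (both), (A only), (neither)
        # linkage = 1 / (1 + 0 + 1) = 0.5
        subs = [Substitution(2, "C"), Substitution(8, "G")]
        reads = ["A" * 10] * 3  # only lengths are used
        placements = [
            placement(0, 0, [(2, "C"), (8, "G")]),
            placement(1, 0, [(2, "C")]),
            placement(2, 0, []),
        ]
        table = pairwise_linkage(placements, reads, subs)
        assert table.mean_linkage == pytest.approx(0.5)
        assert table.pair_counts(0, 1) == (1, 1, 0)
        assert table.count_cocovering(0, 1) == 3

    def test_all_reads_carry_both(self):
        subs = [Substitution(1, "C"), Substitution(5, "T")]
        reads = ["A" * 10] * 2
        placements = [
            placement(0, 0, [(1, "C"), (5, "T")]),
            placement(1, 0, [(1, "C"), (5, "T")]),
        ]
        assert pairwise_linkage(placements, reads, subs).mean_linkage == 1.0

    def test_distant_pair_excluded(self):
        # no read spans both sites -> zero denominator -> pair excluded
        subs = [Substitution(2, "C"), Substitution(500, "G")]
        reads = ["A" * 10] * 2
        placements = [
            placement(0, 0, [(2, "C")]),
            placement(1, 495, [(500, "G")]),
        ]
        table = pairwise_linkage(placements, reads, subs)
        assert table.mean_linkage is None
        assert table.n_pairs_defined == 0

    def test_same_position_pair_skipped(self):
        subs = [Substitution(2, "C"), Substitution(2, "G")]
        reads = ["A" * 10] * 2
        placements = [
            placement(0, 0, [(2, "C")]),
            placement(1, 0, [(2, "G")]),
        ]
        assert pairwise_linkage(placements, reads, subs).n_pairs_defined == 0

    def test_fewer_than_two_substitutions_undefined(self):
        table = pairwise_linkage([], [], [Substitution(0, "C")])
        assert table.mean_linkage is None

    def brute_force(self, placements, reads, subs):
        """Triple loop over substitution pairs and reads."""
        carried = [
            {( p, "ACGT"[b]) for p, b in pl.mismatches} for pl in placements
        ]
        spans = [
            (pl.pos, pl.pos + len(reads[pl.read_id])) for pl in placements
        ]
        values = []
        for i, j in itertools.combinations(range(len(subs)), 2):
            if subs[i].position == subs[j].position:
                continue
            both = a_only = b_only = 0
            key_i = (subs[i].position, subs[i].alt_base)
            key_j = (subs[j].position, subs[j].alt_base)
            for c, (lo, hi) in zip(carried, spans):
                cov_i = lo <= subs[i].position < hi
                cov_j = lo <= subs[j].position < hi
                has_i, has_j = key_i in c, key_j in c
                if has_i and has_j:
                    both += 1
                elif has_i and cov_j:
                    a_only += 1
                elif has_j and cov_i:
                    b_only += 1
            if both + a_only + b_only:
                values.append(both / (both + a_only + b_only))
        return (float(np.mean(values)) if values else None), len(values)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(77)
        for trial in range(15):
            n_subs = int(rng.integers(2, 7))
            positions = rng.choice(60, size=n_subs, replace=False)
            subs = [
                Substitution(int(p), "ACGT"[int(rng.integers(1, 4))])
                for p in sorted(positions)
            ]
            reads = ["A" * 20] * 25
            placements = []
            for r in range(25):
                pos = int(rng.integers(0, 45))
                mism = []
                for s in subs:
                    if pos <= s.position < pos + 20 and rng.random() < 0.4:
                        mism.append((s.position, s.alt_base))
                placements.append(placement(r, pos, mism))
            table = pairwise_linkage(placements, reads, subs)
            expect_mean, expect_n = self.brute_force(placements, reads, subs)
            assert table.n_pairs_defined == expect_n
            if expect_mean is None:
                assert table.mean_linkage is None
            else:
                assert table.mean_linkage == pytest.approx(expect_mean)

    def test_pair_count_invariant(self):
        rng = np.random.default_rng(88)
        subs = [Substitution(5, "C"), Substitution(12, "G"), Substitution(30, "T")]
        reads = ["A" * 25] * 30
        placements = []
        for r in range(30):
            pos = int(rng.integers(0, 30))
            mism = [
                (s.position, s.alt_base)
                for s in subs
                if pos <= s.position < pos + 25 and rng.random() < 0.5
            ]
            placements.append(placement(r, pos, mism))
        table = pairwise_linkage(placements, reads, subs)
        for i, j in itertools.combinations(range(3), 2):
            both, a_only, b_only = table.pair_counts(i, j)
            assert both + a_only + b_only <= table.count_cocovering(i, j)
            link = table.pair_linkage(i, j)
            if link is not None:
                assert 0.0 <= link <= 1.0
                assert table.pair_linkage(j, i) == pytest.approx(link)
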