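# Methods

`ervdiff` asks a single question of a retroviral contig assembled from
short reads: does the population of sequences behind it look like an
endogenous retrovirus family (many old, diverged genomic copies) or like an
exogenous infection (a nearly clonal population with a very recent common
ancestor)? Because short reads cannot be phased into haplotypes, the
package works entirely with per-position allele counts obtained by mapping
the reads back onto the contig, plus one read-level co-occurrence
statistic. Everything needed to validate the approach is simulated; no
external data is required.

## The forward model

A clonal family is produced by repeated duplication of one ancestral
sequence. At each duplication both children are copied independently, each
site substituting with probability r to one of the three alternative bases
(uniformly). After G rounds the family holds 2^G sequences of identical
length; there are no indels, no recombination and no selection, so columns
align trivially and the genealogy is the complete binary tree of depth G.
The defaults G = 5 (32 sequences) and template lengths 3000/5000/8735 nt
define the package's standard study conditions.

Both children mutating independently is a modelling choice (one could
instead keep the parent copy pristine); it makes the family exchangeable
and gives clean closed forms. For two leaves whose most recent common
ancestor lies d duplications back, the expected per-site difference is

    E[d_pair] = 3/4 * (1 - (1 - 4r/3)^(2d)),

and averaging over the 496 leaf pairs of the depth-5 tree gives the
expected true diversity, ~8.3226 r in the small-r limit
(`expected_true_diversity`). Tests check the simulator against this
enumeration rather than against itself.

Co-infection by two related exogenous viruses is the same model with the
first duplication run at an *interclade* rate (the distance between the two
virus strains) and all later duplications at an *intraclade* rate (the
within-strain diversity). The first-round children found two labelled
clades of 16 sequences each.

## Read simulation

Fragments of a fixed 500 nt insert are drawn uniformly from uniformly
chosen templates; mate 1 reads the 5' end forward and mate 2 the 3' end
reverse-complemented (100 nt each, so the inner gap is 300 nt). Base-call
errors are independent per-base substitutions at rate 0 or 0.02 — the
post-filtering error level of short-read data. No quality model, indel
errors, GC bias or fragment-length jitter: the downstream statistics are
mismatch-based and never read qualities, and none of the validated claims
depend on those features. Read names and `ReadPair` fields carry the
template of origin, fragment start and true error positions so tests can
check against ground truth.

## Assembly

A minimal de Bruijn assembler (canonical 31-mers) stands in for a
production metagenome assembler. Contigs are maximal non-branching paths
after three graph-cleaning steps, iterated to a fixed point:

* **Abundance floor.** A k-mer is kept if its count reaches
  `max(min_count, 0.05 * c80)` where c80 is the 80th percentile of k-mer
  abundance weighted by instances — an estimate of backbone coverage. A
  fixed absolute floor cannot work across sequencing depths: at 400x the
  same base-call error recurs in 2–3 reads, while the smallest real
  haplotype class (1 template in 32) sits near 3% of coverage. The 5%
  fraction separates the two at any depth; at low depth the absolute
  `min_count = 2` dominates.
* **Tip clipping.** Dead-end stubs shorter than 2k whose coverage is under
  a quarter of the best continuing branch are removed (error k-mers that
  survive the floor truncate before rejoining the backbone, because the
  error sat near a read end).
* **Bubble (bulge) resolution.** A short unitig (<= 4k = 124 nt by
  default) whose two ends join junctions that are also connected by an
  alternative path of comparable coverage is deleted — first exactly
  parallel arms (identical attachment sets, keep the best covered), then
  single-edge arms whose alternative is found by a bounded depth-first
  search requiring every unitig on the path to carry at least half the
  arm's coverage. Candidates are processed in ascending coverage order and
  a deleted arm cannot serve as another arm's alternative, so the two arms
  of a 50/50 polymorphism can never both disappear. Iterating with
  recompaction resolves nested variant clusters inside-out, and the
  surviving path follows the locally dominant allele — a consensus.

The length bound is the scientifically load-bearing knob: parallel paths
longer than ~4k are *never* merged. When two clades diverge by a few
percent per site their k-mer paths stay separate for stretches much longer
than k between shared anchor windows, so the graph remains branched and
assembly fragments — exactly the contig-size collapse observed at
intermediate interclade rates — while isolated within-family polymorphisms
(arms ~2k) are merged, which is what lets a single-origin family at
moderate rates assemble into one full-length consensus. Raising the bound
would trade the second property against the first.

`attribute_contig` assigns a contig to the parental clade(s) it derives
from: non-overlapping 200 nt windows are aligned (ungapped, both strands)
against every parental sequence; a window votes for the clade of its best
match at >= 90% identity; >= 90% agreement names one clade, two clades
with >= 10% each is "both", no assignable window is "none".

## Mapping and the pileup

Reads are placed ungapped, end-to-end, on the best contig under a mismatch
budget of `floor(0.04 * read_length)` — 4 mismatches per 100 nt read,
the edit-distance fraction a default short-read mapper allows. The
simulators emit no indels, so ungapped placement is exact, and candidate
offsets found by pigeonhole seeding (seed length `L // (budget+1)`, capped
at 31 nt) provably reproduce the exhaustive all-offset scan; a property
test asserts this equality. Ties between co-optimal placements are broken
by a seeded uniform draw. Reads overhanging the contig end are unmapped
(no soft clipping), and mates are mapped independently.

The pileup counts only read bases (shape 4 x N); the contig's own
consensus base contributes no pseudo-count. Coordinates are 0-based
internally and 1-based in the emitted TSV.

## Statistics

With allele counts C_i and coverage n at a position, per-site diversity is
the unbiased pairwise-difference rate `(n/(n-1)) * (1 - sum (C_i/n)^2)`,
i.e. the fraction of mismatching unordered read-base pairs. Nucleotide
diversity, combined minor-allele frequency (1 minus the major-allele
frequency) and the proportion of variable sites are averaged over the
positions with coverage >= 5 (and a non-N reference); the same floor gates
substitution calling. Averaging MAF and variable-site fraction over
qualifying positions only (rather than all positions) is a choice, flagged
by the `min_cov` field every result carries. On the full parental
alignment the same formulas apply with every column at full depth and no
floor.

A substitution is a (position, alternative base) pair with any read
support at a qualifying position; two alternative bases at one position
are distinct substitutions and pairs within one position are skipped. For
substitutions A and B, each read covering both positions is classified as
carrying both, A only, B only (carrying = the aligned base equals that
exact alternative), and the pair's linkage is both/(A_only + B_only +
both); pairs with an empty denominator are dropped and the rest averaged.
Mates are independent observations, so co-coverage means both positions
within one mate's 100 nt span. Two clades of haplotypes push this mean up
because clade-diagnostic substitutions ride the same reads. The
accumulation is sparse-matrix based and is checked against a brute-force
triple loop in tests.

## Experiments and decision rule

`run_scenario` chains the whole pipeline per iteration; assembly failures
are recorded, not raised. Seeds derive from
`SeedSequence(master_seed, spawn_key=(scenario_index, iteration))`, so any
iteration is replayable alone and grid re-runs are bit-identical.
`run_grid` enumerates the 8 x 3 x 2 x 3 scenario design. The co-infection
grid spans interclade rates {0.005, 0.01, 0.02, 0.04, 0.06, 0.1, 0.25}
(the stated endpoints plus the discussed interior), with the intraclade
rate calibrated by log-space bisection so single-origin inferred diversity
lands at ~0.007 (+-20%), the level a chronic HIV infection — the most
diverse known exogenous retrovirus — shows. Calibration and the
co-infection grid use error-free reads: an 0.02 error rate imposes an
inferred-diversity floor near 0.036, far above the 0.007 target, so the
calibration criterion is only attainable without errors, and the
diversity range the co-infection study reports matches error-free
behaviour.

`compare_to_baseline` is a two-sided pooled-variance t-test with
Bonferroni correction (family size is an explicit argument — two-sided is
the conservative reading). `linkage_significance` is the plain empirical
fraction of null values <= observed, no smoothing, with the null count
reported so the 1/n resolution floor is visible. `classify` combines the
two: diversity significantly above the exogenous baseline *and* linkage
below the co-infection null is endogenous-like; diversity within baseline
is exogenous-like; anything else (including high diversity with
co-infection-compatible linkage) is indeterminate.

## Problem sizes and what the tests show

The acceptance-level tests run the study at 5000 nt / 10000 read pairs
with 20 iterations per scenario (the full design specifies 100; 20 keeps
the suite fast while medians and scenario means remain stable). At that scale the suite verifies: exact recovery of
the closed-form expected diversity; error-free inferred diversity within
10% of truth for substitution rates up to 1e-3; Spearman correlation
above 0.95 between inferred and true diversity/MAF across the whole rate
ladder at error 0.02; and the co-infection phenomenology (fragmentation at
intermediate interclade rates, halved coverage and single-clade contigs at
high rates, elevated linkage where contigs draw on both clades).

The 10% absolute-recovery claim is restricted to rates <= 1e-3 by
arithmetic, not convenience: at rate 5e-3 a typical read already differs
from the consensus at ~2.5 sites per 100 nt and at 1e-2 at ~5, so the
0.04 mapping budget censors exactly the divergent reads that carry the
diversity, and assembly itself splinters into subclade contigs. Inferred
diversity then saturates and under-reports — visibly in the package's own
grid output. Rank correlation survives this compression, absolute recovery
does not; any mapper with a fixed mismatch budget shares the effect.

Because the generator omits indels, recombination, quality-correlated
errors and uneven coverage, passing these tests shows that the inference
machinery is correct under the stated model, not that real libraries are
free of artefacts; on real data the mapping-budget saturation above and
reference bias of consensus mapping apply equally.

## Numerical and degenerate-input conventions

Measures over zero qualifying positions are None (undefined), never 0.
Major-allele ties break to the lexicographically smallest base; equal-best
placements by seeded draw; equal-length contigs to the lexicographically
smaller sequence; equal-coverage bubble arms by smallest first k-mer. A
zero-variance t-test returns p = 1 for equal means and a degenerate flag
with p = 0 otherwise. Empty read sets assemble to an empty contig list;
empty null sets and single-sequence alignments raise argument errors.
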