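"""Forward simulation of clonal sequence families.

The model: a single ancestral sequence is repeatedly duplicated; at each
duplication *both* children are independently copied with a per-site
substitution probability. A substituted site always takes one of the three
alternative bases (uniformly), so the rate is an exact per-site difference
probability per branch. There are no indels, so every sequence in a family
has the root's length and columns line up without alignment.

Two modes are supported:

* single origin — one substitution rate for every duplication round; after
  G rounds the family holds 2**G sequences. This emulates the sequence
  population of an endogenous retrovirus family of tunable age.
* co-infection — the first duplication uses a (typically large) interclade
  rate and founds two clades; all later duplications use the intraclade
  rate. This emulates two related exogenous viruses infecting one host.

For two leaves whose most recent common ancestor lies d duplications back,
the expected per-site difference under this model is
``3/4 * (1 - (1 - 4*r/3)**(2*d))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import decode, encode

__all__ = [
    "EvolutionParams",
    "SequenceSet",
    "random_root_sequence",
    "subset_sequence",
    "mutate_copy",
    "evolve_clone_family",
    "evolve_coinfection",
    "expected_pairwise_difference",
    "expected_true_diversity",
]


@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of one clonal-expansion simulation.

    substitution_rate
        Per-site substitution probability per duplication (single-origin
        mode; ignored by the co-infection mode).
    generations
        Number of duplication rounds; the family ends with ``2**generations``
        sequences.
    sequence_length
        Root length in nucleotides.
    interclade_rate / intraclade_rate
        Co-infection mode only: the per-site rate applied at the first
        duplication (founding the two clades) and at every later one.
    seed
        RNG seed; a fixed seed replays the simulation bit-identically.
    """

    substitution_rate: float = 0.0
    generations: int = 5
    sequence_length: int = 5000
    interclade_rate: Optional[float] = None
    intraclade_rate: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "interclade_rate", "intraclade_rate"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if (self.interclade_rate is None) != (self.intraclade_rate is None):
            raise ValueError(
                "interclade_rate and intraclade_rate must be set together"
            )

    @property
    def coinfection(self) -> bool:
        return self.interclade_rate is not None


@dataclass
class SequenceSet:
    """A clonal family: equal-length sequences with clade labels.

    ``lineage_paths`` records, per sequence, the child index taken at each
    duplication (e.g. ``"0.1.1.0.1"``), which identifies its leaf in the
    complete binary genealogy.
    """

    sequences: list[str]
    clade_labels: list[str]
    root: str
    lineage_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences} | {len(self.root)}) > 1:
            raise ValueError("all sequences must share the root's length")
        if len(self.clade_labels) != len(self.sequences):
            raise ValueError("one clade label per sequence required")

    def __len__(self) -> int:
        return len(self.sequences)

    def as_codes(self) -> np.ndarray:
        """Sequences as a (n_sequences, length) uint8 code matrix."""
        return np.vstack([encode(s) for s in self.sequences])

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.clade_labels:
            seen.setdefault(label, None)
        return list(seen)


def random_root_sequence(length: int, seed: Optional[int] = None) -> str:
    """Uniform i.i.d. A/C/G/T sequence of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def subset_sequence(seq: str, length: int) -> str:
    """Leading prefix of ``seq`` of the requested length."""
    if length > len(seq):
        raise ValueError(f"length {length} exceeds sequence length {len(seq)}")
    if length < 1:
        raise ValueError("length must be >= 1")
    return seq[:length]


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One mutated copy: each site substituted with probability ``rate`` to
    one of the 3 other bases uniformly."""
    child = codes.copy()
    if rate <= 0.0:
        return child
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
        child[hit] = (child[hit] + shift) % 4
    return child


def mutate_copy(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Copy ``seq`` with independent per-site substitution at ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    return decode(_mutate_codes(encode(seq), rate, rng))


def _expand(
    root_codes: np.ndarray,
    rates: Sequence[float],
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[str]]:
    """Duplicate every sequence once per listed rate, both children mutating
    independently; parent order then child order keeps replays identical."""
    population = [root_codes]
    paths = [""]
    for rate in rates:
        nxt: list[np.ndarray] = []
        nxt_paths: list[str] = []
        for codes, path in zip(population, paths):
            for child in (0, 1):
                nxt.append(_mutate_codes(codes, rate, rng))
                nxt_paths.append(f"{path}.{child}" if path else str(child))
        population = nxt
        paths = nxt_paths
    return population, paths


def evolve_clone_family(root: str, params: EvolutionParams) -> SequenceSet:
    """Single-origin clonal expansion of ``root`` under ``params``."""
    if params.coinfection:
        raise ValueError("co-infection rates set; use evolve_coinfection")
    codes = encode(root)
    if codes.size != params.sequence_length:
        raise ValueError("root length does not match params.sequence_length")
    rng = np.random.default_rng(params.seed)
    rates = [params.substitution_rate] * params.generations
    population, paths = _expand(codes, rates, rng)
    return SequenceSet(
        sequences=[decode(c) for c in population],
        clade_labels=["clade1"] * len(population),
        root=root,
        lineage_paths=paths,
    )


def evolve_coinfection(root: str, params: EvolutionParams) -> SequenceSet:
    """Two-clade expansion: the first duplication runs at the interclade
    rate and founds the clades; later duplications run at the intraclade
    rate. Labels follow the first-round child."""
    if not params.coinfection:
        raise ValueError("interclade_rate and intraclade_rate must be set")
    if params.generations < 1:
        raise ValueError("co-infection mode needs generations >= 1")
    codes = encode(root)
    if codes.size != params.sequence_length:
        raise ValueError("root length does not match params.sequence_length")
    rng = np.random.default_rng(params.seed)
    rates = [params.interclade_rate] + [params.intraclade_rate] * (
        params.generations - 1
    )
    population, paths = _expand(codes, rates, rng)
    labels = [f"clade{int(p.split('.')[0]) + 1}" for p in paths]
    return SequenceSet(
        sequences=[decode(c) for c in population],
        clade_labels=labels,
        root=root,
        lineage_paths=paths,
    )


def expected_pairwise_difference(rate: float, branch_generations: int) -> float:
    """Expected per-site difference between two sequences separated by the
    given number of mutating branches at per-branch substitution probability
    ``rate`` (uniform-to-3-alternatives model)."""
    return 0.75 * (1.0 - (1.0 - 4.0 * rate / 3.0) ** branch_generations)


def expected_true_diversity(rate: float, generations: int) -> float:
    """Expected mean pairwise per-site difference over all leaf pairs of the
    complete binary genealogy of the given depth: leaves whose MRCA lies d
    rounds back are separated by 2*d mutating branches."""
    n = 2**generations
    total = 0.0
    pairs = 0
    for d in range(1, generations + 1):
        # pairs whose MRCA is exactly d duplications back
        count = 2 ** (generations - d) * 2 ** (d - 1) * 2 ** (d - 1)
        total += count * expected_pairwise_difference(rate, 2 * d)
        pairs += count
    assert pairs == n * (n - 1) // 2
    return total / pairs
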