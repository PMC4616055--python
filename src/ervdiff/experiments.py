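"""Simulation studies: the scenario grid, true-vs-inferred comparison,
co-infection grids, read-set mixing, baseline tests and empirical linkage
significance.

Every scenario iteration runs the full chain: clonal evolution -> paired
read simulation -> de novo assembly -> longest contig -> read-back mapping
-> pileup statistics (and optionally the linkage statistic and a clade
attribution of the contig). Seeds are derived from a single master seed via
``numpy.random.SeedSequence(master_seed, spawn_key=(scenario_index,
iteration))`` so any iteration replays bit-identically in isolation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assemble import assemble_contigs, attribute_contig, longest_contig
from .evolve import (
    EvolutionParams,
    evolve_clone_family,
    evolve_coinfection,
    expected_true_diversity,
    random_root_sequence,
)
from .mapper import ReadMapper, build_pileup, coverage_summary
from .readsim import ReadSimParams, interleaved_reads, simulate_read_pairs
from .stats import (
    DiversityResult,
    call_substitutions,
    diversity_measures,
    pairwise_linkage,
    true_diversity,
)

__all__ = [
    "ScenarioSpec",
    "IterationResult",
    "ScenarioResult",
    "TABLE1_SUBSTITUTION_RATES",
    "TABLE1_SEQUENCE_LENGTHS",
    "TABLE1_ERROR_RATES",
    "TABLE1_READ_PAIRS",
    "DEFAULT_INTERCLADE_LADDER",
    "table1_axes",
    "scenario_specs",
    "run_scenario",
    "run_grid",
    "regress_true_vs_inferred",
    "run_coinfection_grid",
    "calibrate_intraclade_rate",
    "mix_read_sets",
    "compare_to_baseline",
    "linkage_significance",
    "classify",
]

# the standard simulation design: 8 x 3 x 2 x 3 = 144 scenarios
TABLE1_SUBSTITUTION_RATES = (0.0, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2)
TABLE1_SEQUENCE_LENGTHS = (3000, 5000, 8735)
TABLE1_ERROR_RATES = (0.0, 0.02)
TABLE1_READ_PAIRS = (100, 1000, 10000)

DEFAULT_INTERCLADE_LADDER = (0.005, 0.01, 0.02, 0.04, 0.06, 0.1, 0.25)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of a simulation grid. When ``interclade_rate`` and
    ``intraclade_rate`` are set the scenario is a co-infection run and
    ``substitution_rate`` is ignored."""

    substitution_rate: float
    sequence_length: int
    error_rate: float
    n_pairs: int
    iterations: int = 20
    generations: int = 5
    interclade_rate: Optional[float] = None
    intraclade_rate: Optional[float] = None
    read_length: int = 100
    insert_size: int = 500

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def coinfection(self) -> bool:
        return self.interclade_rate is not None


@dataclass(frozen=True)
class IterationResult:
    true: DiversityResult
    inferred: Optional[DiversityResult]
    assembled: bool
    contig_length: int = 0
    mean_coverage: float = 0.0
    n_min_cov_positions: int = 0
    n_mapped: int = 0
    mean_linkage: Optional[float] = None
    attribution: Optional[str] = None


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    iterations: list[IterationResult] = field(default_factory=list)

    def _mean(self, values: list[Optional[float]]) -> Optional[float]:
        vals = [v for v in values if v is not None]
        return float(np.mean(vals)) if vals else None

    def mean_true(self, measure: str = "pi") -> Optional[float]:
        return self._mean([getattr(it.true, measure) for it in self.iterations])

    def mean_inferred(self, measure: str = "pi") -> Optional[float]:
        return self._mean(
            [
                getattr(it.inferred, measure)
                for it in self.iterations
                if it.inferred is not None
            ]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, it in enumerate(self.iterations):
            rows.append(
                {
                    "iteration": i,
                    "true_pi": it.true.pi,
                    "true_maf": it.true.maf,
                    "true_pvar": it.true.pvar,
                    "inferred_pi": it.inferred.pi if it.inferred else None,
                    "inferred_maf": it.inferred.maf if it.inferred else None,
                    "inferred_pvar": it.inferred.pvar if it.inferred else None,
                    "assembled": it.assembled,
                    "contig_length": it.contig_length,
                    "mean_coverage": it.mean_coverage,
                    "n_min_cov_positions": it.n_min_cov_positions,
                    "n_mapped": it.n_mapped,
                    "mean_linkage": it.mean_linkage,
                    "attribution": it.attribution,
                }
            )
        return pd.DataFrame(rows)


def table1_axes() -> dict[str, tuple]:
    return {
        "substitution_rate": TABLE1_SUBSTITUTION_RATES,
        "sequence_length": TABLE1_SEQUENCE_LENGTHS,
        "error_rate": TABLE1_ERROR_RATES,
        "n_pairs": TABLE1_READ_PAIRS,
    }


def scenario_specs(
    axes: Optional[dict[str, tuple]] = None, iterations: int = 20
) -> list[ScenarioSpec]:
    """Cartesian product of the grid axes, in axis order."""
    axes = axes or table1_axes()
    for key in ("substitution_rate", "sequence_length", "error_rate", "n_pairs"):
        if key not in axes or not len(axes[key]):
            raise ValueError(f"axis {key!r} missing or empty")
    return [
        ScenarioSpec(
            substitution_rate=r,
            sequence_length=s,
            error_rate=e,
            n_pairs=n,
            iterations=iterations,
        )
        for r, s, e, n in itertools.product(
            axes["substitution_rate"],
            axes["sequence_length"],
            axes["error_rate"],
            axes["n_pairs"],
        )
    ]


def _iteration_seeds(master_seed: int, scenario_index: int, iteration: int):
    ss = np.random.SeedSequence(
        master_seed, spawn_key=(scenario_index, iteration)
    )
    return ss.spawn(4)  # root, evolution, reads, mapper


def run_scenario(
    spec: ScenarioSpec,
    master_seed: int = 0,
    scenario_index: int = 0,
    *,
    compute_linkage: bool = False,
    attribute: bool = False,
    min_cov: int = 5,
    k: int = 31,
    min_count: int = 2,
    max_mismatch_frac: float = 0.04,
) -> ScenarioResult:
    """Run the full chain ``spec.iterations`` times; assembly failures are
    recorded (not raised) and carry no inferred measures."""
    result = ScenarioResult(spec=spec)
    for it in range(spec.iterations):
        s_root, s_evo, s_reads, s_map = _iteration_seeds(
            master_seed, scenario_index, it
        )
        root = random_root_sequence(spec.sequence_length, seed=s_root)
        eparams = EvolutionParams(
            substitution_rate=spec.substitution_rate,
            generations=spec.generations,
            sequence_length=spec.sequence_length,
            interclade_rate=spec.interclade_rate,
            intraclade_rate=spec.intraclade_rate,
            seed=s_evo,
        )
        if spec.coinfection:
            seqset = evolve_coinfection(root, eparams)
        else:
            seqset = evolve_clone_family(root, eparams)
        truth = true_diversity(seqset)
        pairs = simulate_read_pairs(
            seqset,
            ReadSimParams(
                n_pairs=spec.n_pairs,
                read_length=spec.read_length,
                insert_size=spec.insert_size,
                error_rate=spec.error_rate,
                seed=s_reads,
            ),
        )
        reads = interleaved_reads(pairs)
        contigs = assemble_contigs(reads, k=k, min_count=min_count)
        contig = longest_contig(contigs)
        if contig is None:
            result.iterations.append(
                IterationResult(true=truth, inferred=None, assembled=False)
            )
            continue
        mapper = ReadMapper(contig, max_mismatch_frac, seed=s_map)
        placements = mapper.map_all(reads)
        pileup = build_pileup(placements, reads, contig)
        inferred = diversity_measures(pileup, min_cov=min_cov)
        mean_cov, n_qual = coverage_summary(pileup, min_cov=min_cov)
        linkage = None
        if compute_linkage:
            subs = call_substitutions(pileup, min_cov=min_cov)
            linkage = pairwise_linkage(placements, reads, subs).mean_linkage
        attribution = None
        if attribute:
            attribution = attribute_contig(contig, seqset)
        result.iterations.append(
            IterationResult(
                true=truth,
                inferred=inferred,
                assembled=True,
                contig_length=len(contig.sequence),
                mean_coverage=mean_cov,
                n_min_cov_positions=n_qual,
                n_mapped=sum(pl is not None for pl in placements),
                mean_linkage=linkage,
                attribution=attribution,
            )
        )
    return result


def run_grid(
    axes: Optional[dict[str, tuple]] = None,
    iterations: int = 20,
    master_seed: int = 0,
    **scenario_kwargs,
) -> list[ScenarioResult]:
    """One ScenarioResult per cell of the Cartesian product of the axes."""
    specs = scenario_specs(axes, iterations)
    return [
        run_scenario(spec, master_seed, scenario_index=i, **scenario_kwargs)
        for i, spec in enumerate(specs)
    ]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_scenarios: int


def regress_true_vs_inferred(
    results: Sequence[ScenarioResult], measure: str = "pi"
) -> Optional[RegressionResult]:
    """OLS of scenario-mean inferred (y) on scenario-mean true (x);
    None when fewer than 3 usable scenarios or x has zero variance."""
    xs, ys = [], []
    for res in results:
        x = res.mean_true(measure)
        y = res.mean_inferred(measure)
        if x is not None and y is not None:
            xs.append(x)
            ys.append(y)
    if len(xs) < 3 or np.var(xs) == 0.0:
        return None
    fit = sps.linregress(xs, ys)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_scenarios=len(xs),
    )


def run_coinfection_grid(
    interclade_rates: Sequence[float],
    intraclade_rate: float,
    base_spec: Optional[ScenarioSpec] = None,
    master_seed: int = 0,
    **scenario_kwargs,
) -> dict[float, ScenarioResult]:
    """Co-infection scenarios across an interclade-rate ladder with linkage
    and contig clade attribution recorded."""
    if base_spec is None:
        base_spec = ScenarioSpec(
            substitution_rate=0.0,
            sequence_length=5000,
            error_rate=0.0,
            n_pairs=10000,
        )
    out: dict[float, ScenarioResult] = {}
    for i, rate in enumerate(interclade_rates):
        spec = replace(
            base_spec, interclade_rate=rate, intraclade_rate=intraclade_rate
        )
        out[rate] = run_scenario(
            spec,
            master_seed,
            scenario_index=1000 + i,
            compute_linkage=True,
            attribute=True,
            **scenario_kwargs,
        )
    return out


def calibrate_intraclade_rate(
    target_pi: float = 0.007,
    replicates: int = 10,
    tolerance: float = 0.2,
    master_seed: int = 0,
    sequence_length: int = 5000,
    n_pairs: int = 10000,
    max_steps: int = 12,
) -> float:
    """Bisection for the substitution rate at which a single-origin run
    infers nucleotide diversity ~= ``target_pi`` (relative tolerance
    ``tolerance``), using error-free reads so inference tracks truth."""

    def inferred_pi(rate: float) -> float:
        spec = ScenarioSpec(
            substitution_rate=rate,
            sequence_length=sequence_length,
            error_rate=0.0,
            n_pairs=n_pairs,
            iterations=replicates,
        )
        res = run_scenario(spec, master_seed, scenario_index=9000)
        value = res.mean_inferred("pi")
        return value if value is not None else 0.0

    # analytic first guess: expected true diversity is ~8.32 * rate at G=5
    guess = target_pi / expected_true_diversity(1.0e-6, 5) * 1.0e-6
    lo, hi = guess / 4.0, guess * 4.0
    while inferred_pi(hi) < target_pi and hi < 0.5:
        hi *= 2.0
    while inferred_pi(lo) > target_pi and lo > 1e-8:
        lo /= 2.0
    rate = guess
    for _ in range(max_steps):
        rate = math.sqrt(lo * hi)  # bisect in log space
        value = inferred_pi(rate)
        if abs(value - target_pi) <= tolerance * target_pi:
            return rate
        if value < target_pi:
            lo = rate
        else:
            hi = rate
    return rate


def mix_read_sets(
    reads_a: Sequence[str],
    reads_b: Sequence[str],
    proportion: float,
    seed: Optional[int] = None,
) -> list[str]:
    """Subsample ``proportion`` of set A and ``1 - proportion`` of set B,
    concatenate and shuffle deterministically."""
    if not reads_a or not reads_b:
        raise ValueError("both read sets must be non-empty")
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_a = round(proportion * len(reads_a))
    n_b = round((1.0 - proportion) * len(reads_b))
    pick_a = rng.choice(len(reads_a), size=n_a, replace=False)
    pick_b = rng.choice(len(reads_b), size=n_b, replace=False)
    merged = [reads_a[i] for i in pick_a] + [reads_b[i] for i in pick_b]
    order = rng.permutation(len(merged))
    return [merged[i] for i in order]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    p_bonferroni: float
    degenerate: bool = False


def compare_to_baseline(
    sample_values: Sequence[float],
    baseline_values: Sequence[float],
    n_tests: int = 1,
) -> TTestResult:
    """Two-sided equal-variance (pooled) two-sample t-test with a
    Bonferroni-corrected p over ``n_tests`` comparisons."""
    a = np.asarray(sample_values, dtype=float)
    b = np.asarray(baseline_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    pooled = np.var(a, ddof=1) + np.var(b, ddof=1)
    if pooled == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, 1.0, degenerate=False)
        return TTestResult(math.inf, 0.0, 0.0, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), min(1.0, n_tests * float(p)))


@dataclass(frozen=True)
class EmpiricalP:
    p: float
    n_null: int


def linkage_significance(
    observed: float, null_values: Sequence[float]
) -> EmpiricalP:
    """Empirical significance of an observed mean linkage against simulated
    co-infection nulls: the fraction of null values <= observed (no
    smoothing; the resolution floor is 1 / n_null)."""
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ValueError("null set must be non-empty")
    return EmpiricalP(
        p=float(np.count_nonzero(nulls <= observed)) / nulls.size,
        n_null=int(nulls.size),
    )


@dataclass(frozen=True)
class Classification:
    verdict: str  # endogenous-like | exogenous-like | indeterminate
    diversity_test: Optional[TTestResult]
    linkage_p: Optional[float]
    reason: str


def classify(
    sample_values: Sequence[float],
    baseline_values: Sequence[float],
    linkage_p: Optional[float],
    n_tests: int = 1,
    alpha: float = 0.05,
) -> Classification:
    """Two-step verdict: endogenous-like iff per-replicate diversity
    significantly exceeds the exogenous baseline (Bonferroni p < alpha)
    AND the observed linkage is lower than the co-infection null
    (empirical p < alpha); exogenous-like iff diversity sits within the
    baseline; indeterminate otherwise (e.g. high diversity but linkage
    consistent with co-infection)."""
    if any(v is None for v in sample_values):
        return Classification(
            "indeterminate", None, linkage_p, "undefined diversity values"
        )
    test = compare_to_baseline(sample_values, baseline_values, n_tests)
    exceeds = (
        test.p_bonferroni < alpha
        and float(np.mean(sample_values)) > float(np.mean(baseline_values))
    )
    if not exceeds:
        return Classification(
            "exogenous-like", test, linkage_p, "diversity within baseline"
        )
    if linkage_p is not None and linkage_p < alpha:
        return Classification(
            "endogenous-like",
            test,
            linkage_p,
            "diversity above baseline; linkage below co-infection null",
        )
    return Classification(
        "indeterminate",
        test,
        linkage_p,
        "diversity above baseline but linkage consistent with co-infection",
    )
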