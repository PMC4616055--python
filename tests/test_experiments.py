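"""Orchestration: grids, regression, baseline tests, mixing, verdicts."""

import numpy as np
import pytest

from ervdiff import (
    ScenarioSpec,
    classify,
    compare_to_baseline,
    linkage_significance,
    mix_read_sets,
    regress_true_vs_inferred,
    run_scenario,
    scenario_specs,
    table1_axes,
)
from ervdiff.experiments import ScenarioResult, IterationResult
from ervdiff.stats import DiversityResult


def small_spec(**kw):
    base = dict(
        substitution_rate=1e-3,
        sequence_length=800,
        error_rate=0.0,
        n_pairs=200,
        iterations=2,
    )
    base.update(kw)
    return ScenarioSpec(**base)


class TestGrid:
    def test_full_axes_cardinality(self):
        specs = scenario_specs(table1_axes(), iterations=1)
        assert len(specs) == 144

    def test_small_axes_product(self):
        axes = {
            "substitution_rate": (0.0, 1e-3),
            "sequence_length": (800,),
            "error_rate": (0.0,),
            "n_pairs": (100,),
        }
        assert len(scenario_specs(axes, iterations=1)) == 2

    def test_missing_axis_rejected(self):
        with pytest.raises(ValueError):
            scenario_specs({"substitution_rate": (0.0,)}, iterations=1)


class TestRunScenario:
    def test_zero_rate_zero_inferred(self):
        res = run_scenario(small_spec(substitution_rate=0.0), master_seed=3)
        for it in res.iterations:
            assert it.assembled
            assert it.inferred.pi == 0.0

    def test_deterministic_replay(self):
        spec = small_spec()
        a = run_scenario(spec, master_seed=4).to_dataframe()
        b = run_scenario(spec, master_seed=4).to_dataframe()
        assert a.equals(b)

    def test_iterations_isolated_by_seed(self):
        # different master seeds give different evolved sets
        a = run_scenario(small_spec(), master_seed=5)
        b = run_scenario(small_spec(), master_seed=6)
        assert a.to_dataframe()["true_pi"].tolist() != b.to_dataframe()[
            "true_pi"
        ].tolist()


def fake_results(points):
    """ScenarioResults carrying fixed (true, inferred) pi means."""
    out = []
    for x, y in points:
        res = ScenarioResult(spec=small_spec())
        res.iterations.append(
            IterationResult(
                true=DiversityResult(x, x, x, 10, 0),
                inferred=DiversityResult(y, y, y, 10, 5),
                assembled=True,
            )
        )
        out.append(res)
    return out


class TestRegression:
    def test_exact_linear_fixture(self):
        fit = regress_true_vs_inferred(
            fake_results([(0.0, 1.0), (1.0, 3.0), (2.0, 5.0)])
        )
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_inferred_zero_slope(self):
        fit = regress_true_vs_inferred(
            fake_results([(0.0, 2.0), (1.0, 2.0), (2.0, 2.0)])
        )
        assert fit.slope == pytest.approx(0.0)

    def test_degenerate_x_flagged(self):
        assert (
            regress_true_vs_inferred(
                fake_results([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])
            )
            is None
        )


class TestCompareToBaseline:
    def test_identical_groups(self):
        res = compare_to_baseline([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # pooled variance 5/3, se = sqrt(5/6), t = -2/0.9129 = -2.1909, df 6
        res = compare_to_baseline([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.t == pytest.approx(-2.1909, abs=1e-4)
        assert res.p == pytest.approx(0.0708, abs=1e-3)

    def test_bonferroni_capped_at_one(self):
        res = compare_to_baseline([1, 2, 3, 4], [3, 4, 5, 6], n_tests=100)
        assert res.p_bonferroni == 1.0

    def test_degenerate_zero_variance(self):
        res = compare_to_baseline([2.0, 2.0], [5.0, 5.0])
        assert res.degenerate and res.p == 0.0

    def test_groups_too_small(self):
        with pytest.raises(ValueError):
            compare_to_baseline([1.0], [2.0, 3.0])


class TestLinkageSignificance:
    def test_observed_above_all_nulls(self):
        res = linkage_significance(0.9, [0.1] * 50)
        assert res.p == 1.0 and res.n_null == 50

    def test_fraction_below(self):
        nulls = [0.01, 0.02, 0.03] + [0.5] * 97
        assert linkage_significance(0.04, nulls).p == pytest.approx(0.03)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            linkage_significance(0.5, [])


class TestMixReadSets:
    def test_half_and_half_counts(self):
        a = [f"A{i}" for i in range(1000)]
        b = [f"B{i}" for i in range(1000)]
        merged = mix_read_sets(a, b, 0.5, seed=9)
        assert len(merged) == 1000
        assert sum(r.startswith("A") for r in merged) == 500

    def test_self_mix_preserves_composition(self):
        a = ["AAA", "CCC", "GGG", "TTT"] * 100
        merged = mix_read_sets(a, a, 0.5, seed=10)
        assert len(merged) == 400
        assert abs(merged.count("AAA") - 100) <= 30

    def test_deterministic(self):
        a = [f"A{i}" for i in range(100)]
        b = [f"B{i}" for i in range(100)]
        assert mix_read_sets(a, b, 0.3, seed=1) == mix_read_sets(a, b, 0.3, seed=1)

    def test_validation(self):
        with pytest.raises(ValueError):
            mix_read_sets([], ["A"], 0.5)
        with pytest.raises(ValueError):
            mix_read_sets(["A"], ["C"], 1.5)

    def test_mixed_clades_elevate_diversity_on_one_consensus(self):
        # reads from a related strain mapped onto the other strain's contig
        # add within-budget mismatches, inflating inferred diversity
        from ervdiff import (
            EvolutionParams,
            ReadMapper,
            ReadSimParams,
            assemble_contigs,
            build_pileup,
            diversity_measures,
            evolve_clone_family,
            longest_contig,
            mutate_copy,
            random_root_sequence,
            simulate_read_pairs,
        )
        from ervdiff.readsim import interleaved_reads

        rng = np.random.default_rng(30)
        root = random_root_sequence(800, seed=31)
        other_root = mutate_copy(root, 0.02, rng)

        def family_reads(r, seed):
            fam = evolve_clone_family(
                r,
                EvolutionParams(
                    substitution_rate=5e-4,
                    generations=3,
                    sequence_length=800,
                    seed=seed,
                ),
            )
            pairs = simulate_read_pairs(
                fam, ReadSimParams(n_pairs=600, seed=seed + 1)
            )
            return interleaved_reads(pairs)

        reads_a = family_reads(root, 32)
        reads_b = family_reads(other_root, 34)
        contig = longest_contig(assemble_contigs(reads_a))
        mapper = ReadMapper(contig, seed=36)

        def inferred_pi(reads):
            placements = mapper.map_all(reads)
            pileup = build_pileup(placements, reads, contig)
            return diversity_measures(pileup, 5).pi

        mixed = mix_read_sets(reads_a, reads_b, 0.5, seed=37)
        assert inferred_pi(mixed) > inferred_pi(reads_a)


class TestClassify:
    baseline = [0.006, 0.007, 0.0065, 0.0072]

    def test_high_diversity_low_linkage_endogenous(self):
        verdict = classify(
            [0.05, 0.055, 0.048, 0.052], self.baseline, linkage_p=0.01
        )
        assert verdict.verdict == "endogenous-like"

    def test_diversity_within_baseline_exogenous(self):
        verdict = classify(
            [0.0068, 0.0066, 0.007, 0.0071], self.baseline, linkage_p=0.01
        )
        assert verdict.verdict == "exogenous-like"

    def test_high_diversity_but_coinfection_like_linkage(self):
        verdict = classify(
            [0.05, 0.055, 0.048, 0.052], self.baseline, linkage_p=0.5
        )
        assert verdict.verdict == "indeterminate"

    def test_undefined_diversity_indeterminate(self):
        verdict = classify([None, 0.05], self.baseline, linkage_p=0.01)
        assert verdict.verdict == "indeterminate"
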