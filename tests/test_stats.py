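"""Cohort summaries and the shuffle-and-resample machinery, validated
against exact enumeration."""

import itertools

import numpy as np
import pytest

import fatemap as fm
from fatemap.records import GLIA, NEURON
from fatemap.stats import (
    ORACLE_MAX_VALUES,
    _resampled_means,
    exact_permutation_oracle,
    percent_of_constitutive,
    resampling_test,
    soma_area_comparison,
    summarize_cohort,
)
from fatemap.synth import ConditionSpec


class TestSummaries:
    def test_mean_and_sample_sd(self):
        design = fm.CohortDesign(
            (ConditionSpec("inducible", "E9.5", 0, 0, 0, 0),), 3)
        cohort = fm.generate_cohort(design, seed=0)
        cohort.animals = [
            a.__class__(a.animal_id, a.genotype, a.tamoxifen_day, n, 10)
            for a, n in zip(cohort.animals, (59, 63, 67))
        ]
        s = [x for x in summarize_cohort(cohort) if x.cell_class == NEURON][0]
        assert s.mean == pytest.approx(63)
        assert s.sd == pytest.approx(4)

    def test_constant_counts(self):
        design = fm.CohortDesign(
            (ConditionSpec("constitutive", "none", 63, 0, 63, 0),), 3)
        s = summarize_cohort(fm.generate_cohort(design, seed=1))[0]
        assert (s.mean, s.sd) == (63.0, 0.0)

    def test_sd_zero_cohort_means_equal_design(self, reference_design):
        design = fm.CohortDesign(
            tuple(
                ConditionSpec(c.genotype, c.tamoxifen_day,
                              c.neuron_count_mean, 0, c.glia_count_mean, 0)
                for c in reference_design.conditions),
            3)
        for s in summarize_cohort(fm.generate_cohort(design, seed=2)):
            cond = next(c for c in design.conditions
                        if (c.genotype, c.tamoxifen_day)
                        == (s.genotype, s.tamoxifen_day))
            nominal = (cond.neuron_count_mean if s.cell_class == NEURON
                       else cond.glia_count_mean)
            assert s.mean == nominal

    def test_percentages_relative_to_constitutive(self, reference_design):
        design = fm.CohortDesign(
            tuple(ConditionSpec(c.genotype, c.tamoxifen_day,
                                c.neuron_count_mean, 0, c.glia_count_mean, 0)
                  for c in reference_design.conditions), 3)
        summaries = summarize_cohort(fm.generate_cohort(design, seed=3))
        by_key = {(s.tamoxifen_day, s.cell_class): s for s in summaries}
        assert by_key[("none", NEURON)].pct_of_constitutive == 100.0
        assert by_key[("E9.5", NEURON)].pct_of_constitutive == pytest.approx(
            100 * 63 / 70)
        assert by_key[("E7.5", NEURON)].pct_of_constitutive == pytest.approx(
            100 * 23 / 70)


class TestPercent:
    @pytest.mark.parametrize("num,den,expected",
                             [(26, 70, 37.142857), (70, 70, 100.0),
                              (23, 70, 32.857142)])
    def test_values(self, num, den, expected):
        assert percent_of_constitutive(num, den) == pytest.approx(expected)

    def test_bad_reference(self):
        with pytest.raises(ValueError):
            percent_of_constitutive(10, 0)


class TestResampling:
    def test_no_variation_collapses(self):
        counts = {d: [30, 30, 30] for d in ("E7.5", "E8.5", "E9.5",
                                            "E10.5", "E11.5")}
        r = resampling_test(counts, n_resamples=500, seed=0)
        for d in counts:
            assert r.ci_lower[d] == r.ci_upper[d] == 30
            assert not r.significant_high[d] and not r.significant_low[d]
            assert r.empirical_p[d] == 1.0

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError):
            resampling_test({"a": [1, 2], "b": [3]}, 100)
        with pytest.raises(ValueError):
            resampling_test({"a": [1, 2]}, 100)

    def test_conservation_every_resample(self):
        """Every resample redistributes exactly the pooled multiset
        (checked inside the permutation kernel)."""
        counts = {"a": [1, 2, 3], "b": [9, 9, 10]}
        resampling_test(counts, n_resamples=200, seed=1,
                        _check_conservation=True)

    def test_exchangeability_across_days(self, reference_neuron_counts):
        """Under full shuffling the per-day null distributions are
        identical; the per-day CI bounds differ only by Monte-Carlo
        noise."""
        cohort = fm.generate_cohort(seed=4)
        r = resampling_test(cohort.counts_by_day(NEURON),
                            n_resamples=20_000, seed=5)
        lo = list(r.ci_lower.values())
        hi = list(r.ci_upper.values())
        spread = np.ptp(list(r.per_day_observed_mean.values()))
        assert np.ptp(lo) < 0.15 * spread
        assert np.ptp(hi) < 0.15 * spread

    def test_determinism(self):
        counts = {"a": [1, 5, 3], "b": [9, 2, 10]}
        a = resampling_test(counts, 1000, seed=6)
        b = resampling_test(counts, 1000, seed=6)
        assert a.to_dict() == b.to_dict()


class TestExactOracle:
    def test_two_singletons(self):
        dist = exact_permutation_oracle({"a": [1], "b": [2]})
        for day in ("a", "b"):
            means, probs = dist[day]
            assert list(means) == [1, 2]
            assert list(probs) == [0.5, 0.5]

    def test_six_splits_of_four_values(self):
        """Groups of 2 from {1, 2, 9, 10}: six equally likely splits whose
        group-mean distribution was computed by hand."""
        dist = exact_permutation_oracle({"a": [1, 2], "b": [9, 10]})
        means, probs = dist["a"]
        assert list(means) == [1.5, 5.0, 5.5, 6.0, 9.5]
        assert list(probs) == pytest.approx([1/6, 1/6, 2/6, 1/6, 1/6])
        # symmetry: both groups share the same null distribution
        means_b, probs_b = dist["b"]
        assert list(means_b) == list(means)
        assert list(probs_b) == pytest.approx(list(probs))

    def test_support_bounds_are_extreme_assignments(self):
        counts = {"a": [4, 1, 7], "b": [2, 2, 6]}
        pooled = sorted(v for g in counts.values() for v in g)
        dist = exact_permutation_oracle(counts)
        for day in counts:
            means, probs = dist[day]
            assert means[0] == pytest.approx(np.mean(pooled[:3]))
            assert means[-1] == pytest.approx(np.mean(pooled[-3:]))
            assert probs.sum() == pytest.approx(1.0)

    def test_size_guard(self):
        big = {"a": list(range(7)), "b": list(range(7))}
        assert sum(len(v) for v in big.values()) > ORACLE_MAX_VALUES
        with pytest.raises(ValueError):
            exact_permutation_oracle(big)

    def test_monte_carlo_converges_to_exact(self):
        """CDF sup-norm between Monte-Carlo resampled means and the exact
        enumeration shrinks below 0.02 at 100k resamples."""
        counts = {"a": [1, 2, 9], "b": [10, 4, 6]}
        dist = exact_permutation_oracle(counts)
        pooled = np.array([v for g in counts.values() for v in g], float)
        rng = np.random.default_rng(7)
        rm = _resampled_means(pooled, 2, 3, 100_000, rng)
        for di, day in enumerate(counts):
            means, probs = dist[day]
            exact_cdf = np.cumsum(probs)
            emp_cdf = np.array([(rm[:, di] <= m + 1e-9).mean()
                                for m in means])
            assert np.max(np.abs(emp_cdf - exact_cdf)) < 0.02


class TestSomaAreaComparison:
    def test_identical_groups(self):
        assert soma_area_comparison([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_reference_sample_sizes_highly_significant(self, area_model):
        """n = 37 neurons vs n = 34 glia from the default model separate
        at P < 0.0001."""
        areas = fm.generate_soma_areas(37, 34, area_model, seed=8)
        neurons = [a for a, c in areas if c == NEURON]
        glia = [a for a, c in areas if c == GLIA]
        t, p = soma_area_comparison(neurons, glia)
        assert t > 0
        assert p < 1e-4

    def test_matches_exact_permutation_p_small_n(self):
        """On n = 4 + 4, the pooled-variance t-test P tracks the exact
        permutation P of the mean difference."""
        a = [310.0, 402.0, 355.0, 389.0]
        b = [95.0, 120.0, 88.0, 140.0]
        _, p_t = soma_area_comparison(a, b, equal_var=True)
        pooled = a + b
        obs = abs(np.mean(a) - np.mean(b))
        hits = total = 0
        for idx in itertools.combinations(range(8), 4):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(8) if i not in idx]
            if abs(np.mean(ga) - np.mean(gb)) >= obs - 1e-9:
                hits += 1
            total += 1
        p_perm = hits / total
        assert abs(p_t - p_perm) < 0.1

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            soma_area_comparison([1.0], [2.0, 3.0])
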