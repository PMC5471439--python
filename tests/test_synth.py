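"""Generator contracts: seeded determinism, truncation bounds, and
recovery of the design parameters by the generated data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fatemap as fm
from fatemap.records import GLIA, NEURON
from fatemap.synth import CellSpec, ConditionSpec


class TestSomaAreas:
    def test_empty(self, area_model):
        assert fm.generate_soma_areas(0, 0, area_model, seed=1) == []

    def test_negative_counts_rejected(self, area_model):
        with pytest.raises(ValueError):
            fm.generate_soma_areas(-1, 0, area_model, seed=1)

    def test_truncation_bounds_and_separation(self, area_model):
        areas = fm.generate_soma_areas(500, 500, area_model, seed=7)
        neurons = [a for a, c in areas if c == NEURON]
        glia = [a for a, c in areas if c == GLIA]
        assert min(neurons) >= area_model.neuron_floor
        assert max(glia) <= area_model.glia_ceiling
        assert all(g > 0 for g in glia)
        # non-overlap: every neuron soma larger than every glial soma
        assert max(glia) < min(neurons)

    def test_achieved_means_match_nominal(self, area_model):
        """Despite truncation, the achieved class means stay within 2% of
        the nominal 389 / 88 um^2 (location recalibration)."""
        areas = fm.generate_soma_areas(10_000, 10_000, area_model, seed=3)
        neurons = np.array([a for a, c in areas if c == NEURON])
        glia = np.array([a for a, c in areas if c == GLIA])
        assert abs(neurons.mean() - 389) / 389 < 0.02
        assert abs(glia.mean() - 88) / 88 < 0.02

    def test_determinism(self, area_model):
        a = fm.generate_soma_areas(50, 50, area_model, seed=11)
        b = fm.generate_soma_areas(50, 50, area_model, seed=11)
        assert a == b

    def test_overlapping_model_rejected(self):
        with pytest.raises(ValueError):
            fm.AreaModel(neuron_floor=150, glia_ceiling=160)


class TestCohort:
    def test_sd_zero_gives_rounded_means(self):
        design = fm.CohortDesign(
            (ConditionSpec("inducible", "E9.5", 63.4, 0, 42, 0),), 3)
        cohort = fm.generate_cohort(design, seed=5)
        assert [a.neuron_count for a in cohort] == [63, 63, 63]
        assert [a.glia_count for a in cohort] == [42, 42, 42]

    def test_determinism(self, reference_design):
        a = fm.generate_cohort(reference_design, seed=9)
        b = fm.generate_cohort(reference_design, seed=9)
        assert a.animals == b.animals

    def test_counts_nonnegative_even_for_tiny_means(self):
        """mean - 3 sd < 0 must still give integer counts >= 0."""
        design = fm.CohortDesign(
            (ConditionSpec("inducible", "E11.5", 1, 5, 2, 8),), 50)
        cohort = fm.generate_cohort(design, seed=13)
        assert all(a.neuron_count >= 0 and a.glia_count >= 0 for a in cohort)

    def test_sample_means_track_design_means(self, reference_design):
        """Monte-Carlo check of the generator against its own parameters:
        per-condition sample means fall within 3 sd/sqrt(3) of the design
        means in >= 99% of seeds."""
        ok = total = 0
        for seed in range(1000):
            cohort = fm.generate_cohort(reference_design, seed=seed)
            hit = True
            for cond in reference_design.conditions:
                counts = cohort.counts_for(cond.genotype, cond.tamoxifen_day,
                                           NEURON)
                bound = 3 * cond.neuron_count_sd / np.sqrt(3) + 0.5  # rounding
                if abs(np.mean(counts) - cond.neuron_count_mean) > bound:
                    hit = False
            ok += hit
            total += 1
        assert ok / total >= 0.99

    def test_large_cohort_recovers_design_means(self, reference_design):
        """Generator/analysis closure: summaries of a 300-animal-per-
        condition cohort sit on the design means up to sampling error
        (4 standard errors, including the rounding variance of 1/12),
        i.e. the generator is unbiased."""
        n = 300
        design = fm.CohortDesign(reference_design.conditions, n)
        cohort = fm.generate_cohort(design, seed=21)
        for s in fm.summarize_cohort(cohort):
            cond = next(
                c for c in design.conditions
                if (c.genotype, c.tamoxifen_day) == (s.genotype, s.tamoxifen_day))
            nominal, sd = (
                (cond.neuron_count_mean, cond.neuron_count_sd)
                if s.cell_class == NEURON
                else (cond.glia_count_mean, cond.glia_count_sd))
            se = np.sqrt(sd**2 + 1 / 12) / np.sqrt(n)
            assert abs(s.mean - nominal) <= 4 * se

    def test_csv_round_trip(self, reference_design, tmp_path):
        cohort = fm.generate_cohort(reference_design, seed=2)
        path = tmp_path / "counts.csv"
        cohort.to_csv(path)
        assert fm.CohortDataset.from_csv(path).animals == cohort.animals


class TestRenderStack:
    def test_empty_scene_all_zero(self, small_volume):
        stack = fm.render_stack([], small_volume, blur_sigma=0.0,
                                noise_scale=0.0)
        assert stack.intensities.sum() == 0
        assert stack.intensities.dtype == np.uint16

    def test_analytic_ground_truth_area(self, small_volume):
        cell = CellSpec((60.0, 60.0, 25.0), (11.0, 11.0, 8.0), NEURON)
        stack = fm.render_stack([cell], small_volume, blur_sigma=0.0,
                                noise_scale=0.0)
        assert stack.ground_truth[0].soma_area == pytest.approx(
            np.pi * 121, rel=1e-12)

    def test_centroid_outside_volume_rejected(self, small_volume):
        cell = CellSpec((500.0, 60.0, 25.0), (5.0, 5.0, 4.0), GLIA)
        with pytest.raises(ValueError):
            fm.render_stack([cell], small_volume)

    def test_determinism_with_noise(self, small_volume):
        scene = fm.sample_cell_scene(3, 3, small_volume, seed=4)
        a = fm.render_stack(scene, small_volume, blur_sigma=1.0,
                            noise_scale=50.0, seed=4)
        b = fm.render_stack(scene, small_volume, blur_sigma=1.0,
                            noise_scale=50.0, seed=4)
        assert np.array_equal(a.intensities, b.intensities)

    def test_scene_placement_non_overlapping(self, small_volume):
        scene = fm.sample_cell_scene(10, 10, small_volume, seed=6)
        assert len(scene) == 20
        for i, a in enumerate(scene):
            for b in scene[i + 1:]:
                d = np.linalg.norm(np.subtract(a.centroid, b.centroid))
                assert d > max(a.radii) + max(b.radii)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n_neurons=st.integers(0, 30), n_glia=st.integers(0, 30),
       seed=st.integers(0, 2**20))
def test_area_separation_property(n_neurons, n_glia, seed):
    """For any draw, the glia and neuron area samples never interleave."""
    areas = fm.generate_soma_areas(n_neurons, n_glia, seed=seed)
    neurons = [a for a, c in areas if c == NEURON]
    glia = [a for a, c in areas if c == GLIA]
    if neurons and glia:
        assert max(glia) < min(neurons)
    assert len(areas) == n_neurons + n_glia
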