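"""Synthetic-data generator: determinism, composition targets, planted-label
soundness, depth marginals, GC-bias parameter recovery."""

import math

import numpy as np
import pytest

from concordkit.concordance import MissCategory, classify_missed_site
from concordkit.core import default_config
from concordkit.coverage import depth_histogram, fit_gc_bias, gc_coverage_windows, poisson_expected
from concordkit.synthetic import (
    PLATFORM_MODELS,
    PlatformModel,
    classifier_recovery,
    generate_reference,
    homopolymer_runs,
    plant_truth_variants,
    simulate_platform,
)
from test_coverage import tv_distance


def gc_fraction(seq):
    return sum(c in "GC" for c in seq) / len(seq)


class TestReference:
    def test_seed_determinism(self):
        a = generate_reference(10_000, 0.5, [], seed=1)
        b = generate_reference(10_000, 0.5, [], seed=1)
        assert a.sequences == b.sequences

    @pytest.mark.parametrize("bad", [
        dict(length=500, gc_target=0.5),
        dict(length=10_000, gc_target=1.0),
        dict(length=10_000, gc_target=0.0),
        dict(length=2_000, gc_target=0.5, repeat_spec=[(1_500, 2)]),
    ])
    def test_preconditions(self, bad):
        with pytest.raises(ValueError):
            generate_reference(**bad)

    @pytest.mark.parametrize("target", [0.4, 0.5, 0.6])
    def test_overall_gc_near_target(self, target):
        ref = generate_reference(100_000, target, [], seed=7)
        assert abs(gc_fraction(ref.sequences["chr1"]) - target) <= 0.02

    def test_planted_repeats_are_exact_copies_at_recorded_coordinates(self):
        ref = generate_reference(20_000, 0.45, [(600, 3)], seed=3)
        assert len(ref.repeat_intervals) == 3
        seqs = [ref.sequences[iv.chrom][iv.start:iv.end]
                for iv in ref.repeat_intervals]
        assert len(set(seqs)) == 1 and len(seqs[0]) == 600


class TestTruthVariants:
    def test_zero_rates_give_empty_truth(self, small_reference):
        t = plant_truth_variants(small_reference, 0.0, 0.0, seed=1)
        assert t.variants == []

    def test_seed_determinism(self, small_reference):
        a = plant_truth_variants(small_reference, 1e-3, 2e-4, seed=5)
        b = plant_truth_variants(small_reference, 1e-3, 2e-4, seed=5)
        assert a.variants == b.variants

    def test_snp_count_within_binomial_bounds_on_one_megabase(self):
        ref = generate_reference(1_000_000, 0.45, [], seed=9)
        t = plant_truth_variants(ref, 1e-3, 0.0, seed=10)
        n = len(t.substitutions())
        sd = math.sqrt(1_000_000 * 1e-3)
        assert abs(n - 1_000) <= 4 * sd

    def test_minimum_spacing_and_het_hom_ratio(self, small_reference):
        t = plant_truth_variants(small_reference, 5e-3, 1e-3, seed=6)
        positions = [v.site.pos for v in t.variants]
        assert all(b - a >= 2 for a, b in zip(positions, positions[1:]))
        n_het = sum(v.genotype.value == "het" for v in t.variants)
        frac_het = n_het / len(t.variants)
        sd = math.sqrt((2 / 3) * (1 / 3) / len(t.variants))
        assert abs(frac_het - 2 / 3) <= 4 * sd


class TestHomopolymers:
    def test_runs_found_with_threshold(self):
        seq = "ACGTAAAACGGGGGTC"
        assert homopolymer_runs(seq, 4) == [(4, 8), (9, 14)]
        assert homopolymer_runs(seq, 5) == [(9, 14)]
        assert homopolymer_runs("ACGT", 4) == []


class TestSimulation:
    def test_seed_determinism(self, small_reference, small_truth, config):
        a = simulate_platform(small_truth, small_reference,
                              PLATFORM_MODELS["illumina"], config, seed=3)
        b = simulate_platform(small_truth, small_reference,
                              PLATFORM_MODELS["illumina"], config, seed=3)
        assert a.callset == b.callset
        assert a.evidence == b.evidence
        assert a.labels == b.labels
        assert all(np.array_equal(a.depth[c], b.depth[c]) for c in a.depth)

    @pytest.mark.parametrize("platform", ["roche454", "illumina", "solid"])
    def test_planted_labels_recovered_by_classifier(
            self, small_reference, small_truth, config, platform):
        sim = simulate_platform(small_truth, small_reference,
                                PLATFORM_MODELS[platform], config, seed=21)
        n_miss = sum(isinstance(l, MissCategory) for l in sim.labels.values())
        assert n_miss > 5  # the check must actually exercise misses
        assert classifier_recovery(sim, config) == 1.0

    def test_no_coverage_label_has_zero_depth(
            self, small_reference, small_truth, config):
        sim = simulate_platform(small_truth, small_reference,
                                PLATFORM_MODELS["solid"], config, seed=22)
        zero_sites = [s for s, l in sim.labels.items()
                      if l is MissCategory.NO_COVERAGE]
        for s in zero_sites:
            assert sim.evidence[s].depth == 0
            assert classify_missed_site(
                sim.evidence[s], config.platforms["solid"]) \
                is MissCategory.NO_COVERAGE

    def test_truth_sites_in_repeats_are_mapping_ambiguity_misses(
            self, small_reference, small_truth, config):
        repeat = small_reference.repeat_intervals
        in_repeat = [v.site for v in small_truth.substitutions()
                     if any(iv.contains(v.site) for iv in repeat)]
        if not in_repeat:
            pytest.skip("no truth substitution landed inside a repeat")
        sim_mapq = simulate_platform(small_truth, small_reference,
                                     PLATFORM_MODELS["illumina"], config, seed=4)
        sim_nomapq = simulate_platform(small_truth, small_reference,
                                       PLATFORM_MODELS["roche454"], config, seed=4)
        for s in in_repeat:
            assert sim_mapq.labels[s] is MissCategory.LOW_RMS_MAPQ
            assert sim_nomapq.labels[s] is MissCategory.NON_UNIQUE

    def test_called_sites_survive_the_platform_filter(
            self, small_reference, small_truth, config):
        from concordkit.filters import apply_platform_filter
        sim = simulate_platform(small_truth, small_reference,
                                PLATFORM_MODELS["illumina"], config, seed=8)
        retained, rejected = apply_platform_filter(
            sim.callset, sim.evidence, config.platforms["illumina"], config)
        assert rejected == []
        assert {c.site for c in retained if c.is_substitution} == {
            s for s, l in sim.labels.items() if l in ("called", "fp")}

    def test_pyrosequencing_like_platform_injects_homopolymer_fps(
            self, small_reference, small_truth, config):
        sim = simulate_platform(small_truth, small_reference,
                                PLATFORM_MODELS["roche454"], config, seed=30)
        assert sim.fp_sites
        runs = homopolymer_runs(small_reference.sequences["chr1"], 4)
        run_ends = {end for _, end in runs}
        adjacent = sum(s.pos in run_ends for s in sim.fp_sites)
        assert adjacent > 0


class TestDepthModel:
    def test_unbiased_depth_marginal_is_poisson(self, config):
        ref = generate_reference(200_000, 0.45, [], seed=40)
        truth = plant_truth_variants(ref, 0.0, 0.0, seed=41)
        model = PlatformModel(platform_id="illumina", mean_depth=20.0,
                              gc_beta=0.0, substitution_error_rate=0.0,
                              homopolymer_fp_rate=0.0, duplicate_fraction=0.0,
                              repeat_mapq_penalty=0.0, has_mapq=True)
        sim = simulate_platform(truth, ref, model, config, seed=42)
        hist = depth_histogram(sim.depth["chr1"])
        pmf = poisson_expected(20.0, int(sim.depth["chr1"].max()) + 10)
        assert tv_distance(hist.fractions, pmf) < 0.02

    def test_flat_gc_model_has_no_significant_slope(self, config):
        ref = generate_reference(200_000, 0.45, [], seed=50)
        truth = plant_truth_variants(ref, 0.0, 0.0, seed=51)
        model = PlatformModel(platform_id="illumina", mean_depth=30.0,
                              gc_beta=0.0, substitution_error_rate=0.0,
                              homopolymer_fp_rate=0.0, duplicate_fraction=0.0,
                              repeat_mapq_penalty=0.0, has_mapq=True)
        sim = simulate_platform(truth, ref, model, config, seed=52)
        windows = gc_coverage_windows(ref.sequences, sim.depth, 1_000)
        _, slope, se = fit_gc_bias(windows)
        assert abs(slope) <= 3 * se + 1e-9

    def test_planted_gc_bias_recovered_within_two_standard_errors(self, config):
        ref = generate_reference(200_000, 0.45, [], seed=60)
        truth = plant_truth_variants(ref, 0.0, 0.0, seed=61)
        model = PlatformModel(platform_id="illumina", mean_depth=30.0,
                              gc_beta=-2.0, substitution_error_rate=0.0,
                              homopolymer_fp_rate=0.0, duplicate_fraction=0.0,
                              repeat_mapq_penalty=0.0, has_mapq=True)
        sim = simulate_platform(truth, ref, model, config, seed=62)
        windows = gc_coverage_windows(ref.sequences, sim.depth, 1_000)
        assert len(windows) == 200
        _, slope, se = fit_gc_bias(windows)
        assert abs(slope - (-2.0)) <= 2 * se
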