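"""Dual-channel pipeline rules against independent brute-force oracles,
plus the Lowess normalization properties."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exocargo import (
    ConfigurationError,
    MirnaParams,
    SimulationConfig,
    aggregate_detection,
    build_venn,
    call_slide_status,
    classify_fold_change,
    detection_profiles,
    estimate_slide_background,
    generate_truth,
    lowess_normalize_slide,
    rank_enriched,
    run_mirna_pipeline,
    simulate_two_channel_slides,
    summarize_ratios,
)
from exocargo.mirna import normalize_ratios

from conftest import make_slide_set


class TestSlideBackground:
    @pytest.mark.parametrize(
        "values,expected",
        [([1.0, 2.0, 3.0], 2.0), ([1.0, 2.0, 3.0, 4.0], 2.5)],
    )
    def test_median_conventions(self, values, expected):
        slides = make_slide_set(
            {f"p{i}": v for i, v in enumerate(values)},
            {f"p{i}": 10.0 for i in range(len(values))},
        )
        backgrounds = {(b.slide, b.channel): b.background for b in estimate_slide_background(slides)}
        assert backgrounds[(1, "Hy3")] == expected

    def test_matches_sort_based_median_oracle(self, rng):
        values = rng.uniform(1, 1e4, size=1000)
        slides = make_slide_set(
            {f"p{i:04d}": v for i, v in enumerate(values)},
            {f"p{i:04d}": 1.0 for i in range(1000)},
        )
        ordered = np.sort(values)
        oracle = 0.5 * (ordered[499] + ordered[500])
        result = [b for b in estimate_slide_background(slides) if b.channel == "Hy3"][0]
        assert result.background == oracle

    def test_empty_slide_set_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_slide_background(pd.DataFrame(columns=["slide", "hy3_fg", "hy5_fg"]))


def status_oracle(fg, spot_bg, slide_bg, multiplier=3.0):
    """Literal restatement of the detection rule, evaluated the slow way."""
    at_or_below = sum(1 for f, b in zip(fg, spot_bg) if f <= b)
    if at_or_below >= math.ceil(len(fg) / 2):
        return "absent"
    ordered = sorted(fg)
    n = len(ordered)
    median = ordered[n // 2] if n % 2 else 0.5 * (ordered[n // 2 - 1] + ordered[n // 2])
    return "detectable" if median > multiplier * slide_bg else "below_limit"


class TestCallSlideStatus:
    def test_two_of_four_at_or_below_background_is_absent(self):
        # bright on half the spots does not rescue a probe failing on the other half
        assert call_slide_status([5, 5, 90, 90], [6, 6, 10, 10], slide_background=1.0) == "absent"

    def test_all_zero_signal_is_absent(self):
        assert call_slide_status([0, 0, 0, 0], [0, 0, 0, 0], slide_background=0.0) == "absent"

    def test_exhaustive_patterns_match_oracle(self):
        """All 2^4 at/below-background patterns x {<=, >} 3x-background regimes."""
        slide_bg = 10.0
        for pattern in itertools.product([True, False], repeat=4):
            for bright in (25.0, 35.0):  # median below vs above 3 x 10
                fg = [5.0 if below else bright for below in pattern]
                bg = [5.0] * 4
                assert call_slide_status(fg, bg, slide_bg) == status_oracle(fg, bg, slide_bg)

    @given(
        fg=st.lists(st.floats(0, 1e5, allow_nan=False), min_size=1, max_size=7),
        slide_bg=st.floats(0.1, 1e4),
        data=st.data(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_random_replicates_match_oracle(self, fg, slide_bg, data):
        bg = data.draw(
            st.lists(st.floats(0, 1e4, allow_nan=False), min_size=len(fg), max_size=len(fg))
        )
        assert call_slide_status(fg, bg, slide_bg) == status_oracle(fg, bg, slide_bg)

    def test_mismatched_vector_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            call_slide_status([1, 2, 3], [1, 2], slide_background=1.0)


class TestAggregateDetection:
    def test_detectable_on_two_of_three_slides_is_unreliable(self):
        statuses = ["detectable", "detectable", "below_limit"]
        assert aggregate_detection(statuses, min_slides=3) == "undetected"

    def test_detectable_on_all_slides_is_detected(self):
        assert aggregate_detection(["detectable"] * 3) == "detected"

    def test_random_assignments_match_counting_oracle(self, rng):
        options = np.array(["absent", "below_limit", "detectable"])
        for _ in range(500):
            statuses = list(rng.choice(options, size=rng.integers(1, 6)))
            min_slides = int(rng.integers(1, len(statuses) + 1))
            expected = (
                "detected"
                if sum(s == "detectable" for s in statuses) >= min_slides
                else "undetected"
            )
            assert aggregate_detection(statuses, min_slides) == expected

    def test_min_slides_beyond_available_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate_detection(["detectable"] * 2, min_slides=3)


class TestDetectionMonotonicity:
    def detected_sets(self, slides, multiplier, min_slides):
        profiles = detection_profiles(
            slides, MirnaParams(detect_multiplier=multiplier, min_slides=min_slides)
        )
        return set(profiles.index[profiles["detected_Hy3"] == "detected"])

    def test_raising_multiplier_never_grows_detected_set(self, default_slides):
        previous = None
        for multiplier in (1.0, 2.0, 3.0, 5.0):
            detected = self.detected_sets(default_slides, multiplier, None)
            if previous is not None:
                assert detected <= previous
            previous = detected

    def test_lowering_min_slides_never_shrinks_detected_set(self, default_slides):
        previous = None
        for min_slides in (3, 2, 1):
            detected = self.detected_sets(default_slides, 3.0, min_slides)
            if previous is not None:
                assert detected >= previous
            previous = detected


def lowess_test_config(**overrides):
    base = dict(
        n_probes=300,
        fraction_shared=1.0,
        fraction_exosome_only=0.0,
        fraction_cell_only=0.0,
        enrichment_sd=0.0,
        dye_bias_amplitude=0.0,
        background_level=0.0,
        noise_cv=0.0,
        n_slides=1,
        seed=13,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestLowessNormalization:
    def summarized_channels(self, config, hy3_scale=1.0):
        truth = generate_truth(config)
        slides = simulate_two_channel_slides(truth, config)
        pivot3 = slides.pivot_table(index="probe_id", columns="replicate", values="hy3_fg")
        pivot5 = slides.pivot_table(index="probe_id", columns="replicate", values="hy5_fg")
        return truth, pivot3.median(axis=1) * hy3_scale, pivot5.median(axis=1)

    def test_constant_offset_removed(self):
        _, hy3, hy5 = self.summarized_channels(lowess_test_config(), hy3_scale=2.0 ** 1.7)
        normalized, excluded = lowess_normalize_slide(hy3, hy5)
        assert not excluded
        assert np.abs(normalized).max() < 1e-6
        assert abs(np.median(normalized)) < 1e-6

    def test_channel_swap_negates_ratios(self):
        config = lowess_test_config(enrichment_sd=1.0, dye_bias_amplitude=0.8)
        _, hy3, hy5 = self.summarized_channels(config)
        forward, _ = lowess_normalize_slide(hy3, hy5)
        backward, _ = lowess_normalize_slide(hy5, hy3)
        np.testing.assert_allclose(forward, -backward, atol=1e-12)

    def test_injected_smooth_dye_bias_recovered_in_interior(self):
        config = lowess_test_config(dye_bias_amplitude=0.8, n_probes=500)
        truth, hy3, hy5 = self.summarized_channels(config)
        normalized, _ = lowess_normalize_slide(hy3, hy5)
        a = 0.5 * np.log2(hy3 * hy5)
        interior = (a > a.quantile(0.1)) & (a < a.quantile(0.9))
        truth_fc = truth.set_index("probe_id").loc[normalized.index, "true_log2fc"]
        assert np.abs((normalized - truth_fc)[interior]).max() < 0.05

    def test_idempotence_on_already_normalized_smooth_data(self):
        """A linear-in-A trend is removed exactly, so a second pass is a no-op."""
        _, hy3, hy5 = self.summarized_channels(lowess_test_config(n_probes=200))
        a = 0.5 * np.log2(hy3 * hy5)
        tilted_hy3 = hy3 * 2.0 ** (0.3 * (a - a.mean()))
        once, _ = lowess_normalize_slide(tilted_hy3, hy5)
        renorm_hy3 = hy5 * 2.0 ** once
        twice, _ = lowess_normalize_slide(renorm_hy3, hy5)
        assert np.abs(twice - once).max() < 1e-3

    def test_non_positive_signals_excluded_and_reported(self):
        _, hy3, hy5 = self.summarized_channels(lowess_test_config(n_probes=50))
        hy3.iloc[0] = 0.0
        normalized, excluded = lowess_normalize_slide(hy3, hy5)
        assert excluded == [hy3.index[0]]
        assert np.isnan(normalized.iloc[0])
        assert normalized.iloc[1:].notna().all()

    def test_too_few_probes_rejected(self):
        tiny = pd.Series([1.0] * 4, index=list("abcd"))
        with pytest.raises(ConfigurationError):
            lowess_normalize_slide(tiny, tiny)


class TestSummarizeRatios:
    def test_constant_ratios_have_zero_sd(self):
        ratios = pd.DataFrame({1: [2.0], 2: [2.0], 3: [2.0]}, index=["p1"])
        out = summarize_ratios(ratios)
        assert out.loc["p1", "mean_log2_ratio"] == 2.0
        assert out.loc["p1", "sd_log2_ratio"] == 0.0

    def test_hand_arithmetic(self):
        ratios = pd.DataFrame({1: [1.0], 2: [2.0], 3: [3.0]}, index=["p1"])
        out = summarize_ratios(ratios)
        assert out.loc["p1", "mean_log2_ratio"] == 2.0
        assert out.loc["p1", "sd_log2_ratio"] == 1.0

    def test_matches_two_pass_oracle(self, rng):
        ratios = pd.DataFrame(
            rng.normal(size=(100, 3)), columns=[1, 2, 3],
            index=[f"p{i}" for i in range(100)],
        )
        out = summarize_ratios(ratios)
        for probe in ratios.index:
            values = ratios.loc[probe].to_numpy()
            mean = sum(values) / 3
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 2)
            assert abs(out.loc[probe, "mean_log2_ratio"] - mean) < 1e-12
            assert abs(out.loc[probe, "sd_log2_ratio"] - sd) < 1e-12

    def test_fully_excluded_probe_is_missing_not_zero(self):
        ratios = pd.DataFrame({1: [np.nan, 0.5], 2: [np.nan, 0.7]}, index=["px", "py"])
        out = summarize_ratios(ratios)
        assert np.isnan(out.loc["px", "mean_log2_ratio"])
        assert out.loc["px", "n_slides"] == 0


class TestClassifyFoldChange:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (2.0, "elevated_in_exosomes"),  # boundary inclusive: exactly 4-fold
            (-2.0, "elevated_in_cells"),
            (0.0, "equal"),
            (1.99, "equal"),
            (-1.99, "equal"),
            (3.0, "elevated_in_exosomes"),
            (-3.0, "elevated_in_cells"),
        ],
    )
    def test_boundary_sweep(self, mean, expected):
        assert classify_fold_change(mean, threshold=2.0) == expected

    @given(mean=st.floats(-10, 10, allow_nan=False), threshold=st.floats(0.1, 5))
    @settings(max_examples=200, derandomize=True)
    def test_matches_three_way_comparison_oracle(self, mean, threshold):
        if mean >= threshold:
            expected = "elevated_in_exosomes"
        elif mean <= -threshold:
            expected = "elevated_in_cells"
        else:
            expected = "equal"
        assert classify_fold_change(mean, threshold) == expected

    def test_missing_mean_is_unclassified(self):
        assert classify_fold_change(float("nan")) is None


class TestBuildVenn:
    def test_published_set_sizes(self):
        shared = {f"s{i}" for i in range(89)}
        exo = shared | {f"e{i}" for i in range(27)}
        cell = shared | {f"c{i}" for i in range(45)}
        venn = build_venn(exo, cell)
        assert (venn.exo_total, venn.cell_total) == (116, 134)
        assert (venn.exo_only, venn.cell_only, venn.shared) == (27, 45, 89)
        assert venn.union_size == 161

    def test_disjoint_sets(self):
        venn = build_venn({"a", "b", "c"}, {"d", "e", "f", "g", "h"})
        assert venn.shared == 0 and venn.union_size == 8

    @given(
        exo=st.sets(st.integers(0, 50), max_size=40),
        cell=st.sets(st.integers(0, 50), max_size=40),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_membership_enumeration_oracle(self, exo, cell):
        venn = build_venn(exo, cell)
        both = sum(1 for x in range(51) if x in exo and x in cell)
        only_exo = sum(1 for x in range(51) if x in exo and x not in cell)
        only_cell = sum(1 for x in range(51) if x not in exo and x in cell)
        assert venn.shared == both
        assert venn.exo_only == only_exo
        assert venn.cell_only == only_cell
        assert venn.exo_only + venn.shared == venn.exo_total
        assert venn.cell_only + venn.shared == venn.cell_total


class TestRankEnriched:
    def table(self, means):
        return pd.DataFrame(
            {"mean_log2_ratio": pd.Series(means)}
        ).rename_axis("probe_id")

    def test_descending_for_exosome_direction(self):
        assert rank_enriched(self.table({"a": 3.0, "b": 1.0, "c": 2.0}), 2) == ["a", "c"]

    def test_n_beyond_table_returns_whole_sorted_table(self):
        assert rank_enriched(self.table({"a": 3.0, "b": 1.0}), 10) == ["a", "b"]

    def test_ties_break_lexicographically(self):
        assert rank_enriched(self.table({"z": 1.0, "a": 1.0, "m": 1.0}), 3) == ["a", "m", "z"]

    def test_matches_sort_oracle(self, rng):
        means = {f"p{i:02d}": float(v) for i, v in enumerate(rng.normal(size=50))}
        expected = [k for k, _ in sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert rank_enriched(self.table(means), 50) == expected
        assert rank_enriched(self.table(means), 50, direction="cell") == expected[::-1]


class TestPipelineRecovery:
    def test_noiseless_venn_equals_truth_counts(self, noiseless_config):
        truth = generate_truth(noiseless_config)
        slides = simulate_two_channel_slides(truth, noiseless_config)
        result = run_mirna_pipeline(slides)
        counts = truth["compartment_class"].value_counts()
        assert result.venn.exo_only == counts.get("exosome_only", 0)
        assert result.venn.cell_only == counts.get("cell_only", 0)
        assert result.venn.shared == counts.get("shared", 0)

    def test_normalize_ratios_aligns_slides_and_reports_exclusions(self, default_slides):
        ratios, excluded = normalize_ratios(default_slides)
        assert list(ratios.columns) == [1, 2, 3]
        assert set(excluded) == {1, 2, 3}
        assert ratios.notna().all().all()  # additive background keeps signals positive
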