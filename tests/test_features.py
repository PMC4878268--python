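import numpy as np
import pytest
from hypothesis import given, strategies as st

from calclust import (
    SyntheticConfig,
    default_protocol,
    detect_peaks,
    extract_features,
    generate_dataset,
    kcl_norm,
    kcl_response_feature,
    oscillation_frequency,
    oscillation_magnitude,
    response_speed,
    return_to_baseline,
)
from calclust.features import FEATURE_NAMES, extract_cell_features
from calclust.synthetic import OSCILLATOR, default_kinetics
from calclust.stats import spearman_test

from conftest import make_dataset


def _with_high(high_samples, kcl=3.0, second_low=(1.0, 1.0, 1.0)):
    """18-sample toy trace with a custom high-glucose segment (6 samples)."""
    v = np.ones(18)
    v[4:10] = high_samples
    v[10:13] = second_low
    v[13:16] = kcl
    return v


class TestPerCellFeatures:
    def test_toy_cell_yields_hand_computed_vector(self, toy_trace, toy_times, toy_protocol):
        feats = extract_cell_features(toy_trace, toy_times, toy_protocol)
        expected = {
            "high_glucose_response": 0.25,  # (1.5 - 1) / 2
            "high_glucose_oscillation": 0.25,  # MAD 0.5 / 2
            "low_glucose_oscillation_pre": 0.0,
            "low_glucose_oscillation_post": 0.05,  # MAD 0.1 / 2
            "response_speed": 1.0,  # first peak 1 min after onset
            "counted_peaks": 3.0,
            "oscillation_frequency": 0.5,  # intervals {2, 2} min
            "return_to_baseline": 0.0,
            "kcl_response": 1.0,
        }
        assert feats == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kcl_samples, expected_n",
        [([3.0, 3.0, 3.0], 2.0), ([2.0, 3.0, 4.0], 2.0)],
    )
    def test_kcl_normaliser_is_median_above_baseline(
        self, kcl_samples, expected_n, toy_protocol, toy_times
    ):
        v = np.ones(18)
        v[13:16] = kcl_samples
        assert kcl_norm(v, toy_times, toy_protocol) == pytest.approx(expected_n)

    def test_flat_cell_fails_normaliser_contract(self, toy_protocol, toy_times):
        with pytest.raises(ValueError, match="fails QC"):
            kcl_norm(np.ones(18), toy_times, toy_protocol)

    @pytest.mark.parametrize(
        "kcl_samples, expected",
        [([3.0, 3.0, 3.0], 1.0), ([2.0, 3.0, 4.0], 1.5)],
    )
    def test_kcl_response_max_over_median(self, kcl_samples, expected, toy_protocol, toy_times):
        v = np.ones(18)
        v[13:16] = kcl_samples
        assert kcl_response_feature(v, toy_times, toy_protocol) == pytest.approx(expected)
        assert kcl_response_feature(v, toy_times, toy_protocol) >= 1.0

    def test_oscillation_magnitude_of_constant_epoch_is_zero(self, toy_protocol, toy_times):
        v = _with_high(np.ones(6))
        assert oscillation_magnitude(v, toy_times, toy_protocol) == 0.0

    def test_return_to_baseline_may_go_negative(self, toy_protocol, toy_times):
        v = _with_high(np.ones(6), second_low=(0.8, 0.9, 1.0))
        assert return_to_baseline(v, toy_times, toy_protocol) == pytest.approx(-0.1)


class TestPeakDetection:
    def test_square_wave_has_three_peaks_including_endpoint(
        self, toy_trace, toy_times, toy_protocol
    ):
        peaks = detect_peaks(toy_trace, toy_times, toy_protocol)
        np.testing.assert_allclose(peaks.peak_times, [5.0, 7.0, 9.0])
        assert peaks.threshold == pytest.approx(2.0 / 3.0)

    def test_subthreshold_bump_is_not_a_peak(self, toy_protocol, toy_times):
        v = _with_high([1, 1.5, 1, 1, 1, 1])  # height 0.5 < N/3 = 0.667
        assert len(detect_peaks(v, toy_times, toy_protocol)) == 0

    def test_constant_epoch_has_no_peaks(self, toy_protocol, toy_times):
        v = _with_high(np.ones(6))
        assert len(detect_peaks(v, toy_times, toy_protocol)) == 0

    def test_plateau_counts_once_at_first_sample(self, toy_protocol, toy_times):
        v = _with_high([1, 2, 2, 2, 1, 1])
        peaks = detect_peaks(v, toy_times, toy_protocol)
        np.testing.assert_allclose(peaks.peak_times, [5.0])

    def test_first_sample_peak_uses_one_sampling_interval_latency(
        self, toy_protocol, toy_times
    ):
        v = _with_high([2, 1, 1, 1, 1, 1])
        assert response_speed(v, toy_times, toy_protocol) == pytest.approx(1.0)

    def test_no_peaks_gives_zero_speed_and_frequency(self, toy_protocol, toy_times):
        v = _with_high(np.ones(6))
        assert response_speed(v, toy_times, toy_protocol) == 0.0
        assert oscillation_frequency(v, toy_times, toy_protocol) == 0.0

    def test_single_peak_gives_zero_frequency(self, toy_protocol, toy_times):
        v = _with_high([1, 2, 1, 1, 1, 1])
        assert oscillation_frequency(v, toy_times, toy_protocol) == 0.0

    def test_prominence_mode_ignores_jitter_on_elevated_plateau(
        self, toy_protocol, toy_times
    ):
        # plateau 0.8 above baseline with a 0.05 wiggle: high above baseline,
        # but nothing rises N/3 above its surroundings
        v = _with_high([1.8, 1.85, 1.8, 1.85, 1.8, 1.8])
        assert len(detect_peaks(v, toy_times, toy_protocol)) == 0
        above = detect_peaks(v, toy_times, toy_protocol, qualification="above_baseline")
        assert len(above) == 2

    def test_sinusoid_frequency_recovered_within_sampling_resolution(self):
        protocol = default_protocol()
        times = np.arange(480) / 6.0
        period = 3.0
        trace = np.ones_like(times)
        high = (times >= 20) & (times < 50)
        trace[high] += 0.8 * (1 + np.sin(2 * np.pi * (times[high] - 20) / period))
        trace[(times >= 65) & (times < 75)] = 3.0
        freq = oscillation_frequency(trace, times, protocol)
        assert abs(1.0 / freq - period) <= 1.0 / 6.0


class TestFeatureTable:
    def test_columns_are_fixed_and_typed(self, preset_run):
        table = preset_run["features"]
        assert list(table.columns) == ["cell_id", "field_id", *FEATURE_NAMES]
        assert table[list(FEATURE_NAMES)].notna().all().all()
        assert table["counted_peaks"].dtype.kind == "i"
        assert (table["kcl_response"] >= 1.0).all()

    def test_all_flat_except_kcl_gives_zero_glucose_features(
        self, toy_protocol, toy_times
    ):
        ds = make_dataset(_with_high(np.ones(6)), toy_times)
        row = extract_features(ds, toy_protocol).iloc[0]
        assert row["high_glucose_response"] == 0.0
        assert row["high_glucose_oscillation"] == 0.0
        assert row["counted_peaks"] == 0
        assert row["kcl_response"] == pytest.approx(1.0)

    def test_failing_cell_is_named(self, toy_protocol, toy_times):
        ds = make_dataset(np.ones((1, 18)), toy_times)
        with pytest.raises(ValueError, match="c1"):
            extract_features(ds, toy_protocol)

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_affine_invariance_of_all_nine_features(self, a, b):
        protocol = default_protocol()
        dataset, _ = generate_dataset(
            SyntheticConfig(n_cells=4, weights=(0.5, 0.3, 0.2, 0.0), seed=11)
        )
        base = extract_features(dataset, protocol)
        scaled = make_dataset(a * dataset.values + b, dataset.times)
        moved = extract_features(scaled, protocol)
        np.testing.assert_allclose(
            base[list(FEATURE_NAMES)].to_numpy(),
            moved[list(FEATURE_NAMES)].to_numpy(),
            rtol=1e-8,
            atol=1e-10,
        )

    def test_peak_count_and_frequency_correlate_on_oscillators(self):
        # noiseless oscillator population with a spread of periods
        from dataclasses import replace

        protocol = default_protocol()
        rng = np.random.default_rng(3)
        kin = dict(default_kinetics())
        tables = []
        for period in rng.uniform(2.0, 6.0, size=30):
            kin[OSCILLATOR] = replace(
                kin[OSCILLATOR], period_min=float(period), period_jitter=0.0
            )
            cfg = SyntheticConfig(
                n_cells=1, weights=(1, 0, 0, 0), noise_sd=0.0,
                drift_slope_mean=0.0, drift_slope_sd=0.0, kinetics=dict(kin),
                seed=int(rng.integers(2**31)),
            )
            ds, _ = generate_dataset(cfg)
            tables.append(extract_features(ds, protocol, drift_correct=False))
        import pandas as pd

        table = pd.concat(tables, ignore_index=True)
        res = spearman_test(table["counted_peaks"], table["oscillation_frequency"])
        assert res.statistic > 0.9
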