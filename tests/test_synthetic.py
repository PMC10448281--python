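"""Generator contracts: determinism, planted effects, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

from lonewatch.errors import (
    ConfigurationError,
    DegenerateSignalError,
    ParameterError,
    UndersamplingError,
)
from lonewatch.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_ibi_series,
    generate_ppg,
    inject_missingness,
)
from lonewatch.io import write_cohort


class TestGenerateIBISeries:
    def test_zero_variance_is_constant(self):
        intervals = generate_ibi_series(60.0, 0.0, duration_s=300.0, seed=0)
        assert len(intervals) == 300
        assert np.allclose(intervals, 1000.0)

    def test_mean_interval_within_two_percent(self):
        intervals = generate_ibi_series(75.0, 50.0, duration_s=300.0, seed=3)
        assert abs(np.mean(intervals) - 800.0) / 800.0 < 0.02

    def test_sum_covers_duration(self):
        intervals = generate_ibi_series(80.0, 40.0, duration_s=300.0, seed=4)
        assert np.sum(intervals) >= 300_000.0
        assert np.sum(intervals) - intervals[-1] < 300_000.0

    def test_sd_within_20_percent_of_target(self):
        intervals = generate_ibi_series(75.0, 50.0, duration_s=300.0, seed=2)
        assert abs(np.std(intervals) - 50.0) < 10.0

    def test_spectral_peak_at_modulation_frequency(self):
        # FFT of the interval sequence on the mean-interval grid is an
        # independent check of where the planted power sits
        intervals = generate_ibi_series(
            60.0, 50.0, modulation_hz=0.1, duration_s=600.0, seed=5
        )
        x = intervals - intervals.mean()
        freqs = np.fft.rfftfreq(len(x), d=np.mean(intervals) / 1000.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert abs(peak - 0.1) < 0.02

    def test_sdnn_larger_than_mean_interval_rejected(self):
        with pytest.raises(ParameterError):
            generate_ibi_series(60.0, 1000.0, duration_s=60.0, seed=0)

    @pytest.mark.parametrize("hr", [10.0, 250.0])
    def test_hr_out_of_range_rejected(self, hr):
        with pytest.raises(ParameterError):
            generate_ibi_series(hr, 20.0, duration_s=60.0, seed=0)


class TestGeneratePPG:
    def test_sample_count(self):
        intervals = generate_ibi_series(60.0, 0.0, duration_s=300.0, seed=0)
        seg = generate_ppg(intervals, fs_hz=20.0, seed=0)
        assert len(seg.samples) == 6000

    def test_clean_maxima_spacing_at_60bpm(self):
        intervals = generate_ibi_series(60.0, 0.0, duration_s=120.0, seed=0)
        seg = generate_ppg(intervals, fs_hz=20.0, noise_sd=0.0, seed=0)
        maxima, _ = find_peaks(seg.samples, height=0.5)
        spacings_ms = np.diff(maxima) / 20.0 * 1000.0
        assert np.all(np.abs(spacings_ms - 1000.0) <= 50.0)

    def test_ground_truth_matches_clean_maxima(self):
        intervals = generate_ibi_series(72.0, 40.0, duration_s=120.0, seed=9)
        seg = generate_ppg(intervals, fs_hz=20.0, noise_sd=0.0, seed=0)
        maxima, _ = find_peaks(seg.samples, height=0.5)
        # every stored true peak is a local maximum within one sample
        dists = np.min(np.abs(maxima[None, :] - seg.true_peaks[:, None]), axis=1)
        assert dists.max() <= 1

    def test_empty_series_rejected(self):
        with pytest.raises(DegenerateSignalError):
            generate_ppg(np.array([]), fs_hz=20.0)

    def test_undersampling_rejected(self):
        with pytest.raises(UndersamplingError):
            generate_ppg(np.array([1000.0] * 10), fs_hz=5.0)


class TestGenerateCohort:
    def test_prevalence_rounding(self):
        cfg = CohortConfig(
            n_participants=10, loneliness_prevalence=0.3, fast_mode=True, seed=7
        )
        bundles = generate_cohort(cfg)
        assert sum(b.true_label for b in bundles) == 3

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_participants=1)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_participants=5, missing_day_rate=1.5)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = dict(n_participants=4, loneliness_prevalence=0.5, fast_mode=True, seed=42)
        write_cohort(generate_cohort(CohortConfig(**cfg)), tmp_path / "a")
        write_cohort(generate_cohort(CohortConfig(**cfg)), tmp_path / "b")
        for name in ("sleep.csv", "activity.csv", "ucla.csv", "ibi.csv",
                     "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_planted_intensity_effect(self):
        cfg = CohortConfig(
            n_participants=12,
            loneliness_prevalence=0.5,
            effect_multipliers={"activity_intensity": 0.6},
            fast_mode=True,
            seed=3,
        )
        bundles = generate_cohort(cfg)
        means = {0: [], 1: []}
        for b in bundles:
            daily = b.activity_records.groupby(
                b.activity_records["interval_start"].dt.normalize()
            )["intensity"].sum()
            means[b.true_label].append(daily.mean())
        assert np.mean(means[1]) < np.mean(means[0])

    def test_intensity_effect_monotone_in_multiplier(self):
        lonely_means = []
        for mult in (0.9, 0.6, 0.3):
            cfg = CohortConfig(
                n_participants=8,
                loneliness_prevalence=0.5,
                effect_multipliers={"activity_intensity": mult},
                fast_mode=True,
                seed=13,
            )
            bundles = generate_cohort(cfg)
            vals = [
                b.activity_records["intensity"].sum()
                for b in bundles
                if b.true_label == 1
            ]
            lonely_means.append(np.mean(vals))
        assert lonely_means[0] > lonely_means[1] > lonely_means[2]

    def test_eight_days_per_time_point(self):
        cfg = CohortConfig(n_participants=2, fast_mode=True, seed=0)
        b = generate_cohort(cfg)[0]
        assert len(b.sleep_nights) == 16
        assert len(b.ucla_responses) == 2

    def test_no_missingness_all_days_present(self):
        cfg = CohortConfig(n_participants=2, missing_day_rate=0.0, fast_mode=True, seed=0)
        b = generate_cohort(cfg)[0]
        assert b.ground_truth["dropped_days"] == []


class TestInjectMissingness:
    def _bundle(self, seed=0):
        cfg = CohortConfig(n_participants=2, fast_mode=True, seed=seed)
        return generate_cohort(cfg)[0]

    def test_rate_zero_identity(self):
        b = self._bundle()
        n_nights = len(b.sleep_nights)
        out = inject_missingness(b, 0.0, seed=1)
        assert len(out.sleep_nights) == n_nights
        assert out.ground_truth["dropped_days"] == []

    def test_rate_one_removes_everything(self):
        b = self._bundle()
        out = inject_missingness(b, 1.0, seed=1)
        assert out.sleep_nights == []
        assert len(out.activity_records) == 0
        assert out.ibi_windows == []
        assert len(out.ground_truth["dropped_days"]) == 16

    def test_dropped_count_matches_ground_truth(self):
        b = self._bundle(seed=5)
        out = inject_missingness(b, 0.5, seed=99)
        n_dropped = len(out.ground_truth["dropped_days"])
        assert len(out.sleep_nights) == 16 - n_dropped
        remaining = {str(n.date.date()) for n in out.sleep_nights}
        assert remaining.isdisjoint(out.ground_truth["dropped_days"])


class TestUCLAConsistency:
    def test_social_scores_match_labels(self):
        cfg = CohortConfig(n_participants=10, loneliness_prevalence=0.4,
                           fast_mode=True, seed=21)
        from lonewatch.datasets import score_ucla

        for b in generate_cohort(cfg):
            for resp in b.ucla_responses:
                social, emotional = score_ucla(resp.items)
                assert 6 <= social <= 24 and 6 <= emotional <= 24
                assert (social >= 12) == bool(b.true_label)
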