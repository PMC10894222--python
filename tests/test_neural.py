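import numpy as np
import pandas as pd
import pytest

from tactime.lnp import Condition, NeuronParams, SpikeRaster, simulate_spikes
from tactime.neural import (
    PSTHProfile,
    classify_intensity_coding,
    count_code,
    detect_onset_offset,
    endwindow_rate,
    half_gaussian_kernel,
    pooled_onset_offset_psth,
    population_psth,
    resample_coding_population,
    time_to_count,
    zscore_response,
)
from tactime.synthetic import summed_raster


def step_raster(rate_pre, rate_stim, duration=694.0, t_start=-600.0, t_stop=894.0,
                n_trials=200, seed=0):
    """Poisson raster with a clean rate step over the stimulus epoch."""
    rng = np.random.default_rng(seed)
    times = np.arange(t_start, t_stop)
    rate = np.where((times >= 0) & (times < duration), rate_stim, rate_pre)
    counts = rng.poisson(rate / 1000.0, size=(n_trials, rate.size))
    return SpikeRaster(counts, t_start, 1.0, Condition(duration))


class TestZscore:
    def test_stationary_raster_has_near_zero_z(self):
        raster = step_raster(20.0, 20.0, seed=1)
        times, z = zscore_response(raster)
        stim = (times >= 0) & (times < 694)
        assert abs(np.mean(z[stim])) < 0.5

    def test_rate_step_produces_positive_z(self):
        raster = step_raster(5.0, 60.0, seed=2)
        times, z = zscore_response(raster)
        stim = (times >= 50) & (times < 600)
        base = (times >= -700) & (times < -100)
        assert np.mean(z[stim]) > 10 * abs(np.mean(z[base]))

    def test_baseline_window_must_precede_onset(self):
        raster = step_raster(5.0, 60.0)
        with pytest.raises(ValueError, match="precede"):
            zscore_response(raster, baseline_window=(-100.0, 100.0))

    def test_silent_baseline_flagged(self):
        counts = np.zeros((10, 1000), dtype=int)
        counts[:, 700:] = 1
        raster = SpikeRaster(counts, -600.0, 1.0, Condition(334.0))
        with pytest.raises(ValueError, match="variance"):
            zscore_response(raster)


class TestPopulationPsth:
    def test_kernel_is_normalized(self):
        assert half_gaussian_kernel(25.0).sum() == pytest.approx(1.0, abs=1e-6)

    def test_no_smoothed_mass_before_step(self):
        """The causal pre-boundary kernel must not leak the response
        backward across stimulus onset."""
        counts = np.zeros((50, 1200), dtype=int)
        counts[:, 600:] = 1  # step at t = 0
        raster = SpikeRaster(counts, -600.0, 1.0, Condition(600.0))
        psth = population_psth(raster)
        before = psth.times < -1.0
        assert np.all(psth.rate[before] == 0.0)

    def test_constant_rate_preserved(self):
        counts = np.ones((20, 800), dtype=int)  # 1000 spikes/s
        raster = SpikeRaster(counts, -200.0, 1.0, Condition(600.0))
        psth = population_psth(raster)
        np.testing.assert_allclose(psth.rate, 1000.0, rtol=1e-9)

    def test_pooled_epochs_concatenate_first150_last50(self):
        raster = step_raster(5.0, 40.0, seed=3)
        psth = population_psth(raster)
        pooled = pooled_onset_offset_psth(psth)
        assert pooled.size == 200


class TestOnsetOffset:
    def test_clean_step_detected_within_10_ms(self):
        raster = step_raster(5.0, 80.0, seed=4)  # ~10 baseline SD step
        psth = population_psth(raster)
        det = detect_onset_offset(psth)
        assert det.onset_valid and det.offset_valid
        assert det.onset_ms == pytest.approx(0.0, abs=10.0)
        assert det.offset_ms == pytest.approx(694.0, abs=10.0)

    def test_flat_trace_yields_invalid_flags(self):
        raster = step_raster(20.0, 20.0, seed=5)
        det = detect_onset_offset(population_psth(raster))
        assert not (det.onset_valid and det.offset_valid)

    def test_uniform_boost_leaves_boundaries_unchanged(self):
        """The stopwatch signature: photoexcitation-like rate boosts do not
        move detected onset/offset."""
        base = step_raster(5.0, 60.0, seed=6)
        boosted = step_raster(5.0, 90.0, seed=7)  # 1.5x in-stimulus rate
        det_a = detect_onset_offset(population_psth(base))
        det_b = detect_onset_offset(population_psth(boosted))
        assert det_b.onset_ms == pytest.approx(det_a.onset_ms, abs=5.0)
        assert det_b.offset_ms == pytest.approx(det_a.offset_ms, abs=5.0)

    def test_boost_increases_onset_to_offset_count(self):
        """The integration signature: the same boost that leaves boundaries
        fixed strictly increases the accumulated count."""
        base = step_raster(5.0, 60.0, seed=8)
        boosted = step_raster(5.0, 90.0, seed=9)
        c_a, _ = count_code(base)
        c_b, _ = count_code(boosted)
        assert c_b > c_a * 1.3

    def test_far_detections_marked_outliers(self):
        # response begins 60 ms late: onset detection is a >25 ms outlier
        rng = np.random.default_rng(10)
        times = np.arange(-600.0, 894.0)
        rate = np.where((times >= 60) & (times < 694), 80.0, 5.0)
        counts = rng.poisson(rate / 1000.0, size=(200, rate.size))
        raster = SpikeRaster(counts, -600.0, 1.0, Condition(694.0))
        det = detect_onset_offset(population_psth(raster))
        assert det.onset_outlier and not det.onset_valid


@pytest.fixture(scope="module")
def stationary_rasters():
    """Population-summed rasters at three durations, stationary rate."""
    out = {}
    for T in (334.0, 500.0, 694.0):
        rng = np.random.default_rng(int(T))
        counts = rng.poisson(50.0 / 1000.0, size=(300, int(T)))
        out[T] = SpikeRaster(counts, 0.0, 1.0, Condition(T))
    return out


class TestRateAndCountCodes:
    def test_endwindow_rate_flat_across_durations(self, stationary_rasters):
        frame = endwindow_rate(stationary_rasters, rng=0)
        rates = frame.rate_hz.to_numpy()
        spread = frame.rate_std.to_numpy()
        assert np.ptp(rates) < 3 * spread.max()

    def test_endwindow_rejects_window_longer_than_stimulus(self):
        raster = step_raster(5.0, 50.0, duration=80.0, t_start=0.0, t_stop=80.0)
        with pytest.raises(ValueError, match="exceeds"):
            endwindow_rate({"x": raster}, window_ms=100.0)

    def test_counts_ordered_by_duration(self, stationary_rasters):
        counts = [count_code(r)[0] for r in stationary_rasters.values()]
        assert counts == sorted(counts)

    def test_expected_count_is_rate_times_time(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(50.0 / 1000.0, size=(2000, 334))
        raster = SpikeRaster(counts, 0.0, 1.0, Condition(334.0))
        mean, _ = count_code(raster)
        assert mean == pytest.approx(16.7, rel=0.05)


class TestTimeToCount:
    def test_constant_rate_closed_form(self):
        rate = np.full(600, 50.0 / 1000.0)  # 50 spikes/s in spikes/ms
        t, reached = time_to_count(rate, 20.0)
        assert reached
        assert t == pytest.approx(400.0, rel=1e-6)

    def test_doubling_rate_halves_time(self):
        rate = np.full(600, 0.05)
        t1, _ = time_to_count(rate, 20.0)
        t2, _ = time_to_count(2 * rate, 20.0)
        assert t2 == pytest.approx(t1 / 2, rel=1e-6)

    def test_unreachable_target_reports_maximum(self):
        rate = np.full(100, 0.01)
        t, reached = time_to_count(rate, 50.0)
        assert not reached
        assert t == 100.0

    def test_stochastic_matches_deterministic_within_3_se(self):
        rng = np.random.default_rng(12)
        rate = np.full(600, 0.05)
        counts = rng.poisson(rate, size=(10_000, rate.size))
        raster = SpikeRaster(counts, 0.0, 1.0, Condition(600.0))
        t_mc, reached = time_to_count(raster, 10.0)
        assert reached
        # crossing time SE ~ sqrt(target)/rate / sqrt(n)
        se = np.sqrt(10.0) / 0.05 / np.sqrt(10_000)
        t_det, _ = time_to_count(rate, 10.0)
        # discrete upward-rounding bias of the per-trial crossing < 1 bin
        assert abs(t_mc - t_det) < 3 * se + 1.0

    def test_non_increasing_in_drive_amplitude(self):
        base = np.full(600, 0.05)
        times = [time_to_count(g * base, 15.0)[0] for g in (1.0, 1.5, 2.0, 3.0)]
        assert np.all(np.diff(times) < 0)


class TestIntensityCoding:
    def test_rate_coupled_neuron_classified_coding(self):
        rng = np.random.default_rng(13)
        intensities = np.repeat([34.0, 52.0, 78.0, 119.0], 30)
        rates = 10.0 + 0.2 * intensities + rng.normal(0, 2.0, intensities.size)
        result = classify_intensity_coding(rates, intensities, rng=0)
        assert result["coding"]
        assert result["p_value"] < 0.01

    def test_uncoupled_neuron_rarely_flagged(self):
        rng = np.random.default_rng(21)
        intensities = np.repeat([34.0, 52.0, 78.0, 119.0], 30)
        flagged = 0
        n_rep = 40
        for k in range(n_rep):
            rates = rng.normal(20.0, 3.0, intensities.size)
            flagged += classify_intensity_coding(
                rates, intensities, n_shuffles=400, rng=k
            )["coding"]
        assert flagged / n_rep <= 0.10  # non-coding in >= 90% of repeats

    def test_requires_multiple_intensity_levels(self):
        with pytest.raises(ValueError, match="intensity levels"):
            classify_intensity_coding(np.ones(10), np.full(10, 64.0))


@pytest.fixture(scope="module")
def neuron_rates():
    rng = np.random.default_rng(15)
    return pd.DataFrame(
        dict(
            low=rng.normal(10, 1, 40),
            high=rng.normal(20, 1, 40),
        )
    )


class TestCodingResample:
    def test_means_stable_across_seeds(self, neuron_rates):
        coding = np.r_[np.ones(30, bool), np.zeros(10, bool)]
        a = resample_coding_population(neuron_rates, coding, rng=0).mean()
        b = resample_coding_population(neuron_rates, coding, rng=1).mean()
        assert np.allclose(a, b, rtol=0.02)

    def test_full_coding_fraction_is_plain_bootstrap(self, neuron_rates):
        coding = np.ones(40, bool)
        out = resample_coding_population(neuron_rates, coding, coding_fraction=1.0,
                                         n_iter=200, rng=0)
        assert out.shape == (200, 2)
        assert out.low.mean() == pytest.approx(neuron_rates.low.mean(), rel=0.05)

    def test_single_class_pool_rejected(self, neuron_rates):
        with pytest.raises(ValueError, match="non-coding"):
            resample_coding_population(neuron_rates, np.ones(40, bool), 0.9)


class TestLnpIntegration:
    def test_simulated_photoexcitation_preserves_boundaries_but_adds_spikes(self):
        """End-to-end restatement of the stopwatch/integration dissociation
        on LNP-simulated populations."""
        neuron = NeuronParams(
            i0=-0.5, i1_ss=0.6, i1_peak=1.5, i2_ss=0.3, i2_peak=0.8,
            lambda_max=0.08, upsilon=1.0,
        )
        results = {}
        for label, opto in (("off", 0.0), ("on", 1.0)):
            cond = Condition(694.0, opto_gain=opto, t_start_ms=-600.0, t_stop_ms=894.0)
            rasters = [
                simulate_spikes(neuron, cond, 100, rng=k) for k in range(30)
            ]
            psth = population_psth(rasters)
            det = detect_onset_offset(psth)
            count, _ = count_code(summed_raster(rasters))
            results[label] = (det, count)
        det_off, count_off = results["off"]
        det_on, count_on = results["on"]
        assert det_off.onset_valid and det_on.onset_valid
        assert det_on.onset_ms == pytest.approx(det_off.onset_ms, abs=10.0)
        assert det_on.offset_ms == pytest.approx(det_off.offset_ms, abs=10.0)
        assert count_on > count_off * 1.05
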