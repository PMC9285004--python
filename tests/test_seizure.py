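"""Seizure-envelope detection and network metrics.

Covers baseline auto-selection, the two activity streams against direct
recomputation oracles, the two-window continuity rule, envelope
detection on synthetic seizures with known ground truth, and the
distance/duration/speed formulas on hand-computed toy inputs.
"""

import warnings

import numpy as np
import pytest

from mealfp import (
    ChannelGroup,
    ChannelID,
    ActivitySeries,
    SeizureEnvelope,
    SeizureParams,
    TimeRange,
    ValidationError,
    continuity_filter,
    detect_lfp_activity,
    detect_seizure_envelopes,
    detect_spectral_activity,
    find_initiators,
    max_spread_distance,
    propagation_speed,
    select_baseline,
    sle_durations,
    sle_group_metrics,
    stft_magnitude,
)
from mealfp.seizure import BaselineStats
from mealfp.synth import ScenarioConfig, generate_scenario
from oracles import naive_continuity_intervals

FS = 300.0


def noise_trace(seed, duration_s=180.0, sd=0.02):
    rng = np.random.default_rng(seed)
    return rng.normal(0, sd, size=int(duration_s * FS))


def sle_trace(seed, onset_s=120.0, duration_s=30.0, total_s=180.0):
    ch = ChannelID(1, 1)
    cfg = ScenarioConfig(
        rows=1, cols=1, duration_s=total_s, sle_origin=ch,
        sle_onset_s=onset_s, sle_duration_s=duration_s, seed=seed,
    )
    rec, truth = generate_scenario(cfg)
    return rec.traces[0].astype(float), truth


class TestSelectBaseline:
    def test_tied_scores_pick_earliest_window(self):
        # 10 s-periodic noise makes every candidate window identical, so
        # the tie breaks to the earliest one
        block = np.random.default_rng(0).normal(0, 0.02, size=int(10 * FS))
        x = np.tile(block, 30)
        stats = select_baseline(x, FS)
        assert stats.window.start_s == 0.0
        assert stats.window.duration_s == 60.0
        assert stats.voltage_sd_mv == pytest.approx(0.02, rel=0.05)

    def test_burst_window_avoided(self):
        x = noise_trace(1, 300.0)
        burst = np.arange(int(100 * FS), int(120 * FS))
        x[burst] += 0.5 * np.sin(2 * np.pi * 8 * burst / FS)
        stats = select_baseline(x, FS)
        assert stats.window.end_s <= 100.0 or stats.window.start_s >= 120.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            select_baseline(noise_trace(0, 30.0), FS)

    def test_searches_only_first_five_minutes(self):
        # even if the tail is quieter, the window stays in the search span
        x = noise_trace(2, 600.0)
        x[: int(300 * FS)] *= 2.0
        stats = select_baseline(x, FS)
        assert stats.window.end_s <= 300.0


class TestActivityStreams:
    def _baseline(self, x):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return select_baseline(x, FS)

    def test_constant_spectrum_inactive(self):
        x = noise_trace(3)
        stats = self._baseline(x)
        frame = stft_magnitude(x, FS)
        flat = BaselineStats(
            window=stats.window,
            voltage_mean_mv=stats.voltage_mean_mv,
            voltage_sd_mv=stats.voltage_sd_mv,
            spectral_mean=float(np.mean(frame.summed_magnitude)),
            spectral_sd=float(np.std(frame.summed_magnitude)),
            baseline_mv=stats.baseline_mv,
        )
        series = detect_spectral_activity(frame, flat)
        # all bins near the mean: nothing exceeds mean + 6 SD
        assert not series.active.any()

    def test_threshold_is_mean_plus_k_sd(self):
        frame = stft_magnitude(noise_trace(4, 20.0), FS)
        base = BaselineStats(
            window=TimeRange(0, 60), voltage_mean_mv=0, voltage_sd_mv=1,
            spectral_mean=1.0, spectral_sd=0.5, baseline_mv=0.0,
        )
        frame.summed_magnitude = np.array([1.0, 1.0 + 6 * 0.5, 1.0 + 7 * 0.5] * 5)
        series = detect_spectral_activity(frame, base)
        expected = frame.summed_magnitude > 1.0 + 6 * 0.5
        np.testing.assert_array_equal(series.active, expected)

    def test_spectral_oracle_random_magnitudes(self, rng):
        frame = stft_magnitude(noise_trace(5, 20.0), FS)
        frame.summed_magnitude = rng.uniform(0, 5, size=len(frame.summed_magnitude))
        base = BaselineStats(
            window=TimeRange(0, 60), voltage_mean_mv=0, voltage_sd_mv=1,
            spectral_mean=2.0, spectral_sd=0.3, baseline_mv=0.0,
        )
        series = detect_spectral_activity(frame, base)
        np.testing.assert_array_equal(
            series.active, [m > 2.0 + 6 * 0.3 for m in frame.summed_magnitude]
        )

    def test_zero_spectral_sd_rejected(self):
        frame = stft_magnitude(np.zeros(3000), FS)
        base = BaselineStats(
            window=TimeRange(0, 10), voltage_mean_mv=0, voltage_sd_mv=1,
            spectral_mean=0.0, spectral_sd=0.0, baseline_mv=0.0,
        )
        with pytest.raises(ValidationError):
            detect_spectral_activity(frame, base)

    def test_noise_false_positive_fraction(self):
        # at 6 SD with the width gate, noise marks < 0.1% of samples
        fractions = []
        for seed in range(20):
            x = noise_trace(seed, 120.0)
            stats = self._baseline(x)
            series = detect_lfp_activity(x, FS, stats)
            fractions.append(series.active.mean())
        assert np.mean(fractions) < 1e-3

    def test_injected_events_all_marked(self):
        # 1 mV, 0.05 s monophasic events on 0.02 mV noise: every one marked
        x = noise_trace(60, 120.0)
        event_times = [70.0, 80.0, 90.0]
        t = np.arange(x.size) / FS
        for tc in event_times:
            rel = (t - tc) / 0.05
            lobe = np.sin(np.pi * rel)
            lobe[(rel < 0) | (rel > 1)] = 0
            x += 1.0 * lobe
        stats = self._baseline(x)
        series = detect_lfp_activity(x, FS, stats)
        for tc in event_times:
            i = int((tc + 0.025) * FS)  # event apex
            assert series.active[i - 3 : i + 4].any()

    def test_zero_trace_rejected(self):
        base = BaselineStats(
            window=TimeRange(0, 60), voltage_mean_mv=0, voltage_sd_mv=0,
            spectral_mean=0, spectral_sd=0, baseline_mv=0,
        )
        with pytest.raises(ValidationError):
            detect_lfp_activity(np.zeros(36000), FS, base)


class TestContinuityFilter:
    def _series(self, active, dt=1.0, stream="lfp"):
        active = np.asarray(active, dtype=bool)
        return ActivitySeries(times=np.arange(active.size) * dt, active=active, stream=stream)

    def test_all_inactive_empty(self):
        assert continuity_filter(self._series(np.zeros(100)), 5, 30) == []

    def test_solid_block_single_interval(self):
        active = np.zeros(300, dtype=bool)
        active[100:190] = True  # 3 x window_long of solid activity
        out = continuity_filter(self._series(active), 5, 30)
        assert len(out) == 1
        assert out[0].start_s == pytest.approx(100, abs=5)
        assert out[0].end_s == pytest.approx(190, abs=5)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValidationError):
            continuity_filter(self._series(np.ones(10)), 5, 30)

    def test_matches_naive_oracle(self, rng):
        params = SeizureParams()
        for _ in range(50):
            active = rng.random(int(rng.integers(600, 2000))) < rng.uniform(0.02, 0.3)
            series = self._series(active)
            got = continuity_filter(series, 30, 500, params)
            expected = naive_continuity_intervals(
                active, 30, 500,
                params.density_cutoff_short, params.density_cutoff_long,
            )
            assert [(r.start_s, r.end_s) for r in got] == [
                (float(s), float(e)) for s, e in expected
            ]


class TestEnvelopeDetection:
    def test_pure_noise_has_no_envelopes(self):
        for seed in range(20):
            assert detect_seizure_envelopes(noise_trace(seed, 120.0), FS) == []

    def test_synthetic_sle_recovered(self):
        for seed in range(5):
            x, truth = sle_trace(seed)
            envs = detect_seizure_envelopes(x, FS)
            assert len(envs) == 1
            assert abs(envs[0].start_s - 120.0) <= 2.0
            assert abs(envs[0].duration_s - 30.0) <= 5.0

    def test_short_burst_rejected(self):
        # 8 s of seizure-like activity is below the 10 s minimum
        x, _ = sle_trace(1, duration_s=8.0)
        assert detect_seizure_envelopes(x, FS) == []

    def test_deterministic(self):
        x, _ = sle_trace(2)
        a = detect_seizure_envelopes(x, FS)
        b = detect_seizure_envelopes(x, FS)
        assert a == b

    def test_envelope_time_monotone_in_multipliers(self):
        x, _ = sle_trace(3)
        totals = []
        for k in (4.0, 6.0, 8.0, 12.0):
            params = SeizureParams(spectral_k=k, voltage_k=k)
            envs = detect_seizure_envelopes(x, FS, params)
            totals.append(sum(e.duration_s for e in envs))
        assert totals == sorted(totals, reverse=True)


class TestInitiators:
    def _envs(self, starts):
        out = {}
        for i, s in enumerate(starts):
            ch = ChannelID.from_linear(i + 1)
            out[ch] = [SeizureEnvelope(ch, s, s + 30.0)]
        return out

    def test_single_channel(self):
        envs = self._envs([12.0])
        assert find_initiators(envs, TimeRange(0, 100)) == {ChannelID.from_linear(1)}

    def test_same_bin_rule(self):
        # starts 10.0 and 10.4 share the 1 s bin; 13.0 does not
        envs = self._envs([10.0, 10.4, 13.0])
        got = find_initiators(envs, TimeRange(0, 100), bin_s=1.0)
        assert got == {ChannelID.from_linear(1), ChannelID.from_linear(2)}

    def test_random_starts_match_min_bin_oracle(self, rng):
        for _ in range(50):
            starts = rng.uniform(0, 50, size=int(rng.integers(1, 30)))
            envs = self._envs(starts)
            got = find_initiators(envs, TimeRange(0, 100), bin_s=1.0)
            t_min = starts.min()
            expected = {
                ChannelID.from_linear(i + 1)
                for i, s in enumerate(starts)
                if int(s) == int(t_min)
            }
            assert got == expected

    def test_no_envelopes_signalled(self):
        with pytest.raises(ValidationError):
            find_initiators({}, TimeRange(0, 100))


class TestNetworkMetrics:
    def test_single_channel_zero_distance(self):
        ch = {ChannelID(5, 5)}
        assert max_spread_distance(ch, ch, 60.0) == 0.0

    def test_ten_grid_units_at_60um(self):
        init = {ChannelID(1, 1)}
        part = {ChannelID(1, 1), ChannelID(1, 6), ChannelID(1, 11)}
        assert max_spread_distance(part, init, 60.0) == pytest.approx(600.0)

    def test_multiple_initiators_exhaustive_max(self, rng):
        part = {
            ChannelID.from_linear(int(k) + 1)
            for k in rng.choice(4096, size=50, replace=False)
        }
        init = set(list(part)[:3])
        got = max_spread_distance(part, init, 60.0)
        expected = max(i.distance_to(p, 60.0) for i in init for p in part)
        assert got == expected

    def test_empty_sets_rejected(self):
        with pytest.raises(ValidationError):
            max_spread_distance(set(), set(), 60.0)

    def test_duration_end_minus_start(self):
        ch = ChannelID(1, 1)
        envs = {ch: [SeizureEnvelope(ch, 100.0, 130.0)]}
        per, mean_s, max_s = sle_durations(envs, TimeRange(0, 200))
        assert per[ch] == 30.0 and mean_s == 30.0 and max_s == 30.0

    def test_mean_and_max_duration(self):
        envs = {}
        for i, d in enumerate([10.0, 20.0, 30.0]):
            ch = ChannelID.from_linear(i + 1)
            envs[ch] = [SeizureEnvelope(ch, 50.0, 50.0 + d)]
        _, mean_s, max_s = sle_durations(envs, TimeRange(0, 200))
        assert mean_s == 20.0 and max_s == 30.0

    def test_speed_distance_over_lag(self):
        # initiator at t=0 plus one channel 600 um away starting 2 s later
        a, b = ChannelID(1, 1), ChannelID(1, 11)
        envs = {
            a: [SeizureEnvelope(a, 0.0, 30.0)],
            b: [SeizureEnvelope(b, 2.0, 30.0)],
        }
        speed, defined = propagation_speed(envs, TimeRange(0, 100), {a}, 600.0, 60.0)
        assert defined and speed == pytest.approx(300.0)

    def test_simultaneous_starts_undefined(self):
        a, b = ChannelID(1, 1), ChannelID(1, 2)
        envs = {
            a: [SeizureEnvelope(a, 5.0, 30.0)],
            b: [SeizureEnvelope(b, 5.0, 30.0)],
        }
        speed, defined = propagation_speed(envs, TimeRange(0, 100), {a, b}, 60.0, 60.0)
        assert not defined and speed is None

    def test_group_without_sle_reports_empty(self):
        g = ChannelGroup("g", [ChannelID(1, 1), ChannelID(1, 2)])
        m = sle_group_metrics({}, g, TimeRange(0, 100), 60.0)
        assert not m.has_sle
        assert m.participating == set() and m.max_distance_um is None

    def test_metrics_independent_of_channel_order(self):
        chans = [ChannelID(1, i) for i in range(1, 6)]
        envs = {
            ch: [SeizureEnvelope(ch, 10.0 + 0.5 * i, 40.0)]
            for i, ch in enumerate(chans)
        }
        g = ChannelGroup("g", chans)
        m1 = sle_group_metrics(envs, g, TimeRange(0, 100), 60.0)
        m2 = sle_group_metrics(dict(reversed(list(envs.items()))), g, TimeRange(0, 100), 60.0)
        assert m1.initiators == m2.initiators
        assert m1.max_distance_um == m2.max_distance_um
        assert m1.propagation_speed_um_s == m2.propagation_speed_um_s
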