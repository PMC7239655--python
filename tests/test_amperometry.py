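"""Event detection, spike kinetics, foot delimitation and flicker counting."""

import numpy as np
import pytest

from exopore.amperometry import (
    AmperometricEvent,
    FootStats,
    analyze_trace,
    count_excursions,
    detect_events,
    filtered_derivative,
    foot_fluctuations,
    spike_parameters,
)
from exopore.config import AnalysisConfig
from exopore.conditioning import estimate_baseline, lowpass_array
from exopore.synthetic import EventParams, SpikeGroundTruth, simulate_amperometric_trace
from exopore.trace import Trace
from conftest import embed_template, match_by_peak

RATE = 25000.0
DT = 1000.0 / RATE


def rect_pulse_trace(amp_pA, dur_ms, total_ms=4000.0, at_ms=2000.0):
    x = np.zeros(int(total_ms / DT))
    i0 = int(at_ms / DT)
    x[i0 : i0 + int(dur_ms / DT)] = amp_pA
    return Trace(x, RATE)


class TestDetection:
    def test_noise_free_template_detected_with_precise_onset(self):
        g = SpikeGroundTruth(500.0, 20.0, 0.3, 2.0)
        table = analyze_trace(embed_template(g))
        assert len(table) == 1
        assert abs(table.events[0].onset_ms - 500.0) < 0.2

    def test_subthreshold_amplitude_rejected(self):
        # peak 3 pA is below the 4 pA selection threshold
        g = SpikeGroundTruth(500.0, 3.0, 0.3, 4.0)
        assert len(analyze_trace(embed_template(g))) == 0

    def test_subthreshold_charge_rejected(self):
        # 5 pA x 1.5 ms rectangle carries 7.5 fC, below the 10 fC bound
        assert len(analyze_trace(rect_pulse_trace(5.0, 1.5))) == 0

    @pytest.mark.parametrize(
        "amp,dur,n_expected,kinetics",
        [
            (4.1, 5.0, 1, False),   # just above the 4 pA detection tier
            (3.9, 5.0, 0, None),    # just below it
            (7.1, 5.0, 1, True),    # just above the 7 pA kinetics tier
            (6.9, 5.0, 1, False),   # detected but not kinetics-eligible
            (5.0, 1.9, 0, None),    # charge just below 10 fC
            (5.0, 2.2, 1, False),   # charge just above 10 fC
            (50.0, 99.0, 1, True),  # charge just below 5000 fC
            (50.0, 101.0, 0, None), # charge just above 5000 fC
        ],
    )
    def test_selection_boundaries(self, amp, dur, n_expected, kinetics):
        table = analyze_trace(rect_pulse_trace(amp, dur))
        assert len(table) == n_expected
        if n_expected:
            assert table.events[0].kinetics_eligible == kinetics

    def test_benchmark_recall_and_precision(self):
        params = EventParams(amplitude_range_pA=(5.0, 80.0), foot_probability=0.0)
        trace, truths = simulate_amperometric_trace(
            50, params, noise_sd_pA=1.0, duration_ms=10000.0, seed=1
        )
        table = analyze_trace(trace)
        n_matched, pairs = match_by_peak(table, truths)
        assert n_matched / len(truths) >= 0.98
        assert n_matched / len(table) >= 0.98
        onset_errors = [abs(e.onset_ms - g.onset_ms) for g, e in pairs]
        assert np.median(onset_errors) < 1.0

    def test_raising_detection_threshold_is_monotone(self):
        trace, _ = simulate_amperometric_trace(
            30, EventParams(), noise_sd_pA=1.0, duration_ms=8000.0, seed=4
        )
        base = estimate_baseline(trace)
        counts = []
        for thr in (4.0, 8.0, 15.0, 30.0):
            cfg = AnalysisConfig(min_amplitude_detect_pA=thr)
            counts.append(len(detect_events(trace, base, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            detect_events(rect_pulse_trace(20.0, 5.0), None)

    def test_analysis_is_deterministic(self):
        trace, _ = simulate_amperometric_trace(
            20, EventParams(), noise_sd_pA=1.0, duration_ms=6000.0, seed=9
        )
        df1 = analyze_trace(trace).to_dataframe()
        df2 = analyze_trace(trace).to_dataframe()
        assert df1.equals(df2)

    def test_pure_noise_gives_empty_table(self):
        trace, _ = simulate_amperometric_trace(
            0, noise_sd_pA=1.0, duration_ms=5000.0, seed=2
        )
        assert len(analyze_trace(trace)) == 0

    def test_charge_additivity_over_event_windows(self):
        # amplitudes well above the selection bounds so every event is kept
        params = EventParams(amplitude_range_pA=(15.0, 80.0), foot_probability=0.0)
        trace, _ = simulate_amperometric_trace(
            10, params, noise_sd_pA=0.0, duration_ms=5000.0, seed=6,
        )
        table = analyze_trace(trace)
        assert len(table) == 10
        total = sum(e.charge_fC for e in table)
        # independent integral over the union of the detected windows
        union = 0.0
        for e in table:
            k0 = int(np.floor(e.onset_ms / DT))
            k1 = int(np.ceil(e.end_ms / DT))
            union += np.trapezoid(trace.samples[k0 : k1 + 1], dx=DT)
        assert total == pytest.approx(union, rel=0.01)


class TestSpikeParameters:
    def test_symmetric_triangle_geometry(self):
        # peak 50 pA over a 4 ms base: FWHM 2 ms, charge 100 fC
        n = int(3000 / DT)
        x = np.zeros(n)
        base = int(4.0 / DT)
        tri = np.concatenate(
            [np.linspace(0, 50, base // 2, endpoint=False),
             np.linspace(50, 0, base // 2 + 1)]
        )
        i0 = int(1000 / DT)
        x[i0 : i0 + tri.size] = tri
        e = analyze_trace(Trace(x, RATE)).events[0]
        assert e.amplitude_pA == pytest.approx(50.0, rel=1e-6)
        assert e.half_width_ms == pytest.approx(2.0, rel=0.01)
        assert e.charge_fC == pytest.approx(100.0, rel=0.01)

    def test_linear_ramp_rise_time(self):
        # 0 -> 30 pA over exactly 1 ms, then instant fall: rise time 0.4 ms
        n = int(3000 / DT)
        x = np.zeros(n)
        ramp = np.linspace(0.0, 30.0, int(1.0 / DT) + 1, endpoint=True)
        i0 = int(1000 / DT)
        x[i0 : i0 + ramp.size] = ramp
        e = analyze_trace(Trace(x, RATE)).events[0]
        assert e.rise_time_50_90_ms == pytest.approx(0.4, abs=0.01)

    def test_flicker_into_spike_uses_last_crossing_and_flags(self):
        # current exceeds 50% of the peak, dips, then rises to the peak
        n = int(200 / DT)
        x = np.zeros(n)
        i0 = int(100 / DT)
        seg = np.concatenate([
            np.full(int(1.0 / DT), 12.0),   # above 50% of the 20 pA peak
            np.full(int(1.0 / DT), 5.0),    # dip below 50%
            np.linspace(5.0, 20.0, int(0.4 / DT)),
            np.linspace(20.0, 0.0, int(3.0 / DT)),
        ])
        x[i0 : i0 + seg.size] = seg
        trace = Trace(x, RATE)
        base = estimate_baseline(trace)
        table = detect_events(trace, base)
        e = spike_parameters(trace, base, table.events[0])
        assert e.multiple_rise_crossings
        # rise measured from the final approach to the peak, not the flicker
        assert e.rise_time_50_90_ms < 0.5


class TestFootDetection:
    def _event_with_foot(self, foot_ms, foot_amp=5.0, foot_rise=0.04):
        g = SpikeGroundTruth(
            500.0, 25.0, 0.3, 2.0,
            foot_duration_ms=foot_ms,
            foot_amplitude_pA=foot_amp if foot_ms > 0 else 0.0,
            foot_rise_ms=foot_rise,
        )
        table = analyze_trace(embed_template(g, duration_ms=1500.0))
        assert len(table) == 1
        return table.events[0]

    def test_near_rectangular_foot_recovered(self):
        foot = self._event_with_foot(4.0).foot
        assert foot is not None
        assert foot.duration_ms == pytest.approx(4.0, abs=0.2)
        assert foot.charge_fC == pytest.approx(20.0, abs=1.0)
        assert foot.eligible_for_fluct

    def test_no_foot_template_reports_absent(self):
        assert self._event_with_foot(0.0).foot is None

    def test_short_foot_reported_but_not_fluctuation_eligible(self):
        foot = self._event_with_foot(1.8).foot
        assert foot is not None
        assert not foot.eligible_for_fluct

    def test_foot_duration_defines_fluctuation_eligibility(self):
        foot = self._event_with_foot(2.5).foot
        assert foot.eligible_for_fluct
        assert foot.duration_ms > 2.0


class TestFootFluctuations:
    def test_constant_noise_free_foot_counts_nothing(self):
        x = np.zeros(int(100 / DT))
        i0 = int(40 / DT)
        x[i0 : i0 + int(20 / DT)] = 5.0
        foot = FootStats(45.0, 55.0, 10.0, 5.0, 50.0, True)
        foot = foot_fluctuations(Trace(x, RATE), foot)
        assert foot.fluctuation_count == 0
        assert foot.fluctuation_frequency_kHz == 0.0
        assert foot.rms_noise_pA_per_ms == pytest.approx(0.0, abs=1e-9)

    def test_two_step_flicker_counts_two_excursions(self):
        # 5 ms plateau with one up-step and one down-step; edge ramps are
        # gentle (2.5 pA/ms) so only the internal steps cross +/-6 pA/ms
        x = np.zeros(int(100 / DT))
        i0 = int(50 / DT)
        up = np.linspace(0.0, 5.0, int(2.0 / DT), endpoint=False)
        plateau = np.full(int(5.0 / DT), 5.0)
        plateau[int(2.0 / DT) : int(3.0 / DT)] = 10.0
        down = np.linspace(5.0, 0.0, int(2.0 / DT))
        seg = np.concatenate([up, plateau, down])
        x[i0 : i0 + seg.size] = seg
        foot = FootStats(52.0, 57.0, 5.0, 5.0, 25.0, True)
        foot = foot_fluctuations(Trace(x, RATE), foot)
        assert foot.fluctuation_count == 2
        assert foot.fluctuation_frequency_kHz == pytest.approx(0.4)

    def test_counts_match_brute_force_scan(self, rng):
        def brute(arr, thr):
            c, inpos, inneg = 0, False, False
            for v in arr:
                if v > thr and not inpos:
                    c += 1
                inpos = v > thr
                if v < -thr and not inneg:
                    c += 1
                inneg = v < -thr
            return c

        for _ in range(30):
            d = rng.normal(0.0, 6.0, rng.integers(10, 5000))
            assert count_excursions(d, 6.0) == brute(d, 6.0)

    def test_statistics_invariant_to_constant_offset(self):
        x = np.zeros(int(100 / DT))
        i0 = int(50 / DT)
        plateau = np.full(int(6.0 / DT), 5.0)
        plateau[int(2.0 / DT) : int(2.5 / DT)] = 11.0
        x[i0 : i0 + plateau.size] = plateau
        foot = lambda: FootStats(51.0, 55.5, 4.5, 5.0, 25.0, True)
        f1 = foot_fluctuations(Trace(x, RATE), foot())
        f2 = foot_fluctuations(Trace(x + 40.0, RATE), foot())
        assert f1.fluctuation_count == f2.fluctuation_count
        assert f1.rms_noise_pA_per_ms == pytest.approx(f2.rms_noise_pA_per_ms)

    def test_short_ineligible_foot_left_unfilled(self):
        x = np.zeros(int(100 / DT))
        foot = FootStats(50.0, 51.5, 1.5, 5.0, 7.5, False)
        foot = foot_fluctuations(Trace(x, RATE), foot)
        assert foot.fluctuation_count is None
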