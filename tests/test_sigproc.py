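"""Detection, spectral extraction and cross-section estimation."""

import numpy as np
import pandas as pd
import pytest

import wingbeat as wb
from wingbeat.sigproc import Segment, UnusableEventError, NonInsectError


def _insect(freq=180.0, duration=0.1, noise=0.0, **kw):
    spec = wb.WaveformSpec(
        wingbeat_freq=freq, transit_duration=duration, noise_sd=noise, **kw
    )
    return wb.simulate_transit_waveform(spec)


class TestDetect:
    def test_flat_trace_empty(self, instrument):
        sig = wb.TransitSignal(np.full(40_000, 3.0))
        assert wb.detect_transits(sig, instrument) == []

    def test_single_transit_covers_support(self, instrument):
        sig = _insect()
        segs = wb.detect_transits(sig, instrument)
        assert len(segs) == 1
        # ground-truth support: noiseless samples below the trigger level
        v = sig.samples
        level = np.median(v) * (1 - instrument.detection_threshold)
        support = np.flatnonzero(v < level)
        seg = segs[0]
        covered = np.mean((support >= seg.start) & (support < seg.stop))
        assert covered >= 0.9

    def test_short_dip_excluded(self, instrument):
        sig = _insect(freq=400.0, duration=0.005)
        assert wb.detect_transits(sig, instrument) == []

    def test_slow_flapper_not_fragmented(self, instrument):
        sig = _insect(freq=25.0, duration=1.0)
        assert len(wb.detect_transits(sig, instrument)) == 1

    def test_overlong_event_truncated_and_flagged(self):
        cfg = wb.InstrumentConfig(max_duration=0.05)
        sig = _insect(duration=0.2)
        segs = wb.detect_transits(sig, cfg)
        assert len(segs) == 1
        assert segs[0].truncated
        assert segs[0].duration(sig.sampling_rate) <= 0.05 + 1.0 / sig.sampling_rate


class TestBaseline:
    def test_noiseless_exact(self, instrument):
        # the flank abuts the sub-threshold transit tail, so the median sits
        # within a few mV of the true background rather than exactly on it
        sig = _insect()
        seg = wb.detect_transits(sig, instrument)[0]
        assert wb.estimate_baseline(sig, seg) == pytest.approx(3.0, abs=0.005)

    def test_noisy_median_accuracy(self, instrument):
        sig = _insect(noise=0.01)
        seg = wb.detect_transits(sig, instrument)[0]
        assert wb.estimate_baseline(sig, seg) == pytest.approx(3.0, abs=0.005)

    def test_edge_segment_uses_one_flank(self, instrument):
        sig = _insect()
        seg = wb.detect_transits(sig, instrument)[0]
        # cut the trace so the segment starts at sample 0: right flank only
        cut = wb.TransitSignal(sig.samples[seg.start :], sig.sampling_rate)
        edge = Segment(0, seg.n)
        assert wb.estimate_baseline(cut, edge) == pytest.approx(3.0, abs=0.02)

    def test_no_flanks_raises(self, instrument):
        sig = wb.TransitSignal(np.full(100, 2.0))
        with pytest.raises(UnusableEventError):
            wb.estimate_baseline(sig, Segment(0, 100))


class TestLevels:
    def test_closed_form_depths(self, instrument):
        sig = _insect(duration=0.1)
        seg = wb.detect_transits(sig, instrument)[0]
        v_body, v_wing = wb.estimate_levels(sig, seg, instrument, freq=180.0)
        assert v_wing == pytest.approx(3.0 - 1.2, rel=0.03)
        assert v_body == pytest.approx(3.0 - 0.6, rel=0.03)

    def test_no_modulation_levels_coincide(self, instrument):
        sig = _insect(wing_depth=0.0, body_depth=0.8)
        seg = wb.detect_transits(sig, instrument)[0]
        v_body, v_wing = wb.estimate_levels(sig, seg, instrument)
        assert v_body == v_wing

    def test_ordering_invariant(self, instrument):
        sig = _insect(noise=0.01)
        seg = wb.detect_transits(sig, instrument)[0]
        v0 = wb.estimate_baseline(sig, seg)
        v_body, v_wing = wb.estimate_levels(sig, seg, instrument, freq=180.0)
        assert v_wing <= v_body <= v0

    def test_too_few_samples(self, instrument):
        sig = wb.TransitSignal(np.full(8, 3.0))
        with pytest.raises(UnusableEventError):
            wb.estimate_levels(sig, Segment(0, 8), instrument)


class TestCrossSections:
    @pytest.mark.parametrize(
        "v0,vw,vb,expect_w,expect_b",
        [
            (3.0, 2.4, 2.7, 400.0, 200.0),
            (3.0, 3.0, 3.0, 0.0, 0.0),
            (2.0, 1.0, 1.5, 1000.0, 500.0),
        ],
    )
    def test_arithmetic(self, v0, vw, vb, expect_w, expect_b):
        cfg = wb.InstrumentConfig(beam_area_A=2000.0)
        sw, sb = wb.cross_sections(v0, vw, vb, cfg)
        assert sw == pytest.approx(expect_w)
        assert sb == pytest.approx(expect_b)

    def test_zero_background_rejected(self, instrument):
        with pytest.raises(UnusableEventError):
            wb.cross_sections(0.0, 0.0, 0.0, instrument)

    @pytest.mark.parametrize(
        "sw,sb,expect", [(400.0, 200.0, 2 / 3), (5.0, 5.0, 0.5), (0.0, 7.0, 0.0)]
    )
    def test_ratio(self, sw, sb, expect):
        assert wb.wing_body_ratio(sw, sb) == pytest.approx(expect)

    def test_ratio_undefined_for_zero_total(self):
        with pytest.raises(UnusableEventError):
            wb.wing_body_ratio(0.0, 0.0)


class TestFrequencyExtraction:
    @pytest.mark.parametrize("freq", list(range(25, 701, 25)))
    def test_round_trip_noiseless(self, freq, instrument):
        """Across the insect band, the extracted fundamental matches the
        generating frequency within 2 Hz on noiseless waveforms."""
        duration = min(1.0, max(0.2, 25.0 / freq))
        sig = _insect(freq=float(freq), duration=duration)
        seg = wb.detect_transits(sig, instrument)[0]
        f = wb.extract_wingbeat_frequency(sig, seg, instrument)
        assert abs(f - freq) <= 2.0

    @pytest.mark.parametrize("freq", [50.0, 180.0, 400.0])
    def test_cross_section_round_trip(self, freq, instrument):
        """Extracted cross-sections match the closed-form values implied by
        the generating depths within 2%."""
        sig = _insect(freq=freq, duration=0.5)
        seg = wb.detect_transits(sig, instrument)[0]
        f = wb.extract_wingbeat_frequency(sig, seg, instrument)
        v0 = wb.estimate_baseline(sig, seg)
        v_body, v_wing = wb.estimate_levels(sig, seg, instrument, freq=f)
        sw, sb = wb.cross_sections(v0, v_wing, v_body, instrument)
        A = instrument.beam_area_A
        assert sw == pytest.approx(0.4 * A, rel=0.02)
        assert sb == pytest.approx(0.2 * A, rel=0.02)

    def test_strong_harmonic_not_mistaken_for_fundamental(self, instrument):
        """A 200 Hz harmonic 1.2x taller than the 100 Hz fundamental must
        not capture the estimate: the fundamental is the lowest prominent
        peak whose taller peers are integer multiples."""
        sig = _insect(freq=100.0, duration=0.2, harmonic_amps=(1.2, 0.3))
        seg = wb.detect_transits(sig, instrument)[0]
        f = wb.extract_wingbeat_frequency(sig, seg, instrument)
        assert f == pytest.approx(100.0, abs=2.0)

    def test_pure_dip_has_no_fundamental(self, instrument):
        sig = wb.simulate_droplet_waveform(0.1, depth=0.8)
        seg = wb.detect_transits(sig, instrument)[0]
        with pytest.raises(NonInsectError):
            wb.extract_wingbeat_frequency(sig, seg, instrument)


class TestClassification:
    def test_droplet_is_non_insect(self, instrument):
        for noise in (0.0, 0.01):
            sig = wb.simulate_droplet_waveform(0.12, 0.8, noise_sd=noise, seed=1)
            seg = wb.detect_transits(sig, instrument)[0]
            assert wb.classify_event(sig, seg, instrument) == "non_insect"

    def test_insect_is_insect(self, instrument):
        sig = _insect(noise=0.005)
        seg = wb.detect_transits(sig, instrument)[0]
        assert wb.classify_event(sig, seg, instrument) == "insect"

    def test_six_ms_event_fails_duration_rule(self, instrument):
        """Even a modulated segment is rejected when shorter than 10 ms."""
        sig = _insect(freq=400.0, duration=0.1)
        n6 = int(0.006 * sig.sampling_rate)
        centre = np.argmin(sig.samples)
        seg = Segment(centre - n6 // 2, centre + n6 // 2)
        assert wb.classify_event(sig, seg, instrument) == "non_insect"


class TestExtractEvents:
    def test_counts_reconcile_over_mixed_traces(self, instrument):
        """Every detected segment is counted exactly once."""
        rng = np.random.default_rng(0)
        traces = [
            _insect(freq=float(f), noise=0.005)
            for f in rng.uniform(50, 600, size=5)
        ] + [
            wb.simulate_droplet_waveform(0.1, 0.8, noise_sd=0.005, seed=int(s))
            for s in range(3)
        ]
        total = {"detected": 0, "insect": 0, "non_insect": 0, "unusable": 0}
        events = []
        for sig in traces:
            evs, counts = wb.extract_events(sig, instrument)
            events.extend(evs)
            for key in total:
                total[key] += counts[key]
        assert total["detected"] == (
            total["insect"] + total["non_insect"] + total["unusable"]
        )
        assert total["insect"] == len(events) == 5
        assert total["non_insect"] == 3
        for ev in events:
            assert ev.v_wing <= ev.v_body <= ev.v0
            assert 0.0 <= ev.ratio <= 1.0
            assert 0.0 <= ev.sigma_b <= ev.sigma_w <= instrument.beam_area_A
            assert instrument.band[0] <= ev.freq <= instrument.band[1]


class TestAttachTemperature:
    @pytest.fixture()
    def weather(self):
        ts = pd.date_range("2022-06-01 12:00", periods=120, freq="1min")
        return pd.DataFrame(
            {
                "timestamp_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                "temperature_C": np.linspace(20.0, 26.0, ts.size).round(3),
            }
        )

    def test_nearest_record_wins(self, weather):
        events = pd.DataFrame(
            {"timestamp_iso8601": ["2022-06-01T12:00:20", "2022-06-01T12:00:40"]}
        )
        out = wb.attach_temperature(events, weather)
        assert out.loc[0, "temperature_C"] == weather.loc[0, "temperature_C"]
        assert out.loc[1, "temperature_C"] == weather.loc[1, "temperature_C"]
        assert not out["temp_stale"].any()

    def test_exact_match(self, weather):
        events = pd.DataFrame({"timestamp_iso8601": ["2022-06-01T12:30:00"]})
        out = wb.attach_temperature(events, weather)
        assert out.loc[0, "temperature_C"] == weather.loc[30, "temperature_C"]

    def test_stale_event_flagged(self, weather):
        events = pd.DataFrame({"timestamp_iso8601": ["2022-06-01T16:00:00"]})
        out = wb.attach_temperature(events, weather)
        assert bool(out.loc[0, "temp_stale"])

    def test_empty_weather_rejected(self, weather):
        with pytest.raises(ValueError, match="empty"):
            wb.attach_temperature(
                pd.DataFrame({"timestamp_iso8601": ["2022-06-01T12:00:00"]}),
                weather.iloc[0:0],
            )
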