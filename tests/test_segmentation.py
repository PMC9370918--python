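import numpy as np
import pytest

from liftkin import (
    AngleSeries,
    Event,
    build_events,
    detect_troughs,
    event_bounds,
    palletization_subset,
    time_normalize,
)
from liftkin.segmentation import LOAD_MAP
from conftest import ground_truth_palletization

RATE = 50.0


class TestDetectTroughs:
    def test_recovers_generated_deep_dips(self, default_session):
        ts, gt = default_session
        c7z = ts.marker("C7")[:, 2]
        troughs = detect_troughs(c7z, ts.rate, k=24)
        assert len(troughs) == 24
        truth = gt.events[gt.events.ground].trough_s.unique()
        truth.sort()
        np.testing.assert_allclose(troughs / ts.rate, truth, atol=0.1)

    def test_monotone_signal_has_no_minima(self):
        with pytest.raises(ValueError, match="0 admissible"):
            detect_troughs(np.linspace(0, 1, 1000), RATE, k=1)

    def test_single_parabola_dip(self):
        t = np.arange(500) / RATE
        sig = (t - 5.0) ** 2
        (frame,) = detect_troughs(sig, RATE, k=1)
        assert abs(frame - 250) <= 2

    def test_offset_invariance_and_shift_equivariance(self):
        rng = np.random.default_rng(0)
        t = np.arange(3000) / RATE
        sig = np.cos(2 * np.pi * t / 15.0) + 0.01 * rng.standard_normal(len(t))
        base = detect_troughs(sig, RATE, k=3)
        offset = detect_troughs(sig + 123.4, RATE, k=3)
        np.testing.assert_array_equal(base, offset)
        shift = 200
        shifted = detect_troughs(np.r_[sig[:shift][::-1], sig], RATE, k=3)
        inner = shifted[(shifted > shift + 100) & (shifted < len(sig))]
        np.testing.assert_allclose(inner - shift, base[: len(inner)], atol=2)


class TestPalletizationSubset:
    def test_first_twelve_of_twentyfour(self):
        troughs = np.arange(24) * 100
        np.testing.assert_array_equal(
            palletization_subset(troughs, 12), troughs[:12]
        )

    def test_exactly_twelve_pass_through(self):
        troughs = np.arange(12) * 100
        np.testing.assert_array_equal(palletization_subset(troughs, 12), troughs)

    def test_too_few_troughs_rejected(self):
        with pytest.raises(ValueError, match="12"):
            palletization_subset(np.arange(10) * 100, 12)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            palletization_subset(np.array([500, 100, 300]), 2)


class TestEventBounds:
    @staticmethod
    def _raised_cosine(onset_s=4.0, ttp=2.0, t_str=1.8, peak=55.0, base=5.0,
                       n=1000):
        t = np.arange(n) / RATE
        y = np.full(n, base)
        rise = (t >= onset_s) & (t <= onset_s + ttp)
        y[rise] = base + (peak - base) * 0.5 * (
            1 - np.cos(np.pi * (t[rise] - onset_s) / ttp)
        )
        fall = (t > onset_s + ttp) & (t <= onset_s + ttp + t_str)
        y[fall] = base + (peak - base) * 0.5 * (
            1 + np.cos(np.pi * (t[fall] - onset_s - ttp) / t_str)
        )
        return AngleSeries(y, "trunk_inclination", RATE), onset_s, ttp, t_str

    def test_bounds_near_known_onset_offset(self):
        ang, onset, ttp, t_str = self._raised_cosine()
        trough = int((onset + ttp) * RATE)
        start, end, flags = event_bounds(ang, trough, 6.0, 5.0)
        assert flags == ()
        assert start / RATE == pytest.approx(onset, abs=0.1)
        assert end / RATE == pytest.approx(onset + ttp + t_str, abs=0.1)

    def test_flat_signal_falls_back_to_window_edges(self):
        ang = AngleSeries(np.full(1000, 30.0), "trunk_inclination", RATE)
        start, end, flags = event_bounds(ang, 500, 4.0, 5.0)
        assert start == 500 - 200 and end == 500 + 200
        assert "start_at_window_edge" in flags and "end_at_window_edge" in flags

    def test_zero_threshold_collapses_to_window_edges(self):
        ang, onset, ttp, _ = self._raised_cosine()
        trough = int((onset + ttp) * RATE)
        start, end, flags = event_bounds(ang, trough, 3.0, 0.0)
        assert start == trough - 150 and end == trough + 150

    def test_window_clipped_at_session_boundary(self):
        ang, onset, ttp, _ = self._raised_cosine(onset_s=1.0, n=400)
        trough = int((onset + ttp) * RATE)
        *_, flags = event_bounds(ang, trough, 6.0, 5.0)
        assert "window_clipped" in flags


class TestBuildEvents:
    @staticmethod
    def _troughs_and_bounds(k):
        troughs = 100 + np.arange(k) * 300
        bounds = [(int(t) - 80, int(t) + 80, ()) for t in troughs]
        return troughs, bounds

    def test_twelve_troughs_make_twentyfour_labelled_events(self):
        troughs, bounds = self._troughs_and_bounds(12)
        es = build_events(troughs, bounds, RATE)
        assert len(es) == 24
        for action, phase, load, n in (
            ("picking", "bending", "unloaded", 6),
            ("picking", "straightening", "loaded", 6),
            ("placing", "bending", "loaded", 6),
            ("placing", "straightening", "unloaded", 6),
        ):
            sel = es.select(action=action, phase=phase)
            assert len(sel) == n
            assert all(e.load == load for e in sel)
            assert [e.repeat_index for e in sel] == list(range(1, 7))

    def test_first_action_placing_flips_labels(self):
        troughs, bounds = self._troughs_and_bounds(4)
        pick_first = build_events(troughs, bounds, RATE, first_action="picking")
        place_first = build_events(troughs, bounds, RATE, first_action="placing")
        flip = {"picking": "placing", "placing": "picking"}
        for a, b in zip(pick_first, place_first):
            assert b.action == flip[a.action]
            assert b.load == LOAD_MAP[(b.action, b.phase)]

    def test_two_troughs_give_four_events(self):
        troughs, bounds = self._troughs_and_bounds(2)
        es = build_events(troughs, bounds, RATE)
        assert len(es) == 4
        assert {e.repeat_index for e in es} == {1}

    def test_odd_trough_count_flags_last_pair(self):
        troughs, bounds = self._troughs_and_bounds(3)
        es = build_events(troughs, bounds, RATE)
        assert len(es) == 6
        assert all("unpaired_trough" in e.flags for e in es.events[-2:])

    def test_events_only_overlap_at_shared_trough(self, processed_default):
        events = sorted(processed_default.events, key=lambda e: e.start_frame)
        for a, b in zip(events, events[1:]):
            assert a.end_frame <= b.start_frame or (
                a.trough_frame == b.trough_frame and a.end_frame == b.trough_frame
            )


class TestTimeNormalize:
    @staticmethod
    def _event(start, end):
        return Event(end, start, end, "bending", "picking", "unloaded")

    def test_linear_ramp_stays_linear(self):
        series = AngleSeries(np.arange(500, dtype=float), "trunk_inclination", RATE)
        prof = time_normalize(series, self._event(100, 300))
        np.testing.assert_allclose(prof.values, np.linspace(100, 300, 101), atol=1e-9)

    def test_endpoints_exact(self):
        rng = np.random.default_rng(4)
        series = AngleSeries(rng.standard_normal(400), "shoulder_flexion", RATE)
        prof = time_normalize(series, self._event(37, 251))
        assert prof.values[0] == series.values[37]
        assert prof.values[-1] == series.values[251]

    def test_matches_per_point_interpolation_oracle(self):
        t = np.arange(600) / RATE
        series = AngleSeries(np.sin(t), "trunk_inclination", RATE)
        start, end = 50, 333
        prof = time_normalize(series, self._event(start, end))
        # independent per-point linear interpolation
        for i, p in enumerate(np.linspace(0, 1, 101)):
            x = start + p * (end - start)
            lo = int(np.floor(x))
            frac = x - lo
            expect = (1 - frac) * series.values[lo] + frac * series.values[
                min(lo + 1, 599)
            ]
            assert prof.values[i] == pytest.approx(expect, abs=1e-9)

    def test_short_interval_rejected(self):
        series = AngleSeries(np.zeros(10), "trunk_inclination", RATE)
        with pytest.raises(ValueError, match="shorter"):
            time_normalize(series, self._event(5, 5))


def test_end_to_end_recovery_noise_free(processed_noise_free, noise_free_session):
    """Every ground-level palletization event is found with correct labels
    and boundaries within 0.1 s of the generator's threshold-crossing truth."""
    _, gt = noise_free_session
    det = processed_noise_free.events.to_frame()
    truth = ground_truth_palletization(gt)
    assert len(det) == len(truth) == 24
    for col in ("phase", "action", "load"):
        assert (det[col].values == truth[col].values).all()
    assert np.abs(det.start_s.values - truth.start_thr_s.values).max() < 0.1
    assert np.abs(det.end_s.values - truth.end_thr_s.values).max() < 0.1
    assert np.abs(det.trough_s.values - truth.trough_s.values).max() < 0.1
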