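"""Unit tests for the On-event detector, coincidence gating and policies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mothnav.controller import (
    OnEventDetector,
    OnEventDetectorConfig,
    OneStepPolicy,
    PolicyConfig,
    TwoStepPolicy,
    coincidence_gate,
    on_event_stream,
)


class TestDetector:
    def test_printed_rule_example(self):
        # 3 ISIs < 70 ms then silence: event at burst end + 350 ms
        events = on_event_stream([0.0, 50.0, 110.0, 175.0])
        assert np.allclose(events, [525.0])

    def test_long_isis_never_arm(self):
        events = on_event_stream(np.arange(0.0, 2000.0, 80.0))
        assert events.size == 0

    def test_two_bursts_two_events(self):
        burst = np.array([0.0, 40.0, 80.0, 120.0])
        spikes = np.concatenate([burst, burst + 2000.0])
        events = on_event_stream(spikes)
        assert np.allclose(events, [470.0, 2470.0])

    def test_intervening_spike_cancels_pending_event(self):
        # a spike 200 ms after the burst (ISI in (70, 350)) resets tracking
        events = on_event_stream([0.0, 40.0, 80.0, 120.0, 320.0])
        assert events.size == 0

    def test_out_of_order_rejected(self):
        det = OnEventDetector()
        det.update(100.0)
        with pytest.raises(ValueError):
            det.update(50.0)

    def test_poll_resolves_event_online(self):
        det = OnEventDetector()
        for t in (0.0, 40.0, 80.0, 120.0):
            assert det.update(t) is None
        assert det.poll(400.0) is None         # silence not yet provable
        assert det.poll(470.0) == 470.0
        assert det.poll(1000.0) is None        # no double emission

    @given(st.lists(st.floats(0.0, 5000.0), min_size=0, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_chunked_streaming_equals_offline(self, raw):
        spikes = np.unique(np.asarray(raw))
        offline = on_event_stream(spikes)
        det = OnEventDetector()
        online = []
        for t in spikes:
            ev = det.update(float(t))
            if ev is not None:
                online.append(ev)
            # polling between spikes must not change the result
            ev = det.poll(float(t))
            if ev is not None:
                online.append(ev)
        ev = det.poll(math.inf)
        if ev is not None:
            online.append(ev)
        assert np.allclose(offline, online)
        # causality: each event time is at least the detector's ISI bound
        # after the burst's last spike, never before data justified it
        for e in offline:
            assert np.any(np.isclose(spikes + 350.0, e))


class TestCoincidence:
    def test_identical_streams_pass_through(self):
        a = np.array([1.0, 2.0, 3.0])
        assert np.allclose(coincidence_gate(a, a, 100.0), a)

    def test_disjoint_streams_empty(self):
        assert coincidence_gate([1.0], [10.0], 0.5).size == 0

    def test_later_of_matched_pair(self):
        out = coincidence_gate([1.0], [1.05], 0.1)
        assert np.allclose(out, [1.05])

    @given(
        st.lists(st.floats(0, 100), max_size=20),
        st.lists(st.floats(0, 100), max_size=20),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_never_increases_event_count(self, a, b, w):
        a = np.unique(np.asarray(a))
        b = np.unique(np.asarray(b))
        out = coincidence_gate(a, b, w)
        assert out.size <= min(a.size, b.size)


class TestPolicies:
    cfg = PolicyConfig()

    def test_no_event_means_pure_spiral(self):
        pol = OneStepPolicy(self.cfg)
        headings = [pol.command(t, 0.1).heading_rad for t in np.arange(0, 30, 0.1)]
        # spiral heading advances monotonically (never a constant surge)
        assert np.all(np.diff(headings) > 0)

    def test_surge_window_after_event(self):
        pol = OneStepPolicy(self.cfg)
        pol.notify_event(10.0)
        assert pol.command(10.0, 0.1).heading_rad == 0.0
        assert pol.command(14.9, 0.1).heading_rad == 0.0
        assert pol.command(15.0, 0.1).heading_rad != 0.0

    def test_event_during_spiral_preempts_to_surge(self):
        pol = OneStepPolicy(self.cfg)
        pol.notify_event(0.0)
        for t in np.arange(0.0, 40.0, 0.1):
            pol.command(t, 0.1)
        pol.notify_event(40.0)
        assert pol.command(40.0, 0.1).heading_rad == 0.0

    def test_two_step_phase_sequence(self):
        pol = TwoStepPolicy(self.cfg)
        pol.notify_event(0.0)
        surge = pol.command(2.0, 0.1).heading_rad
        zig = pol.command(6.0, 0.1).heading_rad
        zig2 = pol.command(23.9, 0.1).heading_rad
        spiral = [pol.command(t, 0.1).heading_rad for t in np.arange(24.0, 30.0, 0.1)]
        assert surge == 0.0
        assert abs(zig) == pytest.approx(math.pi / 2)
        assert abs(zig2) == pytest.approx(math.pi / 2)
        assert np.all(np.diff(spiral) > 0)

    def test_zigzag_legs_double_and_alternate(self):
        cfg = PolicyConfig(zigzag_duration_s=200.0, zigzag_initial_m=0.25)
        pol = TwoStepPolicy(cfg)
        pol.notify_event(0.0)
        dt = 0.1
        headings = [pol.command(5.0 + k * dt, dt).heading_rad
                    for k in range(int(60.0 / dt))]
        h = np.asarray(headings)
        changes = np.nonzero(np.diff(np.sign(h)))[0]
        leg_durations = np.diff(np.concatenate([[0], changes])) * dt
        lengths = leg_durations * cfg.speed_mps
        # successive legs approximately double (turn resolution is one step)
        ratios = lengths[1:] / lengths[:-1]
        assert np.all(ratios > 1.7)
        assert np.all(ratios < 2.3)

    def test_constant_speed_contract(self):
        pol = TwoStepPolicy(self.cfg)
        pol.notify_event(0.0)
        total = sum(pol.command(t, 0.1).speed_mps * 0.1 for t in np.arange(0, 60, 0.1))
        assert total == pytest.approx(self.cfg.speed_mps * 60.0, rel=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PolicyConfig(surge_duration_s=0.0)
        with pytest.raises(ValueError):
            PolicyConfig(zigzag_factor=1.0)
        with pytest.raises(ValueError):
            OnEventDetectorConfig(isi_burst_max_ms=70.0, isi_inhib_min_ms=50.0)
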