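"""Online action selection: On-event detection and cast-surge policies.

The command neuron signals pheromone presence with an On burst followed by
SK-mediated inhibition.  The detector implements the online reading of that
signature: after ``k_burst`` consecutive interspike intervals shorter than
``isi_burst_max`` the detector arms, and the event fires at burst end +
``isi_inhib_min`` provided no spike intervenes (a spike before that restarts
burst tracking).  Event times are therefore causal: the event is emitted at
the earliest time the criterion is provably satisfied.

Policies map events to motion.  One-step casting: surge upwind for a fixed
time after each event, otherwise spiral.  Two-step casting: surge, then
crosswind zigzag with leg lengths doubling every reversal (the optimal
doubling schedule for linear search), then spiral.  A new event preempts any
casting phase and restarts the surge timer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OnEventDetectorConfig",
    "OnEventDetector",
    "on_event_stream",
    "coincidence_gate",
    "PolicyConfig",
    "MotorCommand",
    "OneStepPolicy",
    "TwoStepPolicy",
    "make_policy",
]


@dataclass(frozen=True)
class OnEventDetectorConfig:
    k_burst: int = 3
    isi_burst_max_ms: float = 70.0
    isi_inhib_min_ms: float = 350.0

    def __post_init__(self) -> None:
        if self.k_burst < 1:
            raise ValueError("k_burst must be >= 1")
        if self.isi_inhib_min_ms <= self.isi_burst_max_ms:
            raise ValueError("inhibition ISI must exceed the burst ISI bound")


class OnEventDetector:
    """Streaming On-event detector (burst followed by inhibition)."""

    def __init__(self, config: OnEventDetectorConfig = OnEventDetectorConfig()):
        self.config = config
        self._last_spike: float | None = None
        self._run = 0          # consecutive short ISIs
        self._armed = False

    def update(self, t_spike: float) -> float | None:
        """Feed one spike; returns an event time if one is resolved by it."""
        c = self.config
        event = None
        if self._last_spike is not None:
            if t_spike < self._last_spike:
                raise ValueError("spikes must arrive in time order")
            isi = t_spike - self._last_spike
            if self._armed and isi >= c.isi_inhib_min_ms:
                event = self._last_spike + c.isi_inhib_min_ms
                self._run = 0
                self._armed = False
            elif isi < c.isi_burst_max_ms:
                self._run += 1
                self._armed = self._run >= c.k_burst
            else:
                self._run = 0
                self._armed = False
        self._last_spike = t_spike
        return event

    def poll(self, t_now: float) -> float | None:
        """Resolve a pending event if enough silence has elapsed."""
        c = self.config
        if (
            self._armed
            and self._last_spike is not None
            and t_now - self._last_spike >= c.isi_inhib_min_ms
        ):
            self._armed = False
            self._run = 0
            return self._last_spike + c.isi_inhib_min_ms
        return None


def on_event_stream(
    spikes, config: OnEventDetectorConfig = OnEventDetectorConfig()
) -> np.ndarray:
    """Offline application of the online detector to a full spike list."""
    det = OnEventDetector(config)
    events = []
    for t in spikes:
        ev = det.update(float(t))
        if ev is not None:
            events.append(ev)
    ev = det.poll(math.inf)
    if ev is not None:
        events.append(ev)
    return np.asarray(events)


def coincidence_gate(events_a, events_b, window_ms: float) -> np.ndarray:
    """Two-neuron coincidence gating: emit the later of each matched pair.

    Events are matched chronologically within the window; unmatched events
    are dropped, so the output count never exceeds either input count.
    """
    a = np.asarray(events_a, dtype=float)
    b = np.asarray(events_b, dtype=float)
    out = []
    i = j = 0
    while i < a.size and j < b.size:
        if abs(a[i] - b[j]) <= window_ms:
            out.append(max(a[i], b[j]))
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return np.asarray(out)


# --------------------------------------------------------------------------
# policies


@dataclass(frozen=True)
class PolicyConfig:
    surge_duration_s: float = 5.0
    zigzag_duration_s: float = 19.0
    speed_mps: float = 0.056
    spiral_pitch_m: float = 0.3       # Archimedean pitch per turn (simulator)
    spiral_r0_m: float = 0.2          # ~ a robot turning circle
    zigzag_initial_m: float = 0.05    # 19 s at 5.6 cm/s spans 4+ doubling legs
    zigzag_factor: float = 2.0
    # per-trial casting randomization (the robot's initial heading varied):
    spiral_heading_offset_rad: float = 0.0
    spiral_direction: float = 1.0     # +1 counterclockwise, -1 clockwise
    zigzag_first_sign: float = 1.0

    def __post_init__(self) -> None:
        if self.surge_duration_s <= 0 or self.zigzag_duration_s <= 0:
            raise ValueError("phase durations must be positive")
        if self.zigzag_factor <= 1:
            raise ValueError("zigzag doubling factor must exceed 1")


@dataclass(frozen=True)
class MotorCommand:
    heading_rad: float      # relative to upwind (0 = upwind, +pi/2 = left)
    speed_mps: float
    valid_for_s: float

    def __post_init__(self) -> None:
        if self.speed_mps < 0:
            raise ValueError("speed must be >= 0")


class _CastSurgeBase:
    """Shared surge/spiral machinery; subclasses define the casting chain."""

    def __init__(self, config: PolicyConfig = PolicyConfig()):
        self.config = config
        self.last_event: float | None = None
        self._reset_casting()

    def _reset_casting(self) -> None:
        c = self.config
        self._spiral_phi = 0.0
        self._spiral_r = c.spiral_r0_m
        self._zig_leg = 0
        self._zig_into_leg = 0.0
        self._zig_sign = c.zigzag_first_sign

    def notify_event(self, t_s: float) -> None:
        """A fresh On event preempts casting and (re)starts the surge timer."""
        self.last_event = t_s
        self._reset_casting()

    # -- casting primitives -------------------------------------------
    def _spiral_heading(self, dt_s: float) -> float:
        c = self.config
        coil = c.spiral_pitch_m / (2.0 * math.pi)
        r = c.spiral_r0_m + coil * self._spiral_phi
        heading = c.spiral_heading_offset_rad + c.spiral_direction * (
            self._spiral_phi + math.atan2(r, coil))
        self._spiral_phi += c.speed_mps * dt_s / math.hypot(r, coil)
        return heading

    def _zigzag_heading(self, dt_s: float) -> float:
        c = self.config
        leg_len = c.zigzag_initial_m * c.zigzag_factor ** self._zig_leg
        self._zig_into_leg += c.speed_mps * dt_s
        heading = self._zig_sign * math.pi / 2.0
        if self._zig_into_leg >= leg_len:
            self._zig_into_leg = 0.0
            self._zig_leg += 1
            self._zig_sign = -self._zig_sign
        return heading

    def command(self, t_s: float, dt_s: float) -> MotorCommand:
        c = self.config
        since = math.inf if self.last_event is None else t_s - self.last_event
        heading = self._casting_heading(since, dt_s)
        return MotorCommand(heading_rad=heading, speed_mps=c.speed_mps, valid_for_s=dt_s)


class OneStepPolicy(_CastSurgeBase):
    """On -> surge; Off and baseline -> spiral casting."""

    def _casting_heading(self, since_event: float, dt_s: float) -> float:
        if since_event < self.config.surge_duration_s:
            return 0.0
        return self._spiral_heading(dt_s)


class TwoStepPolicy(_CastSurgeBase):
    """On -> surge; Off -> crosswind zigzag; baseline -> spiral casting."""

    def _casting_heading(self, since_event: float, dt_s: float) -> float:
        c = self.config
        if since_event < c.surge_duration_s:
            return 0.0
        if since_event < c.surge_duration_s + c.zigzag_duration_s:
            return self._zigzag_heading(dt_s)
        return self._spiral_heading(dt_s)


def make_policy(strategy: str, config: PolicyConfig = PolicyConfig()):
    if strategy == "one_step":
        return OneStepPolicy(config)
    if strategy == "two_step":
        return TwoStepPolicy(config)
    raise ValueError("strategy must be 'one_step' or 'two_step'")
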