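"""Closed-loop trial simulator.

A 2-D arena with laminar wind, a stochastic intermittent plume, and an agent
that senses pheromone patches through the full pipeline: patch encounters
drive the ORN population rate, pooled Poisson ORN spikes are filtered into a
somatic current, the command neuron converts the current into a multiphasic
spike response, the On-event detector extracts detections, and the policy
maps detections to surge/zigzag/spiral motion at constant speed.

The plume is the one deliberately invented component: the encounter rate
field is ``nu(x, y) = nu0 * exp(-(x / (w * sqrt(y_src - y)))^2)`` downwind of
the source and zero upwind, so the 90%-of-detections contour is parabolic
and detections near the start are sporadic (seconds apart on the
centerline).  All plume-dependent claims are therefore treated as ordinal,
never cardinal.

Geometry: the agent starts at (0, 0); the source sits at (0, 2) m; the fan
behind the source blows wind in the -y direction, so +y is upwind and the
plume extends from the source toward (and past) the start.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .controller import (
    OnEventDetector,
    OnEventDetectorConfig,
    PolicyConfig,
    coincidence_gate,
    make_policy,
)
from .neuron import NeuronParams, OnlineNeuron, perturb_params
from .orn import DriveKernel, ORNRateModel, StimulusProtocol, rate
from .stats import rayleigh

__all__ = [
    "ArenaConfig",
    "movement_vectors",
    "PlumeModel",
    "TrialResult",
    "TrackAngleStats",
    "encounter_rate",
    "encounter_sample",
    "simulate_trial",
    "search_distance",
    "track_angles",
]


@dataclass(frozen=True)
class ArenaConfig:
    x_bounds: tuple[float, float] = (-1.25, 1.25)   # m (crosswind)
    y_bounds: tuple[float, float] = (-1.0, 3.0)     # m (wind axis, +y upwind)
    start: tuple[float, float] = (0.0, 0.0)
    source: tuple[float, float] = (0.0, 2.0)
    wind_speed_mps: float = 0.9
    goal_radius_m: float = 0.2
    speed_mps: float = 0.056
    sensing_dt_ms: float = 1.0
    kinematic_dt_ms: float = 100.0
    timeout_s: float = 300.0
    boundary: str = "clamp"         # "clamp": slide along the wall;
                                    # "fail": wall contact ends the trial

    def __post_init__(self) -> None:
        if self.goal_radius_m <= 0:
            raise ValueError("goal radius must be positive")
        x, y = self.source
        if not (self.x_bounds[0] <= x <= self.x_bounds[1]
                and self.y_bounds[0] <= y <= self.y_bounds[1]):
            raise ValueError("source must lie inside the arena")


@dataclass(frozen=True)
class PlumeModel:
    """Intermittent patch-encounter field downwind of the source."""

    nu0_hz: float = 0.25           # peak rate on the centerline at the start
    width_scale: float = 0.12      # m per sqrt(m) of downwind distance
    patch_duration_ms: float = 200.0
    patch_dose_ng: float = 1.0
    source_scale: float = 1.0      # 0 = no pheromone control
    # sensor-noise channel: rare spurious low-dose patches, position- and
    # pheromone-independent (models EAG noise blips); detected only
    # probabilistically, which is what two-neuron coincidence gating filters
    noise_rate_hz: float = 0.004
    noise_dose_ng: float = 0.001
    # slow crosswind meander of the plume centerline (Ornstein-Uhlenbeck)
    meander_sd_m: float = 0.3
    meander_tau_s: float = 10.0

    #: virtual origin of the corridor, m upwind of the source (finite width
    #: at the source itself)
    virtual_origin_m: float = 0.1

    def contour_halfwidth(self, downwind_m) -> np.ndarray:
        """Half-width of the 90%-of-detections (parabolic) contour."""
        dy = np.maximum(downwind_m, 0.0) + self.virtual_origin_m
        return 1.1631 * self.width_scale * np.sqrt(dy)


def encounter_rate(plume: PlumeModel, arena: ArenaConfig, x, y, meander_m: float = 0.0):
    """Patch-encounter rate nu(x, y) in patches/s (0 upwind of the source).

    ``meander_m`` shifts the instantaneous centerline crosswind (the plume
    wanders slowly about the time-averaged, symmetric field).
    """
    sx, sy = arena.source
    # the corridor has a small finite extent at the source itself (a real
    # plume is not a zero-width parabola tip): virtual origin upwind
    dy = sy - np.asarray(y, dtype=float) + plume.virtual_origin_m
    # the plume is anchored at the source: crosswind meander grows with
    # downwind distance (normalized to the start-to-source distance of 2 m)
    dx = np.asarray(x, dtype=float) - sx - meander_m * np.sqrt(np.maximum(dy, 0.0) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(dy > 0, (dx / (plume.width_scale * np.sqrt(np.maximum(dy, 1e-12)))) ** 2, np.inf)
    # flux conservation: the same patch flux crosses every downwind section,
    # so the centerline peak rate rises as the corridor narrows (capped);
    # nu0 is the peak rate at the start-to-source distance of 2 m
    peak = plume.nu0_hz * np.minimum(np.sqrt(2.0 / np.maximum(dy, 1e-3)), 4.0)
    return peak * plume.source_scale * np.exp(-arg)


def encounter_sample(plume: PlumeModel, arena: ArenaConfig, position, dt_s: float,
                     rng: np.random.Generator, meander_m: float = 0.0) -> np.ndarray:
    """Poisson patch-onset times (s, offsets within the step) at a position."""
    nu = float(encounter_rate(plume, arena, position[0], position[1], meander_m))
    n = rng.poisson(nu * dt_s)
    return np.sort(rng.uniform(0.0, dt_s, n)) if n else np.empty(0)


@dataclass(frozen=True)
class TrialResult:
    trajectory: pd.DataFrame        # t_s, x_m, y_m
    detections: np.ndarray          # patch onset times (s)
    on_events: np.ndarray           # surge-trigger times (s)
    success: bool
    search_distance_m: float
    duration_s: float
    false_events: int = 0           # events with no detection in the preceding 3 s


@dataclass(frozen=True)
class TrackAngleStats:
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    rayleigh_z: float
    rayleigh_p: float
    mode_deg: float


def search_distance(xy: np.ndarray) -> float:
    """Total path length (m) of a trajectory array of shape (n, 2)."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or len(xy) == 0:
        raise ValueError("trajectory must be a non-empty (n, 2) array")
    if len(xy) == 1:
        return 0.0
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def movement_vectors(xy: np.ndarray, stride: int = 1) -> np.ndarray:
    """Per-segment displacement vectors (every ``stride`` trajectory samples)."""
    xy = np.asarray(xy, dtype=float)
    return np.diff(xy[::max(stride, 1)], axis=0)


def track_angles(xy: np.ndarray, bin_deg: float = 20.0, stride: int = 1) -> TrackAngleStats:
    """Movement-vector angles relative to upwind (+y), with a Rayleigh test.

    0 deg = upwind, +/-90 deg = crosswind; requires >= 10 movement vectors.
    ``stride`` coarsens the trajectory sampling before vectors are taken
    (behavioural analyses use seconds-scale movement segments).
    """
    d = movement_vectors(xy, stride)
    d = d[np.hypot(d[:, 0], d[:, 1]) > 1e-12]
    if len(d) < 10:
        raise ValueError("need at least 10 movement vectors")
    ang = np.arctan2(-d[:, 0], d[:, 1])           # signed angle from +y
    z, p = rayleigh(ang)
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(np.degrees(ang), bins=edges)
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    return TrackAngleStats(bin_edges_deg=edges, counts=counts,
                           rayleigh_z=z, rayleigh_p=p, mode_deg=mode)


class _SensoryChannel:
    """One neuron's sensing chain: ORN counts -> drive -> neuron -> detector."""

    def __init__(self, orn_model, kernel, params, detector_cfg, dt_neuron, rng):
        self.orn_model = orn_model
        self.kernel = kernel
        self.neuron = OnlineNeuron(params, dt=dt_neuron)
        self.detector = OnEventDetector(detector_cfg)
        self.rng = rng
        self._alpha = math.exp(-1.0 / kernel.tau_ms)
        self._zi = np.zeros(1)
        self.events_ms: list[float] = []

    def step(self, lam_hz: np.ndarray, t_end_ms: float) -> None:
        counts = self.rng.poisson(self.orn_model.n_orns * lam_hz * 1e-3)
        x = self.kernel.amplitude_na * counts.astype(float)
        drive, self._zi = lfilter([1.0], [1.0, -self._alpha], x, zi=self._zi)
        for t_sp in self.neuron.step(drive, 1.0):
            ev = self.detector.update(t_sp)
            if ev is not None:
                self.events_ms.append(ev)
        ev = self.detector.poll(t_end_ms)
        if ev is not None:
            self.events_ms.append(ev)


def simulate_trial(
    arena: ArenaConfig = ArenaConfig(),
    plume: PlumeModel = PlumeModel(),
    orn_model: ORNRateModel = ORNRateModel(),
    kernel: DriveKernel = DriveKernel(),
    neuron_params: NeuronParams = NeuronParams(),
    detector_config: OnEventDetectorConfig = OnEventDetectorConfig(),
    policy_config: PolicyConfig = PolicyConfig(),
    strategy: str = "one_step",
    seed: int = 0,
    dt_neuron_ms: float = 0.05,
    two_neuron: bool = False,
    perturb_cv: float = 0.2,
    coincidence_window_ms: float = 300.0,
    theory_mode: bool = False,
) -> TrialResult:
    """Run one closed-loop trial; fully reproducible from the seed.

    ``two_neuron`` instantiates a second, parameter-perturbed neuron fed by
    an independent ORN sampling of the same rate, and gates surge commands
    on coincident detections.  ``theory_mode`` replaces the sensory chain by
    idealized deterministic detection exactly at the plume centerline (used
    to check the search-theory bound).
    """
    ss = np.random.SeedSequence(seed)
    rng_plume, rng_orn1, rng_orn2, rng_params = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    pc = dataclasses.replace(
        policy_config,
        spiral_heading_offset_rad=float(rng_params.uniform(0.0, 2.0 * math.pi)),
        spiral_direction=float(rng_params.choice([-1.0, 1.0])),
        zigzag_first_sign=float(rng_params.choice([-1.0, 1.0])),
    )
    policy = make_policy(strategy, pc)
    meander = 0.0
    m_alpha = math.exp(-arena.kinematic_dt_ms * 1e-3 / plume.meander_tau_s)
    m_sd1 = plume.meander_sd_m * math.sqrt(max(0.0, 1.0 - m_alpha * m_alpha))
    chans = []
    if not theory_mode:
        chans.append(_SensoryChannel(orn_model, kernel, neuron_params,
                                     detector_config, dt_neuron_ms, rng_orn1))
        if two_neuron:
            p2 = perturb_params(neuron_params, perturb_cv, seed=rng_params)
            chans.append(_SensoryChannel(orn_model, kernel, p2,
                                         detector_config, dt_neuron_ms, rng_orn2))

    dt_k = arena.kinematic_dt_ms * 1e-3
    n_steps = int(round(arena.timeout_s / dt_k))
    pos = np.array(arena.start, dtype=float)
    src = np.asarray(arena.source, dtype=float)
    pulses: list[list[float]] = []      # [onset_ms, duration_ms, dose_ng]
    detections: list[float] = []
    emitted: list[float] = []
    traj = np.empty((n_steps + 1, 3))
    traj[0] = (0.0, pos[0], pos[1])
    success = False
    n_traj = 1
    gate_tail: list[float] = []
    prev_x = pos[0]

    for k in range(n_steps):
        t0_ms = k * arena.kinematic_dt_ms
        t1_ms = t0_ms + arena.kinematic_dt_ms

        if theory_mode:
            crossed = (prev_x == 0.0) or (prev_x * pos[0] <= 0.0)
            if crossed and pos[1] < src[1] and abs(pos[0]) < 0.5:
                detections.append(t0_ms * 1e-3)
                emitted.append(t0_ms * 1e-3)
                policy.notify_event(t0_ms * 1e-3)
        else:
            meander = m_alpha * meander + m_sd1 * rng_plume.standard_normal()
            hits = [(t0_ms + off_s * 1e3, plume.patch_dose_ng, True)
                    for off_s in encounter_sample(plume, arena, pos, dt_k, rng_plume, meander)]
            n_noise = rng_plume.poisson(plume.noise_rate_hz * dt_k)
            hits += [(t0_ms + u * 1e3, plume.noise_dose_ng, False)
                     for u in np.sort(rng_plume.uniform(0.0, dt_k, n_noise))]
            for onset, dose, real in sorted(hits):
                if real:
                    detections.append(onset * 1e-3)
                if pulses and onset < pulses[-1][0] + pulses[-1][1]:
                    if real:  # a real patch refreshes/extends the contact
                        pulses[-1][1] = onset + plume.patch_duration_ms - pulses[-1][0]
                        pulses[-1][2] = max(pulses[-1][2], dose)
                else:
                    pulses.append([onset, plume.patch_duration_ms, dose])
            # drop pulses that no longer influence the rate
            horizon = t0_ms - 4.0 * orn_model.tau_slow
            while len(pulses) > 1 and pulses[1][0] < horizon:
                pulses.pop(0)
            grid = np.arange(t0_ms, t1_ms, arena.sensing_dt_ms) + 0.5 * arena.sensing_dt_ms
            if pulses:
                proto = StimulusProtocol(
                    tuple((p[0], p[1], p[2]) for p in pulses),
                    max(t1_ms, pulses[-1][0] + pulses[-1][1]) + 1.0,
                )
                lam = rate(orn_model, proto, grid)
            else:
                lam = np.full(grid.shape, orn_model.baseline_hz)
            new_events: list[np.ndarray] = []
            for ch in chans:
                n_before = len(ch.events_ms)
                ch.step(lam, t1_ms)
                new_events.append(np.asarray(ch.events_ms))
            if two_neuron:
                gated = coincidence_gate(new_events[0], new_events[1],
                                         coincidence_window_ms)
                fresh = [g for g in gated if g not in gate_tail]
                gate_tail = list(gated)
                for g in fresh:
                    emitted.append(g * 1e-3)
                    policy.notify_event(g * 1e-3)
            else:
                for g in new_events[0][len(emitted):]:
                    emitted.append(g * 1e-3)
                    policy.notify_event(g * 1e-3)

        cmd = policy.command(t0_ms * 1e-3, dt_k)
        th = cmd.heading_rad
        step_v = np.array([-math.sin(th), math.cos(th)]) * cmd.speed_mps * dt_k
        prev_x = pos[0]
        pos = pos + step_v
        outside = not (arena.x_bounds[0] <= pos[0] <= arena.x_bounds[1]
                       and arena.y_bounds[0] <= pos[1] <= arena.y_bounds[1])
        pos[0] = min(max(pos[0], arena.x_bounds[0]), arena.x_bounds[1])
        pos[1] = min(max(pos[1], arena.y_bounds[0]), arena.y_bounds[1])
        traj[n_traj] = (t1_ms * 1e-3, pos[0], pos[1])
        n_traj += 1
        if outside and arena.boundary == "fail":
            break
        if np.hypot(*(pos - src)) <= arena.goal_radius_m:
            success = True
            break

    df = pd.DataFrame(traj[:n_traj], columns=["t_s", "x_m", "y_m"])
    dist = search_distance(df[["x_m", "y_m"]].to_numpy())
    det = np.asarray(detections)
    evs = np.asarray(emitted)
    false_events = int(
        sum(1 for e in evs if not np.any((det < e) & (det > e - 3.0)))
    )
    return TrialResult(
        trajectory=df,
        detections=det,
        on_events=evs,
        success=success,
        search_distance_m=dist,
        duration_s=float(df["t_s"].iloc[-1]),
        false_events=false_events,
    )
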