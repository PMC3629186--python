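"""Biophysical On/Off command neuron.

Single-compartment Hodgkin-Huxley model with five currents: leak, fast Na+,
delayed-rectifier K+, high-voltage-activated Ca2+, and a small-conductance
Ca2+-activated K+ current (SK).  The SK current is the mechanism of interest:
calcium entering during the stimulus-driven burst activates SK, which
hyperpolarizes the cell and carves the inhibitory phase between the On burst
and the tonic Off discharge.  Blocking SK (``scale_sk`` factor 0) turns the
multiphasic response monophasic.

Spike kinetics follow the Wang-Buzsaki fast-spiking parameterization (m
instantaneous, temperature factor folded into the h/n rate constants); the
Ca2+ current uses an instantaneous sigmoidal activation, the calcium pool is
first order, and SK activation is an instantaneous Hill function of
intracellular Ca2+.  Free parameters (g_Ca, g_SK, tau_Ca, k_Ca, K_sk, and the
ORN drive gain in :mod:`mothnav.orn`) were calibrated once against the
measured response laws (On duration tracking stimulus duration, ~400 ms
inhibitory phase, dose-dependent On latency) and are frozen as the defaults
below.

Units: mV, ms, nA, nF, uS, uM throughout.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass

import numpy as np
from numba import njit

from .spiketrain import SpikeTrain

__all__ = [
    "NeuronParams",
    "NeuronState",
    "OnlineNeuron",
    "NumericalDivergenceError",
    "integrate",
    "detect_spikes",
    "scale_sk",
    "perturb_params",
    "SK_SWEEP_MIN",
    "SK_SWEEP_MAX",
]

#: bounds of the SK-conductance sweep used in the block experiments (uS)
SK_SWEEP_MIN = 0.05
SK_SWEEP_MAX = 0.5

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 1.0


class NumericalDivergenceError(RuntimeError):
    """Raised when the integrator state becomes non-finite."""


@dataclass(frozen=True)
class NeuronParams:
    """Maximal conductances, reversal potentials and Ca/SK kinetics.

    The defaults are the calibrated, frozen parameter set used throughout the
    package.  ``g_sk`` of an intact neuron equals the top of the sweep range
    (0.5 uS); ``scale_sk`` maps a normalized block factor onto the sweep.
    """

    c_m: float = 1.0          # nF
    g_na: float = 35.0        # uS
    g_k: float = 9.0
    g_leak: float = 0.1
    g_ca: float = 0.1
    g_sk: float = 0.5
    e_na: float = 55.0        # mV
    e_k: float = -90.0
    e_leak: float = -65.0
    e_ca: float = 120.0
    tau_ca: float = 400.0     # ms, Ca removal
    k_ca: float = 0.0016      # uM per (nA*ms), Ca influx gain
    k_sk: float = 0.4         # uM, SK half-activation
    n_sk: float = 2.0         # SK Hill coefficient
    ca_rest: float = 0.05     # uM

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_leak", "g_ca", "g_sk"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be positive")
        if not (self.e_k < self.e_leak < self.e_na):
            raise ValueError("reversal potentials must satisfy E_K < E_leak < E_Na")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.c_m, self.g_na, self.g_k, self.g_leak, self.g_ca, self.g_sk,
             self.e_na, self.e_k, self.e_leak, self.e_ca,
             self.tau_ca, self.k_ca, self.k_sk, self.n_sk, self.ca_rest],
            dtype=np.float64,
        )

    # -- flat key/value (TOML) round trip ------------------------------
    def to_toml(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "NeuronParams":
        return cls(**tomllib.loads(text))


@dataclass
class NeuronState:
    """Instantaneous integrator state."""

    v: float = -64.0
    h: float = 0.78
    n: float = 0.09
    ca: float = 0.05
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        # layout: v, h, n, ca, t, v_prev, t_last_spike
        return np.array([self.v, self.h, self.n, self.ca, self.t, self.v, -1e12])


@njit(cache=True, inline="always")
def _derivs(v, h, n, ca, drive, p):
    cm = p[0]
    if abs(v + 35.0) > 1e-9:
        am = 0.1 * (v + 35.0) / (1.0 - math.exp(-(v + 35.0) / 10.0))
    else:
        am = 1.0
    bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
    minf = am / (am + bm)
    ah = 0.35 * math.exp(-(v + 58.0) / 20.0)
    bh = 5.0 / (1.0 + math.exp(-(v + 28.0) / 10.0))
    if abs(v + 34.0) > 1e-9:
        an = 0.05 * (v + 34.0) / (1.0 - math.exp(-(v + 34.0) / 10.0))
    else:
        an = 0.5
    bn = 0.625 * math.exp(-(v + 44.0) / 80.0)

    i_na = p[1] * minf ** 3 * h * (v - p[6])
    i_k = p[2] * n ** 4 * (v - p[7])
    i_leak = p[3] * (v - p[8])
    s = 1.0 / (1.0 + math.exp(-(v + 25.0) / 5.0))
    i_ca = p[4] * s * s * (v - p[9])
    act = ca ** p[13] / (ca ** p[13] + p[12] ** p[13])
    i_sk = p[5] * act * (v - p[7])

    dv = (-i_na - i_k - i_leak - i_ca - i_sk + drive) / cm
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    dca = -p[11] * i_ca - (ca - p[14]) / p[10]
    return dv, dh, dn, dca


@njit(cache=True)
def _rk4_chunk(state, drive, drive_dt, dt, p, threshold, refractory, v_out, record_stride):
    """Advance the state through ``len(drive)*drive_dt`` ms.

    ``state`` layout: [v, h, n, ca, t, v_prev, t_last_spike]; modified in
    place.  Drive samples are linearly interpolated.  Returns (spike_times,
    status, bad_t): status 0 = ok, 1..4 name the first non-finite variable
    (v, h, n, ca).
    """
    n_samp = drive.shape[0]
    t_end = n_samp * drive_dt
    nsteps = int(round(t_end / dt))
    spikes = []
    v = state[0]; h = state[1]; n = state[2]; ca = state[3]
    t0 = state[4]; vprev = state[5]; last_sp = state[6]
    for i in range(nsteps):
        tl = i * dt  # time within chunk
        x = tl / drive_dt
        j = int(x)
        if j >= n_samp - 1:
            drv = drive[n_samp - 1]
        else:
            fr = x - j
            drv = drive[j] * (1.0 - fr) + drive[j + 1] * fr
        d1 = _derivs(v, h, n, ca, drv, p)
        d2 = _derivs(v + 0.5 * dt * d1[0], h + 0.5 * dt * d1[1],
                     n + 0.5 * dt * d1[2], ca + 0.5 * dt * d1[3], drv, p)
        d3 = _derivs(v + 0.5 * dt * d2[0], h + 0.5 * dt * d2[1],
                     n + 0.5 * dt * d2[2], ca + 0.5 * dt * d2[3], drv, p)
        d4 = _derivs(v + dt * d3[0], h + dt * d3[1],
                     n + dt * d3[2], ca + dt * d3[3], drv, p)
        v = v + dt / 6.0 * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
        h = h + dt / 6.0 * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
        n = n + dt / 6.0 * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
        ca = ca + dt / 6.0 * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3])
        t = t0 + (i + 1) * dt
        if not math.isfinite(v):
            state[0] = v; state[4] = t
            return np.array(spikes), 1, t
        if not math.isfinite(h):
            state[1] = h; state[4] = t
            return np.array(spikes), 2, t
        if not math.isfinite(n):
            state[2] = n; state[4] = t
            return np.array(spikes), 3, t
        if not math.isfinite(ca):
            state[3] = ca; state[4] = t
            return np.array(spikes), 4, t
        if vprev < threshold and v >= threshold and (t - last_sp) >= refractory:
            spikes.append(t)
            last_sp = t
        vprev = v
        if record_stride > 0 and (i + 1) % record_stride == 0:
            v_out[(i + 1) // record_stride - 1] = v
    state[0] = v; state[1] = h; state[2] = n; state[3] = ca
    state[4] = t0 + nsteps * dt; state[5] = vprev; state[6] = last_sp
    return np.array(spikes), 0, 0.0


_STATE_NAMES = {1: "v", 2: "h", 3: "n", 4: "ca"}


def integrate(
    params: NeuronParams,
    drive: np.ndarray,
    drive_dt_ms: float = 1.0,
    dt: float = 0.01,
    state: NeuronState | None = None,
    record_ms: float = 1.0,
    trial_id: int = 0,
    neuron_id: int = 0,
):
    """Integrate the neuron against a current drive (nA).

    Parameters
    ----------
    drive : 1-D array of current samples (nA) at spacing ``drive_dt_ms``
        (must be at most 1 ms, i.e. >= 1 kHz); linearly interpolated to the
        integration step ``dt``.
    dt : RK4 step in ms (default 0.01; <= 0.05 for production use).
    record_ms : spacing of the recorded voltage trace.

    Returns
    -------
    (t_ms, v_mv, spikes) : recorded voltage trace and a :class:`SpikeTrain`
    of upward 0-mV crossings (1 ms refractory).
    """
    if drive_dt_ms > 1.0 + 1e-12:
        raise ValueError("drive must be sampled at 1 kHz or faster")
    if dt > 0.05 + 1e-12:
        raise ValueError("dt must be <= 0.05 ms")
    drive = np.ascontiguousarray(drive, dtype=np.float64)
    st = (state or NeuronState(ca=params.ca_rest)).as_array()
    stride = max(1, int(round(record_ms / dt)))
    nsteps = int(round(len(drive) * drive_dt_ms / dt))
    v_out = np.empty(nsteps // stride, dtype=np.float64)
    spikes, status, bad_t = _rk4_chunk(
        st, drive, drive_dt_ms, dt, params.as_array(),
        SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS, v_out, stride,
    )
    if status != 0:
        raise NumericalDivergenceError(
            f"state variable '{_STATE_NAMES[status]}' became non-finite at t = {bad_t:.3f} ms"
        )
    t_ms = (np.arange(1, len(v_out) + 1) * stride) * dt
    return t_ms, v_out, SpikeTrain(spikes, trial_id=trial_id, neuron_id=neuron_id)


class OnlineNeuron:
    """Stateful chunk-wise integrator for closed-loop simulation."""

    def __init__(self, params: NeuronParams, dt: float = 0.05):
        self.params = params
        self._p = params.as_array()
        self.dt = dt
        self._state = NeuronState(ca=params.ca_rest).as_array()
        self._dummy = np.empty(0, dtype=np.float64)

    @property
    def t_ms(self) -> float:
        return float(self._state[4])

    def step(self, drive: np.ndarray, drive_dt_ms: float = 1.0) -> np.ndarray:
        """Advance by one drive chunk; returns absolute spike times (ms)."""
        spikes, status, bad_t = _rk4_chunk(
            self._state, np.ascontiguousarray(drive, dtype=np.float64),
            drive_dt_ms, self.dt, self._p,
            SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS, self._dummy, 0,
        )
        if status != 0:
            raise NumericalDivergenceError(
                f"state variable '{_STATE_NAMES[status]}' became non-finite at t = {bad_t:.3f} ms"
            )
        return spikes


def detect_spikes(
    v: np.ndarray,
    dt_ms: float,
    threshold: float = SPIKE_THRESHOLD_MV,
    refractory: float = SPIKE_REFRACTORY_MS,
    t0: float = 0.0,
) -> SpikeTrain:
    """Upward threshold crossings of a uniformly sampled trace.

    One spike per crossing, successive spikes separated by at least the
    refractory period.  An empty trace yields an empty train.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        return SpikeTrain(np.empty(0))
    up = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
    times = t0 + up * dt_ms
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory:
            kept.append(t)
    return SpikeTrain(np.array(kept))


def scale_sk(params: NeuronParams, factor: float) -> NeuronParams:
    """Map a normalized SK-block factor onto the conductance sweep.

    factor 1 leaves the parameters untouched (intact SK); factor 0 removes
    the SK conductance entirely (full block); intermediate factors map
    linearly onto the sweep range [0.05, 0.5] uS.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError("SK scale factor must lie in [0, 1]")
    if factor == 1.0:
        return params
    g = 0.0 if factor == 0.0 else SK_SWEEP_MIN + factor * (SK_SWEEP_MAX - SK_SWEEP_MIN)
    return dataclasses.replace(params, g_sk=g)


def perturb_params(
    params: NeuronParams,
    cv: float,
    fields: tuple[str, ...] = ("g_sk", "tau_ca"),
    seed: int | np.random.Generator = 0,
) -> NeuronParams:
    """Multiply selected parameters by truncated Gaussian factors (mean 1, sd cv).

    Used to instantiate heterogeneous neuron pairs; non-positive draws are
    resampled so the result is always a valid parameter set.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    updates = {}
    for name in fields:
        if not hasattr(params, name):
            raise ValueError(f"unknown parameter field {name!r}")
        factor = 0.0
        while factor <= 0.0:
            factor = 1.0 + cv * rng.standard_normal()
        updates[name] = getattr(params, name) * factor
    return dataclasses.replace(params, **updates)
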