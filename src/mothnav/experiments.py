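"""Experiment drivers: the figure-level protocols run end to end.

Each driver wires the full simulation pipeline (stimulus protocol -> ORN
population rate -> pooled Poisson spikes -> synaptic drive -> command neuron
-> phase segmentation / navigation) with fresh seeds, and reports per-run
metrics plus summary statistics.  The calibrated model defaults are frozen
in :class:`mothnav.orn.ORNRateModel` and :class:`mothnav.neuron.NeuronParams`;
the drivers here only consume them.

Measurement conventions for pulse trains: latency is taken at the first
spike of a >= 3-spike burst (robust to sparse spontaneous firing), the On
phase ends at the last spike before the first >= 150 ms silent gap, and the
Off phase between pulses is the tonic firing between the end of that gap and
the next pulse's On start.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .metrics import SegmentationConfig, segment_phases
from .neuron import NeuronParams, integrate, scale_sk
from .orn import (
    DriveKernel,
    ORNRateModel,
    StimulusProtocol,
    drive_from_counts,
    sample_population_counts,
)
from .spiketrain import SpikeTrain
from .stats import fisher_exact, kruskal_wallis, mann_whitney, rayleigh  # noqa: F401

__all__ = [
    "ExperimentReport",
    "simulate_response",
    "burst_latency",
    "pulse_phases",
    "run_duration_series",
    "run_dose_series",
    "run_sk_sweep",
    "run_gap_series",
    "run_navigation_batch",
]


@dataclass(frozen=True)
class ExperimentReport:
    experiment_id: str
    config: dict
    per_run: pd.DataFrame
    summary: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "experiment_id": self.experiment_id,
                "config": self.config,
                "per_run": self.per_run.to_dict(orient="records"),
                "summary": self.summary,
            },
            indent=2,
            default=float,
        )


def simulate_response(
    protocol: StimulusProtocol,
    params: NeuronParams = NeuronParams(),
    orn_model: ORNRateModel = ORNRateModel(),
    kernel: DriveKernel = DriveKernel(),
    seed: int = 0,
    dt: float = 0.01,
) -> SpikeTrain:
    """Run the ORN -> drive -> neuron pipeline for one protocol realization."""
    counts = sample_population_counts(orn_model, protocol, seed)
    drive = drive_from_counts(counts, kernel)
    _, _, spikes = integrate(params, drive, 1.0, dt=dt)
    return spikes


def burst_latency(train: SpikeTrain, onset_ms: float, isi_max: float = 70.0,
                  k: int = 3) -> float:
    """Latency of the first >= k-spike burst after onset (nan if none)."""
    t = train.times[train.times >= onset_ms]
    for i in range(t.size - k + 1):
        if np.all(np.diff(t[i:i + k]) < isi_max):
            return float(t[i] - onset_ms)
    return float("nan")


def pulse_phases(train: SpikeTrain, onset_ms: float, duration_ms: float,
                 window_end_ms: float, gap_min: float = 150.0) -> dict:
    """Gap-based On/I/Off measurement for one pulse of a train.

    Returns latency, On end, I duration and Off presence/duration within
    [onset, window_end); used by the pulsed-gap experiment where the next
    pulse's On truncates the current Off.
    """
    lat = burst_latency(train, onset_ms)
    out = {"latency": lat, "on_end": np.nan, "i_dur": np.nan,
           "off_present": False, "off_dur": np.nan}
    if np.isnan(lat):
        return out
    t = train.times[(train.times >= onset_ms + lat) & (train.times < window_end_ms)]
    gaps = np.diff(t)
    idx = np.nonzero(gaps >= gap_min)[0]
    if idx.size == 0:
        out["on_end"] = float(t[-1] - onset_ms) if t.size else np.nan
        return out
    on_end = t[idx[0]]
    out["on_end"] = float(on_end - onset_ms)
    if on_end - onset_ms > lat + duration_ms + 800.0:
        return out
    out["i_dur"] = float(gaps[idx[0]])
    off = t[idx[0] + 1:]
    if off.size >= 2 and off[-1] - off[0] > 40.0:
        out["off_present"] = True
        out["off_dur"] = float(off[-1] - off[0] + 30.0)
    return out


def run_duration_series(
    n_runs: int = 10,
    seed: int = 0,
    durations=(100.0, 200.0, 500.0, 1000.0),
    dose: float = 1.0,
    params: NeuronParams = NeuronParams(),
    orn_model: ORNRateModel = ORNRateModel(),
    dt: float = 0.01,
) -> ExperimentReport:
    """Single 1-ng pulses of varying duration; regresses On duration on
    stimulus duration and collects inhibitory-phase durations."""
    rows = []
    cfg = SegmentationConfig()
    for d_i, dur in enumerate(durations):
        proto = StimulusProtocol.single(duration=dur, dose=dose)
        for r in range(n_runs):
            sp = simulate_response(proto, params, orn_model, seed=seed * 100003 + d_i * 1009 + r, dt=dt)
            seg = segment_phases(sp, (1000.0, dur), cfg)
            rows.append({
                "stim_ms": dur, "run": r,
                "on_latency": seg.on_latency, "on_dur": seg.on_duration,
                "i_dur": seg.i_duration, "off_dur": seg.off_duration,
            })
    df = pd.DataFrame(rows)
    ok = df.dropna(subset=["on_dur"])
    if ok["stim_ms"].nunique() >= 2:
        slope, intercept = np.polyfit(ok["stim_ms"], ok["on_dur"], 1)
    else:
        slope, intercept = float("nan"), float("nan")
    pred = slope * ok["stim_ms"] + intercept
    ss_res = float(((ok["on_dur"] - pred) ** 2).sum())
    ss_tot = float(((ok["on_dur"] - ok["on_dur"].mean()) ** 2).sum())
    i_by_dur = [g.dropna().to_numpy() for _, g in df.groupby("stim_ms")["i_dur"]]
    i_long = df[df["stim_ms"] >= 200.0]["i_dur"].dropna()
    summary = {
        "on_slope": float(slope),
        "on_intercept_ms": float(intercept),
        "r2": 1.0 - ss_res / ss_tot if ss_tot else float("nan"),
        "i_mean_ms": float(i_long.mean()),
        "i_sd_ms": float(i_long.std()),
        "latency_mean_ms": float(df[df["stim_ms"] == 200.0]["on_latency"].dropna().mean()),
        "i_kruskal_p": kruskal_wallis([g for g in i_by_dur if g.size])[1]
        if sum(g.size > 0 for g in i_by_dur) >= 2 else float("nan"),
    }
    return ExperimentReport("duration_series", {"n_runs": n_runs, "seed": seed,
                                                "durations": list(durations)}, df, summary)


def run_dose_series(
    n_runs: int = 10,
    seed: int = 0,
    doses=(0.001, 0.01, 0.1, 1.0, 10.0),
    heterogeneous: bool = True,
    params: NeuronParams = NeuronParams(),
    orn_model: ORNRateModel = ORNRateModel(),
    dt: float = 0.02,
) -> ExperimentReport:
    """200-ms stimuli across doses; latency, phase durations and PSTH shape.

    ``heterogeneous`` perturbs g_SK and tau_Ca by 20% per run, mirroring the
    between-neuron variability of pooled recordings; the dose-invariance of
    the inhibitory phase is only meaningful at that variance scale.
    """
    from .metrics import psth
    from .neuron import perturb_params

    rows = []
    cfg = SegmentationConfig()
    psth_by_dose = {}
    for q_i, q in enumerate(doses):
        proto = StimulusProtocol.single(dose=q, tail=4000.0)
        trains = []
        for r in range(n_runs):
            p = params
            if heterogeneous:
                p = perturb_params(params, 0.2, seed=seed * 1000 + q_i * 100 + r)
            sp = simulate_response(proto, p, orn_model,
                                   seed=seed * 999 + 20000 + q_i * 17 + r, dt=dt)
            trains.append(sp)
            seg = segment_phases(sp, (1000.0, 200.0), cfg)
            rows.append({"dose_ng": q, "run": r, "on_latency": seg.on_latency,
                         "on_dur": seg.on_duration, "i_dur": seg.i_duration,
                         "off_dur": seg.off_duration})
        centers, rate_hz = psth(trains, t_range=(0.0, proto.total_duration))
        psth_by_dose[q] = {
            "baseline_hz": float(rate_hz[centers < 900.0].mean()),
            "on_peak_hz": float(rate_hz[(centers > 1000.0) & (centers < 1600.0)].max()),
            "i_trough_hz": float(rate_hz[(centers > 1600.0) & (centers < 1900.0)].min()),
            "off_hz": float(rate_hz[(centers > 2100.0) & (centers < 3100.0)].mean()),
        }
    df = pd.DataFrame(rows)
    i_groups = [g.dropna().to_numpy() for _, g in df.groupby("dose_ng")["i_dur"]]
    usable = [g for g in i_groups if g.size >= 5]
    summary = {
        "i_by_dose": {q: float(df[df.dose_ng == q]["i_dur"].mean()) for q in doses},
        "i_kruskal_p": kruskal_wallis(usable)[1] if len(usable) >= 2 else float("nan"),
        "latency_by_dose": {q: float(df[df.dose_ng == q]["on_latency"].mean()) for q in doses},
        "psth": psth_by_dose,
    }
    return ExperimentReport("dose_series", {"n_runs": n_runs, "seed": seed,
                                            "doses": list(doses)}, df, summary)


def run_sk_sweep(
    factors=(1.0, 0.75, 0.5, 0.25, 0.0),
    stimulus_ms: float = 200.0,
    n_runs: int = 5,
    seed: int = 0,
    params: NeuronParams = NeuronParams(),
    orn_model: ORNRateModel = ORNRateModel(),
    dt: float = 0.01,
) -> ExperimentReport:
    """On and I durations versus the normalized SK-conductance decrease."""
    rows = []
    cfg = SegmentationConfig()
    proto = StimulusProtocol.single(duration=stimulus_ms)
    for f_i, f in enumerate(factors):
        p = scale_sk(params, f)
        for r in range(n_runs):
            sp = simulate_response(proto, p, orn_model, seed=seed * 90001 + f_i * 607 + r, dt=dt)
            seg = segment_phases(sp, (1000.0, stimulus_ms), cfg)
            rows.append({"sk_factor": f, "g_sk": p.g_sk, "run": r,
                         "on_dur": seg.on_duration, "i_dur": seg.i_duration,
                         "i_present": seg.i_end is not None})
    df = pd.DataFrame(rows)
    agg = df.groupby("sk_factor").agg(
        i_mean=("i_dur", "mean"), on_mean=("on_dur", "mean"),
        i_rate=("i_present", "mean")).reset_index()
    summary = {
        "i_by_factor": dict(zip(agg["sk_factor"], agg["i_mean"])),
        "on_by_factor": dict(zip(agg["sk_factor"], agg["on_mean"])),
        "i_present_by_factor": dict(zip(agg["sk_factor"], agg["i_rate"])),
    }
    return ExperimentReport("sk_sweep", {"factors": list(factors), "n_runs": n_runs,
                                         "seed": seed}, df, summary)


def run_gap_series(
    n_runs: int = 5,
    seed: int = 0,
    gaps=(300.0, 500.0, 700.0, 1000.0, 2000.0, 5000.0),
    params: NeuronParams = NeuronParams(),
    orn_model: ORNRateModel = ORNRateModel(),
    dt: float = 0.01,
) -> ExperimentReport:
    """Pulsed protocols; Off-phase presence and duration versus air gap."""
    rows = []
    for g_i, gap in enumerate(gaps):
        proto = StimulusProtocol.pulse_train(gap=gap)
        lat_guess = orn_model.onset_latency(proto.pulses[0][2]) + 35.0
        for r in range(n_runs):
            sp = simulate_response(proto, params, orn_model,
                                   seed=seed * 70001 + g_i * 503 + r, dt=dt)
            for k in range(len(proto.pulses) - 1):
                onset, dur, _ = proto.pulses[k]
                nxt = proto.pulses[k + 1][0]
                ph = pulse_phases(sp, onset, dur, nxt + lat_guess)
                rows.append({"gap_ms": gap, "run": r, "pulse": k, **ph})
    df = pd.DataFrame(rows)
    agg = df.groupby("gap_ms").agg(off_rate=("off_present", "mean"),
                                   off_dur=("off_dur", "mean")).reset_index()
    fit_rows = agg[agg["off_rate"] > 0.5]
    if len(fit_rows) >= 3:
        slope, intercept = np.polyfit(fit_rows["gap_ms"], fit_rows["off_dur"], 1)
    else:
        slope, intercept = float("nan"), float("nan")
    summary = {
        "off_rate_by_gap": dict(zip(agg["gap_ms"], agg["off_rate"])),
        "off_dur_by_gap": dict(zip(agg["gap_ms"], agg["off_dur"])),
        "off_slope": float(slope),
        "off_intercept_ms": float(intercept),
    }
    return ExperimentReport("gap_series", {"n_runs": n_runs, "seed": seed,
                                           "gaps": list(gaps)}, df, summary)


def run_navigation_batch(
    strategy: str = "one_step",
    sk_factor: float = 1.0,
    n_trials: int = 30,
    seed: int = 0,
    **sim_kwargs,
) -> ExperimentReport:
    """Batch of seeded closed-loop trials for one condition."""
    from .arena import simulate_trial, track_angles
    from .neuron import NeuronParams, scale_sk

    params = scale_sk(sim_kwargs.pop("neuron_params", NeuronParams()), sk_factor)
    rows = []
    all_xy = []
    for i in range(n_trials):
        res = simulate_trial(neuron_params=params, strategy=strategy,
                             seed=seed * 50021 + i, **sim_kwargs)
        rows.append({
            "trial": i, "success": res.success,
            "search_distance_m": res.search_distance_m,
            "duration_s": res.duration_s,
            "n_detections": len(res.detections),
            "n_events": len(res.on_events),
            "false_events": res.false_events,
        })
        all_xy.append(res.trajectory[["x_m", "y_m"]].to_numpy())
    df = pd.DataFrame(rows)
    succ = df[df["success"]]
    pooled = np.concatenate(all_xy) if all_xy else np.empty((0, 2))
    # pool per-trial movement vectors (not across trial boundaries)
    # behavioural-scale movement vectors: 5-s segments, evenly subsampled to
    # a fixed pooled size so the Rayleigh test has comparable power across
    # conditions
    angs = None
    try:
        from .arena import movement_vectors
        d = np.concatenate([movement_vectors(xy, stride=50) for xy in all_xy])
        d = d[np.hypot(d[:, 0], d[:, 1]) > 1e-12]
        if len(d) > 300:
            d = d[:: len(d) // 300 + 1]
        if len(d) >= 10:
            ang = np.arctan2(-d[:, 0], d[:, 1])
            z, p = rayleigh(ang)
            edges = np.arange(-180.0, 181.0, 20.0)
            counts, _ = np.histogram(np.degrees(ang), bins=edges)
            mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
            angs = {"rayleigh_z": z, "rayleigh_p": p, "mode_deg": float(mode)}
    except ValueError:
        pass
    summary = {
        "success_rate": float(df["success"].mean()),
        "n_success": int(df["success"].sum()),
        "search_distance_median_m": float(succ["search_distance_m"].median())
        if len(succ) else float("nan"),
        "search_distance_mean_m": float(succ["search_distance_m"].mean())
        if len(succ) else float("nan"),
        "false_events_per_trial": float(df["false_events"].mean()),
        "track_angles": angs,
    }
    return ExperimentReport(
        f"navigation_{strategy}_sk{sk_factor:g}",
        {"strategy": strategy, "sk_factor": sk_factor, "n_trials": n_trials, "seed": seed},
        df, summary,
    )
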