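"""Synthetic spike-train ensembles and canned stimulus protocols.

These generators produce the controlled inputs used to validate the
statistics layer: multiphasic templates with known phase boundaries and
known jitter (for segmentation and sigma/rho recovery), Poisson controls,
and the stimulus-protocol sets of the standard experimental designs (dose
series, pulsed-gap series, duration series).  All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orn import StimulusProtocol
from .spiketrain import SpikeTrain

__all__ = ["MultiphasicTemplate", "make_trials", "paper_protocols"]


@dataclass(frozen=True)
class MultiphasicTemplate:
    """Piecewise-rate template emulating the On / I / Off response shape."""

    baseline_hz: float = 10.0
    on_hz: float = 100.0
    on_window: tuple[float, float] = (1000.0, 1200.0)
    i_window: tuple[float, float] = (1200.0, 1600.0)
    off_hz: float = 30.0
    off_window: tuple[float, float] = (1600.0, 3100.0)
    total_ms: float = 5000.0
    jitter_sd_ms: float = 0.0
    deletion_p: float = 0.0
    locked: bool = True            # On spikes shared across trials (then jittered)

    def __post_init__(self) -> None:
        for r in (self.baseline_hz, self.on_hz, self.off_hz):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not (self.on_window[0] < self.on_window[1] <= self.i_window[0]
                <= self.i_window[1] <= self.off_window[0] < self.off_window[1]):
            raise ValueError("windows must be ordered and disjoint")


def _poisson_times(rng, rate_hz, t0, t1):
    n = rng.poisson(max(rate_hz, 0.0) * (t1 - t0) * 1e-3)
    return rng.uniform(t0, t1, n)


def make_trials(template: MultiphasicTemplate, n_trials: int,
                seed: int | np.random.Generator = 0) -> list[SpikeTrain]:
    """Draw trials from the template's piecewise rate.

    Baseline/Off spikes are independent Poisson per trial; On spikes are
    drawn once from the template (if ``locked``) and then jittered with
    Gaussian sd ``jitter_sd_ms`` and thinned with ``deletion_p`` per trial,
    so the configured jitter is the ground truth for precision estimators.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tpl = template
    on0, on1 = tpl.on_window
    locked_on = _poisson_times(rng, tpl.on_hz, on0, on1) if tpl.locked else None
    trials = []
    for k in range(n_trials):
        parts = [
            _poisson_times(rng, tpl.baseline_hz, 0.0, on0),
            _poisson_times(rng, tpl.off_hz, *tpl.off_window),
            _poisson_times(rng, tpl.baseline_hz, tpl.off_window[1], tpl.total_ms),
        ]
        on = locked_on if tpl.locked else _poisson_times(rng, tpl.on_hz, on0, on1)
        on = np.asarray(on, dtype=float)
        if tpl.deletion_p > 0 and on.size:
            on = on[rng.uniform(size=on.size) >= tpl.deletion_p]
        if tpl.jitter_sd_ms > 0 and on.size:
            on = on + rng.normal(0.0, tpl.jitter_sd_ms, on.size)
        parts.append(np.clip(on, 0.0, tpl.total_ms - 1e-6))
        times = np.sort(np.concatenate(parts))
        # enforce strictly increasing times (duplicates are measure-zero but
        # possible after clipping)
        times = times[np.concatenate([[True], np.diff(times) > 0])]
        trials.append(SpikeTrain(times, trial_id=k))
    return trials


def paper_protocols() -> dict[str, StimulusProtocol | list[StimulusProtocol]]:
    """The standard stimulus designs, as named protocol records.

    * ``dose_series``: single 200-ms pulses at 0.001-10 ng (5 doses).
    * ``gap_series``: 5-pulse trains (200 ms pulses) at air gaps 300-5000 ms.
    * ``duration_series``: single 1-ng pulses of 100-1000 ms.
    * ``randomized_gap_series``: one 5-pulse train whose air gaps are a fixed
      shuffled draw from the 100 ms - 5 s range.
    """
    doses = (0.001, 0.01, 0.1, 1.0, 10.0)
    dose_series = [StimulusProtocol.single(dose=q) for q in doses]
    gaps = (300.0, 500.0, 700.0, 1000.0, 2000.0, 5000.0)
    gap_series = [StimulusProtocol.pulse_train(gap=g) for g in gaps]
    durations = (100.0, 200.0, 500.0, 1000.0)
    duration_series = [StimulusProtocol.single(duration=d) for d in durations]
    rand_gaps = (700.0, 100.0, 2000.0, 5000.0)
    pulses = []
    t = 1000.0
    for g in (0.0,) + rand_gaps:
        t += g
        pulses.append((t, 200.0, 1.0))
        t += 200.0
    randomized = StimulusProtocol(tuple(pulses), t + 6500.0)
    return {
        "dose_series": dose_series,
        "gap_series": gap_series,
        "duration_series": duration_series,
        "randomized_gap_series": randomized,
    }
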