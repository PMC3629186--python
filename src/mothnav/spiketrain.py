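"""Spike-train container shared by the neuron, metrics and controller layers.

A :class:`SpikeTrain` is an ordered sequence of spike times in milliseconds,
tagged with a trial and neuron label.  All recording-like objects in the
package (simulated command-neuron output, sampled ORN populations, synthetic
test ensembles) travel in this form, and the CSV schema
``trial_id,neuron_id,spike_time_ms`` is the on-disk interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeTrain", "read_spike_trains", "write_spike_trains"]


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) with trial/neuron labels."""

    times: np.ndarray
    trial_id: int = 0
    neuron_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if t.size and (np.any(~np.isfinite(t)) or np.any(t < 0)):
            raise ValueError("spike times must be finite and non-negative")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)

    def shifted(self, delta_ms: float) -> "SpikeTrain":
        return SpikeTrain(self.times + delta_ms, self.trial_id, self.neuron_id)

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Spike times in the half-open interval [t0, t1)."""
        t = self.times
        return t[(t >= t0) & (t < t1)]

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def write_spike_trains(trains: list[SpikeTrain], path) -> None:
    rows = [
        (tr.trial_id, tr.neuron_id, t)
        for tr in trains
        for t in tr.times
    ]
    df = pd.DataFrame(rows, columns=["trial_id", "neuron_id", "spike_time_ms"])
    df.to_csv(path, index=False)


def read_spike_trains(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    out = []
    for (trial, neuron), grp in df.groupby(["trial_id", "neuron_id"], sort=True):
        out.append(
            SpikeTrain(np.sort(grp["spike_time_ms"].to_numpy(float)), int(trial), int(neuron))
        )
    return out
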