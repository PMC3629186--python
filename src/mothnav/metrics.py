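"""Spike-train statistics: phase segmentation, precision/reliability,
shuffle surrogates, PSTH, autocorrelation and multi-neuron ROC analysis.

Phase segmentation operationalizes the multiphasic On/I/Off response: the On
burst is the first post-onset epoch whose Gaussian-smoothed firing rate
exceeds a baseline-derived threshold, the inhibitory phase I is the silent
gap that follows it, and the Off phase is the tonic supra-baseline discharge
after I.  The I criterion is spike-gap based (first inter-spike gap >= 120 ms
beginning soon after the On end): at the low spontaneous rates of these
neurons a rate-threshold criterion cannot resolve a few-hundred-ms silence.

Precision sigma and reliability rho follow the pairwise-matching convention:
spikes of every trial pair are greedily matched one-to-one within a window,
sigma is the standard deviation of matched offsets divided by sqrt(2) (so it
estimates the per-trial jitter, not the jitter of the pairwise difference),
and rho is the pooled fraction of unmatched spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import mannwhitneyu

from .spiketrain import SpikeTrain

__all__ = [
    "SegmentationConfig",
    "PhaseSegmentation",
    "PrecisionReliability",
    "RocCurve",
    "smoothed_rate",
    "segment_phases",
    "jitter_reliability",
    "shuffle_isi",
    "shuffle_null",
    "psth",
    "autocorr",
    "roc_multi",
]


@dataclass(frozen=True)
class SegmentationConfig:
    kernel_sd_ms: float = 20.0       # boundary-refinement bandwidth
    detect_sd_ms: float = 50.0       # coarser bandwidth for On detection
    baseline_ms: float = 800.0       # pre-onset window used for baseline stats
    on_floor_hz: float = 15.0        # minimum On threshold
    on_sustain_ms: float = 30.0      # the rate must stay above threshold this long
    on_end_floor_hz: float = 5.0     # On ends when the rate falls below this
    i_gap_min_ms: float = 150.0      # minimum silent gap to call an I phase
    i_search_ms: float = 800.0       # I must start within this after the response offset
    off_floor_hz: float = 1.5
    off_sustain_ms: float = 200.0


@dataclass(frozen=True)
class PhaseSegmentation:
    """Absolute phase boundaries (ms); missing phases are None."""

    onset: float
    on_onset: float | None = None
    on_end: float | None = None
    i_end: float | None = None
    off_end: float | None = None

    @property
    def on_latency(self):
        return None if self.on_onset is None else self.on_onset - self.onset

    @property
    def on_duration(self):
        if self.on_onset is None or self.on_end is None:
            return None
        return self.on_end - self.on_onset

    @property
    def i_duration(self):
        if self.on_end is None or self.i_end is None:
            return None
        return self.i_end - self.on_end

    @property
    def off_duration(self):
        if self.i_end is None or self.off_end is None:
            return None
        return self.off_end - self.i_end


def smoothed_rate(train: SpikeTrain, t0: float, t1: float, sd_ms: float = 20.0):
    """Gaussian-kernel firing-rate estimate on a 1-ms grid over [t0, t1)."""
    edges = np.arange(t0, t1, 1.0)
    counts = np.zeros(edges.shape)
    t = train.window(t0, t1)
    if t.size:
        np.add.at(counts, ((t - t0)).astype(np.int64), 1.0)
    return edges, gaussian_filter1d(counts, sd_ms, mode="constant") * 1000.0


def segment_phases(
    train: SpikeTrain,
    stim: tuple[float, float],
    config: SegmentationConfig = SegmentationConfig(),
    window_end: float | None = None,
) -> PhaseSegmentation:
    """Segment a response into On / I / Off phases.

    ``stim`` is (onset_ms, duration_ms); ``window_end`` truncates the search
    (used for pulse trains, where the next pulse's On ends the current Off).
    Raises if there is no pre-stimulus baseline window.
    """
    onset, duration = stim
    if onset - config.baseline_ms < 0:
        raise ValueError("no pre-stimulus baseline window available")
    t_end = window_end if window_end is not None else (
        train.times[-1] + 200.0 if len(train) else onset + duration + 1000.0
    )
    t_end = max(t_end, onset + duration + 200.0)
    # coarse-bandwidth rate for detection (low baseline variance), fine
    # bandwidth only refines boundaries via the spikes themselves
    grid, r = smoothed_rate(train, onset - config.baseline_ms, t_end, config.detect_sd_ms)
    pre = grid < onset - 3 * config.detect_sd_ms
    base_mean = float(r[pre].mean()) if pre.any() else 0.0
    base_sd = float(r[pre].std()) if pre.any() else 0.0
    base_max = float(r[pre].max()) if pre.any() else 0.0
    thr_on = max(base_mean + 4.0 * base_sd, config.on_floor_hz, 1.3 * base_max)

    # the coarse kernel spreads the On rise ~3 sd backwards in time
    post = grid >= onset - 3.0 * config.detect_sd_ms
    above = r >= thr_on
    up = np.nonzero(post & above & ~np.roll(above, 1))[0]
    # accept the first excursion that stays above threshold long enough
    # (rejects single-spike blips of the smoothed baseline rate)
    t_up = None
    for u in up:
        end = u
        while end < len(above) and above[end]:
            end += 1
        if end - u >= config.on_sustain_ms and r[u:end].max() >= 1.5 * thr_on:
            t_up = grid[u]
            break
    if t_up is None:
        return PhaseSegmentation(onset=onset)
    spikes = train.times
    cand = spikes[spikes >= max(t_up - 1.5 * config.kernel_sd_ms, onset)]
    if cand.size == 0:
        return PhaseSegmentation(onset=onset)
    on_onset = float(cand[0])

    # On end: firing is contiguous (inter-spike gaps below the I-gap bound)
    # from the onset until the burst stops; the first long gap ends the On
    # and is the inhibitory-phase candidate.
    burst = spikes[(spikes >= on_onset) & (spikes < t_end)]
    gaps = np.diff(burst)
    long_gaps = np.nonzero(gaps >= config.i_gap_min_ms)[0]
    if long_gaps.size == 0:
        on_end = float(burst[-1]) if burst.size else on_onset
        return PhaseSegmentation(onset=onset, on_onset=on_onset, on_end=on_end)
    on_end = float(burst[long_gaps[0]])
    seg = PhaseSegmentation(onset=onset, on_onset=on_onset, on_end=on_end)
    stim_locked_limit = onset + duration + config.i_search_ms
    if on_end > stim_locked_limit:
        return seg
    i_end = float(burst[long_gaps[0] + 1])
    seg = PhaseSegmentation(onset=onset, on_onset=on_onset, on_end=on_end, i_end=i_end)

    # Off: tonic discharge until the rate falls back to baseline (sustained)
    thr_off = max(base_mean + base_sd, config.off_floor_hz)
    after = grid >= i_end
    below = (r < thr_off) & after
    run_len = int(config.off_sustain_ms)
    idx = np.nonzero(below)[0]
    off_limit = t_end
    if idx.size:
        # first index from which the rate stays below threshold for the run
        csum = np.cumsum(below.astype(int))
        for i0 in idx:
            i1 = min(i0 + run_len, len(below))
            if csum[i1 - 1] - (csum[i0 - 1] if i0 else 0) == i1 - i0:
                off_limit = grid[i0]
                break
    off_spikes = spikes[(spikes >= i_end) & (spikes <= off_limit)]
    if off_spikes.size == 0:
        return seg
    return PhaseSegmentation(onset=onset, on_onset=on_onset, on_end=on_end,
                             i_end=i_end, off_end=float(off_spikes[-1]))


# --------------------------------------------------------------------------
# precision / reliability


@dataclass(frozen=True)
class PrecisionReliability:
    sigma: float | None
    rho: float
    n_pairs: int
    sigma_star: float | None = None
    rho_star: float | None = None
    p_sigma: float | None = None
    p_rho: float | None = None


def _match_pair(a: np.ndarray, b: np.ndarray, window: float):
    """Greedy one-to-one nearest matching; returns (offsets, n_unmatched)."""
    if a.size == 0 or b.size == 0:
        return np.empty(0), a.size + b.size
    d = np.abs(a[:, None] - b[None, :])
    ii, jj = np.nonzero(d <= window)
    order = np.argsort(d[ii, jj], kind="stable")
    used_a = np.zeros(a.size, bool)
    used_b = np.zeros(b.size, bool)
    offsets = []
    for k in order:
        i, j = ii[k], jj[k]
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            offsets.append(a[i] - b[j])
    m = len(offsets)
    return np.asarray(offsets), (a.size - m) + (b.size - m)


def jitter_reliability(
    trials: list[SpikeTrain], window: float = 25.0, _per_pair: bool = False
):
    """Spike-timing jitter sigma (ms) and fraction of non-coincident spikes rho.

    All trial pairs are matched; sigma = sd of pooled matched offsets / sqrt(2)
    (per-trial jitter convention), rho = pooled unmatched fraction.  With all
    trials empty sigma is undefined (None) and rho = 0 by convention.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    offsets_all, unmatched, total = [], 0, 0
    per_sigma, per_rho = [], []
    n = len(trials)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = trials[i].times, trials[j].times
            off, um = _match_pair(a, b, window)
            offsets_all.append(off)
            unmatched += um
            total += a.size + b.size
            if off.size >= 2:
                per_sigma.append(off.std(ddof=1) / math.sqrt(2.0))
            per_rho.append(um / (a.size + b.size) if (a.size + b.size) else 0.0)
    pooled = np.concatenate(offsets_all) if offsets_all else np.empty(0)
    sigma = float(pooled.std(ddof=1) / math.sqrt(2.0)) if pooled.size >= 2 else None
    rho = unmatched / total if total else 0.0
    res = PrecisionReliability(sigma=sigma, rho=float(rho), n_pairs=n * (n - 1) // 2)
    if _per_pair:
        return res, np.asarray(per_sigma), np.asarray(per_rho)
    return res


def shuffle_isi(train: SpikeTrain, rng: np.random.Generator) -> SpikeTrain:
    """ISI-preserving shuffle: anchor the first spike, permute the ISIs."""
    t = train.times
    if t.size < 2:
        return train
    isis = rng.permutation(np.diff(t))
    return SpikeTrain(t[0] + np.concatenate([[0.0], np.cumsum(isis)]),
                      train.trial_id, train.neuron_id)


def shuffle_null(
    trials: list[SpikeTrain],
    n_surrogates: int = 20,
    seed: int | np.random.Generator = 0,
    window: float = 25.0,
) -> PrecisionReliability:
    """sigma*/rho* from ISI-shuffled surrogates plus Mann-Whitney p-values.

    The surrogate preserves each trial's ISI multiset (first spike anchored)
    while destroying within-trial timing; per-pair sigma and rho of the
    originals are compared against the pooled surrogate values.
    """
    for tr in trials:
        if len(tr) < 2:
            raise ValueError("every trial needs at least two spikes for the shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    res, sig0, rho0 = jitter_reliability(trials, window, _per_pair=True)
    sig_s, rho_s = [], []
    star_sigmas, star_rhos = [], []
    for _ in range(n_surrogates):
        surr = [shuffle_isi(tr, rng) for tr in trials]
        r, ss, rr = jitter_reliability(surr, window, _per_pair=True)
        sig_s.append(ss)
        rho_s.append(rr)
        if r.sigma is not None:
            star_sigmas.append(r.sigma)
        star_rhos.append(r.rho)
    sig_s = np.concatenate(sig_s) if sig_s else np.empty(0)
    rho_s = np.concatenate(rho_s) if rho_s else np.empty(0)
    p_sig = (
        float(mannwhitneyu(sig0, sig_s, alternative="two-sided").pvalue)
        if sig0.size and sig_s.size else None
    )
    p_rho = (
        float(mannwhitneyu(rho0, rho_s, alternative="two-sided").pvalue)
        if rho0.size and rho_s.size else None
    )
    return PrecisionReliability(
        sigma=res.sigma, rho=res.rho, n_pairs=res.n_pairs,
        sigma_star=float(np.mean(star_sigmas)) if star_sigmas else None,
        rho_star=float(np.mean(star_rhos)) if star_rhos else None,
        p_sigma=p_sig, p_rho=p_rho,
    )


# --------------------------------------------------------------------------
# PSTH / autocorrelation / ROC


def psth(
    trials: list[SpikeTrain],
    window: float = 100.0,
    overlap: float = 50.0,
    t_range: tuple[float, float] | None = None,
):
    """Sliding-window mean firing rate (Hz) across trials.

    Window centers advance by (window - overlap); returns (centers, rate).
    """
    if not trials:
        raise ValueError("need at least one trial")
    if overlap >= window:
        raise ValueError("overlap must be smaller than the window")
    if t_range is None:
        hi = max((tr.times[-1] for tr in trials if len(tr)), default=window)
        t_range = (0.0, hi)
    step = window - overlap
    centers = np.arange(t_range[0] + window / 2, t_range[1] - window / 2 + 1e-9, step)
    if centers.size == 0:
        centers = np.array([(t_range[0] + t_range[1]) / 2])
    rates = np.zeros(centers.shape)
    for tr in trials:
        t = tr.times
        for k, c in enumerate(centers):
            rates[k] += np.count_nonzero((t >= c - window / 2) & (t < c + window / 2))
    rates *= 1000.0 / (window * len(trials))
    return centers, rates


def autocorr(train: SpikeTrain, bin_ms: float = 10.0, max_lag_ms: float = 2000.0):
    """Normalized spike-count autocorrelation (value 1 at lag 0).

    Counts are binned; c(tau) = sum_k x_k x_{k+tau} / sum_k x_k^2, evaluated
    for non-negative lags (the function is symmetric).  Empty lag range
    yields empty output.
    """
    if len(train) == 0:
        raise ValueError("train is empty")
    n_lags = int(max_lag_ms / bin_ms)
    if n_lags <= 0:
        return np.empty(0), np.empty(0)
    t = train.times
    n_bins = int(t[-1] / bin_ms) + 1
    x = np.zeros(n_bins)
    np.add.at(x, (t / bin_ms).astype(np.int64), 1.0)
    denom = float(np.dot(x, x))
    lags = np.arange(n_lags + 1)
    c = np.array([np.dot(x[: n_bins - L], x[L:]) / denom if L < n_bins else 0.0
                  for L in lags])
    return lags * bin_ms, c


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _coincidence_counts(trial: list[SpikeTrain], window: float, interval) -> int:
    """Count reference-neuron spikes coincident across all k neurons."""
    lo, hi = interval
    ref = trial[0].window(lo, hi)
    if len(trial) == 1:
        return ref.size
    ok = np.ones(ref.size, dtype=bool)
    for other in trial[1:]:
        t = other.times
        if t.size == 0:
            return 0
        idx = np.searchsorted(t, ref)
        near = np.full(ref.size, np.inf)
        left = idx > 0
        near[left] = np.abs(ref[left] - t[idx[left] - 1])
        right = idx < t.size
        near[right] = np.minimum(near[right], np.abs(t[idx[right]] - ref[right]))
        ok &= near <= window
    return int(ok.sum())


def roc_multi(
    signal_trials: list[list[SpikeTrain]],
    noise_trials: list[list[SpikeTrain]],
    k: int | None = None,
    window: float = 5.0,
    interval: tuple[float, float] = (0.0, 500.0),
) -> RocCurve:
    """ROC over a k-neuron coincidence-count detection statistic.

    Each trial is a list of simultaneously recorded trains (one per neuron);
    the statistic is the number of reference-neuron spikes in ``interval``
    that have a coincident spike (within ``window`` ms) in every other
    neuron.  The ROC is swept over the integer count threshold and the AUC
    computed by trapezoid.
    """
    if not signal_trials or not noise_trials:
        raise ValueError("need signal and noise trials")
    widths = {len(tr) for tr in signal_trials} | {len(tr) for tr in noise_trials}
    if len(widths) != 1:
        raise ValueError("all trials must contain the same number of neurons")
    k_found = widths.pop()
    if k is not None and k != k_found:
        raise ValueError(f"trials contain {k_found} neurons, expected {k}")
    s = np.array([_coincidence_counts(tr, window, interval) for tr in signal_trials])
    n = np.array([_coincidence_counts(tr, window, interval) for tr in noise_trials])
    # descending thresholds trace the ROC from (0, 0) to (1, 1)
    thresholds = np.unique(np.concatenate([[0], s, n, [max(s.max(), n.max()) + 1]]))[::-1]
    tpr = np.array([(s >= th).mean() for th in thresholds])
    fpr = np.array([(n >= th).mean() for th in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
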