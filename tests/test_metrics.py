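"""Unit tests for segmentation, precision/reliability, PSTH, autocorrelation
and ROC analysis, using synthetic ensembles with known ground truth."""

import dataclasses

import numpy as np
import pytest

from mothnav.fixtures import MultiphasicTemplate, make_trials
from mothnav.metrics import (
    SegmentationConfig,
    autocorr,
    jitter_reliability,
    psth,
    roc_multi,
    segment_phases,
    shuffle_isi,
    shuffle_null,
)
from mothnav.spiketrain import SpikeTrain
from tests.conftest import poisson_train


@pytest.fixture
def multiphasic(rng):
    tpl = MultiphasicTemplate(
        baseline_hz=10.0, on_hz=100.0, on_window=(1000.0, 1200.0),
        i_window=(1200.0, 1600.0), off_hz=30.0, off_window=(1600.0, 3100.0),
        total_ms=5000.0, locked=False,
    )
    return make_trials(tpl, 8, seed=rng)


class TestSegmentation:
    def test_recovers_constructed_boundaries(self, multiphasic):
        on, i, off = [], [], []
        for tr in multiphasic:
            seg = segment_phases(tr, (1000.0, 200.0))
            if seg.on_duration is not None:
                on.append(seg.on_duration)
            if seg.i_duration is not None:
                i.append(seg.i_duration)
            if seg.off_duration is not None:
                off.append(seg.off_duration)
        assert np.mean(on) == pytest.approx(200.0, rel=0.2)
        assert np.mean(i) == pytest.approx(400.0, rel=0.2)
        assert np.mean(off) == pytest.approx(1500.0, rel=0.2)

    def test_pure_poisson_has_no_on(self, rng):
        tr = SpikeTrain(poisson_train(rng, 10.0, 0.0, 5000.0))
        seg = segment_phases(tr, (1000.0, 200.0))
        assert seg.on_onset is None

    def test_requires_baseline_window(self, rng):
        tr = SpikeTrain(poisson_train(rng, 10.0, 0.0, 2000.0))
        with pytest.raises(ValueError, match="baseline"):
            segment_phases(tr, (100.0, 200.0))

    def test_translation_equivariance(self, multiphasic):
        delta = 1500.0
        tr = multiphasic[0]
        seg0 = segment_phases(tr, (1000.0, 200.0))
        seg1 = segment_phases(tr.shifted(delta), (1000.0 + delta, 200.0))
        for name in ("on_onset", "on_end", "i_end", "off_end"):
            a, b = getattr(seg0, name), getattr(seg1, name)
            if a is None:
                assert b is None
            else:
                assert b == pytest.approx(a + delta, abs=1e-6)


class TestJitterReliability:
    def test_identical_trials_are_perfectly_precise(self, rng):
        t = poisson_train(rng, 50.0, 0.0, 1000.0)
        res = jitter_reliability([SpikeTrain(t, trial_id=k) for k in range(4)])
        assert res.sigma == pytest.approx(0.0, abs=1e-12)
        assert res.rho == 0.0
        assert res.n_pairs == 6

    def test_recovers_known_jitter(self, rng):
        base = np.sort(rng.uniform(100.0, 900.0, 60))
        trials = [SpikeTrain(np.sort(base + rng.normal(0, 3.0, base.size)), trial_id=k)
                  for k in range(10)]
        res = jitter_reliability(trials)
        # sd of pairwise offsets is 3*sqrt(2); the /sqrt(2) convention maps it
        # back to the per-trial jitter
        assert 2.2 < res.sigma < 3.8
        assert res.rho < 0.1

    def test_empty_versus_full_pair_is_unreliable(self, rng):
        full = SpikeTrain(poisson_train(rng, 40.0, 0.0, 1000.0), trial_id=0)
        empty = SpikeTrain(np.empty(0), trial_id=1)
        res = jitter_reliability([full, empty])
        assert res.rho == 1.0
        assert res.sigma is None

    def test_all_empty_by_convention(self):
        res = jitter_reliability([SpikeTrain(np.empty(0)), SpikeTrain(np.empty(0))])
        assert res.sigma is None
        assert res.rho == 0.0

    def test_trial_order_invariance(self, rng):
        trials = [SpikeTrain(poisson_train(rng, 30.0, 0.0, 2000.0), trial_id=k)
                  for k in range(5)]
        a = jitter_reliability(trials)
        b = jitter_reliability(trials[::-1])
        assert a.sigma == pytest.approx(b.sigma)
        assert a.rho == pytest.approx(b.rho)


class TestShuffleNull:
    def test_shuffle_preserves_isi_multiset(self, rng):
        tr = SpikeTrain(poisson_train(rng, 40.0, 0.0, 2000.0))
        surr = shuffle_isi(tr, rng)
        assert np.allclose(np.sort(np.diff(tr.times)), np.sort(np.diff(surr.times)))
        assert surr.times[0] == tr.times[0]

    def test_phase_locked_ensemble_beats_null(self, rng):
        base = np.sort(rng.uniform(1000.0, 1200.0, 25))
        trials = []
        for k in range(10):
            on = base + rng.normal(0, 2.0, base.size)
            bg = poisson_train(rng, 8.0, 0.0, 3000.0)
            trials.append(SpikeTrain(np.sort(np.concatenate([on, bg])), trial_id=k))
        res = shuffle_null(trials, n_surrogates=10, seed=rng)
        assert res.sigma < res.sigma_star
        assert res.p_sigma < 0.05

    def test_homogeneous_poisson_is_usually_not_significant(self):
        n_sig = 0
        reps = 12
        for r in range(reps):
            rr = np.random.default_rng(500 + r)
            trials = [SpikeTrain(poisson_train(rr, 25.0, 0.0, 2000.0), trial_id=k)
                      for k in range(8)]
            res = shuffle_null(trials, n_surrogates=8, seed=rr)
            if res.p_sigma is not None and res.p_sigma < 0.05:
                n_sig += 1
        assert n_sig <= reps - int(0.75 * reps)


class TestPsth:
    def test_empty_trials_give_zero(self):
        centers, rates = psth([SpikeTrain(np.empty(0))], t_range=(0.0, 1000.0))
        assert np.all(rates == 0.0)
        assert np.allclose(np.diff(centers), 50.0)

    def test_poisson_rate_recovered(self, rng):
        trials = [SpikeTrain(poisson_train(rng, 20.0, 0.0, 5000.0), trial_id=k)
                  for k in range(50)]
        _, rates = psth(trials, t_range=(0.0, 5000.0))
        assert abs(rates.mean() - 20.0) < 2.0

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            psth([SpikeTrain(np.array([1.0]))], window=100.0, overlap=100.0)


class TestAutocorr:
    def test_periodic_train_peaks_at_period(self):
        t = np.concatenate([k * 500.0 + np.arange(0.0, 60.0, 10.0) for k in range(12)])
        lags, c = autocorr(SpikeTrain(np.unique(t)), bin_ms=10.0, max_lag_ms=1600.0)
        assert c[0] == pytest.approx(1.0)
        for period in (500.0, 1000.0, 1500.0):
            k = int(period / 10.0)
            window = c[k - 10 : k + 11]
            assert c[k] >= 0.8 * window.max()
            assert c[k] > c[k - 25]

    def test_poisson_is_flat_relative_to_shuffle(self, rng):
        tr = SpikeTrain(poisson_train(rng, 30.0, 0.0, 30000.0))
        lags, c = autocorr(tr, bin_ms=10.0, max_lag_ms=1000.0)
        body = c[5:]
        null_sd = body.std()
        assert body.max() - body.mean() < 5.0 * null_sd

    def test_empty_lag_range(self, rng):
        tr = SpikeTrain(poisson_train(rng, 30.0, 0.0, 1000.0))
        lags, c = autocorr(tr, bin_ms=10.0, max_lag_ms=0.0)
        assert lags.size == 0 and c.size == 0


class TestRoc:
    @staticmethod
    def _trials(rng, rate_hz, n, k=1):
        return [[SpikeTrain(poisson_train(rng, rate_hz, 0.0, 500.0), neuron_id=j)
                 for j in range(k)] for _ in range(n)]

    def test_no_information_auc_half(self, rng):
        s = self._trials(rng, 20.0, 500)
        n = self._trials(rng, 20.0, 500)
        assert roc_multi(s, n).auc == pytest.approx(0.5, abs=0.05)

    def test_perfect_separation_auc_one(self, rng):
        s = self._trials(rng, 80.0, 100)
        n = [[SpikeTrain(np.empty(0))] for _ in range(100)]
        assert roc_multi(s, n).auc == 1.0

    def test_multi_neuron_ordering(self, rng):
        # a few shared stimulus-locked spikes buried in strong independent
        # noise: single-neuron counts barely separate signal from noise, but
        # chance k-wise coincidences are rare, so multi-neuron coincidence
        # counts separate progressively better
        def pop(locked):
            out = []
            for _ in range(200):
                trial = []
                base = np.sort(rng.uniform(0.0, 500.0, 4)) if locked else None
                for j in range(3):
                    noise = poisson_train(rng, 70.0, 0.0, 500.0)
                    if locked:
                        t = np.concatenate([base + rng.normal(0, 1.5, base.size), noise])
                    else:
                        t = noise
                    trial.append(SpikeTrain(np.unique(np.clip(np.sort(t), 0, None)), neuron_id=j))
                out.append(trial)
            return out

        sig, noi = pop(True), pop(False)
        aucs = {}
        for k in (1, 2, 3):
            s_k = [tr[:k] for tr in sig]
            n_k = [tr[:k] for tr in noi]
            aucs[k] = roc_multi(s_k, n_k, window=5.0).auc
        assert aucs[3] > aucs[2] > aucs[1]
        assert aucs[1] < 0.8

    def test_mismatched_neuron_counts_rejected(self, rng):
        s = self._trials(rng, 20.0, 5, k=2)
        n = self._trials(rng, 20.0, 5, k=1)
        with pytest.raises(ValueError):
            roc_multi(s, n)
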