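"""Unit tests for the ORN population rate model, Poisson sampling and drive."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from mothnav.orn import (
    DriveKernel,
    ORNRateModel,
    StimulusProtocol,
    calibrate_dose_law,
    drive_from_spikes,
    rate,
    sample_population,
    sample_population_counts,
)
from mothnav.spiketrain import SpikeTrain


@pytest.fixture(scope="module")
def model():
    return ORNRateModel()


class TestProtocol:
    def test_rejects_overlapping_pulses(self):
        with pytest.raises(ValueError):
            StimulusProtocol(((0.0, 300.0, 1.0), (200.0, 200.0, 1.0)), 2000.0)

    def test_rejects_nonpositive_dose(self):
        with pytest.raises(ValueError):
            StimulusProtocol(((0.0, 200.0, 0.0),), 1000.0)

    def test_air_gaps(self):
        p = StimulusProtocol.pulse_train(n_pulses=3, duration=200.0, gap=500.0)
        assert np.allclose(p.air_gaps(), [500.0, 500.0])

    def test_csv_round_trip(self, tmp_path):
        p = StimulusProtocol.pulse_train(n_pulses=2, gap=700.0)
        p.to_csv(tmp_path / "p.csv")
        q = StimulusProtocol.from_csv(tmp_path / "p.csv")
        assert q.pulses == p.pulses


class TestRate:
    def test_baseline_before_onset(self, model):
        p = StimulusProtocol.single()
        assert rate(model, p, 500.0) == pytest.approx(model.baseline_hz)

    def test_triphasic_shape(self, model):
        p = StimulusProtocol.single(onset=1000.0, duration=200.0, dose=1.0)
        s = 1000.0 + model.onset_latency(1.0)
        peak = rate(model, p, s + 60.0)
        plateau = rate(model, p, s + 195.0)
        late = rate(model, p, s + 200.0 + 15000.0)
        assert peak > plateau > model.baseline_hz
        assert late == pytest.approx(model.baseline_hz, abs=1.0)

    def test_response_integral_grows_with_duration(self, model):
        integrals = []
        for dur in (200.0, 500.0, 1000.0):
            p = StimulusProtocol.single(duration=dur, tail=15000.0)
            t = np.arange(0.0, p.total_duration, 1.0)
            integrals.append(np.trapezoid(rate(model, p, t) - model.baseline_hz, t))
        assert integrals[0] < integrals[1] < integrals[2]

    def test_rate_is_clamped_nonnegative_and_ceiling(self, model):
        p = StimulusProtocol.pulse_train(n_pulses=5, gap=300.0, dose=10.0)
        lam = rate(model, p, np.arange(0.0, p.total_duration, 5.0))
        assert lam.min() >= 0.0
        assert lam.max() <= model.ceiling_hz


class TestSampling:
    def test_zero_rate_gives_empty_trains(self):
        m = ORNRateModel(baseline_hz=0.0)
        p = StimulusProtocol(((5000.0, 200.0, 1e-9),), 6000.0)
        trains = sample_population(m, p, seed=0, n_orns=5)
        # dose ~0 contributes ~0 amplitude; all spikes come from thinning the
        # near-zero rate
        assert sum(len(t) for t in trains) <= 1

    def test_seed_determinism(self, model):
        p = StimulusProtocol.single(tail=1000.0)
        a = sample_population(model, p, seed=5, n_orns=3)
        b = sample_population(model, p, seed=5, n_orns=3)
        c = sample_population(model, p, seed=6, n_orns=3)
        assert all(np.array_equal(x.times, y.times) for x, y in zip(a, b))
        assert any(not np.array_equal(x.times, y.times) for x, y in zip(a, c))

    def test_counts_are_poisson_chisquare(self):
        # constant 20 Hz for 10 s -> per-train counts ~ Poisson(200)
        m = ORNRateModel(baseline_hz=20.0)
        p = StimulusProtocol(((9990.0, 5.0, 1e-9),), 10000.0)
        trains = sample_population(m, p, seed=1, n_orns=200)
        counts = np.array([len(t) for t in trains])
        mu = 200.0
        edges = sps.poisson.ppf([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0], mu)
        edges[0], edges[-1] = -np.inf, np.inf
        obs, _ = np.histogram(counts, bins=edges)
        probs = np.diff(sps.poisson.cdf(np.concatenate([[-1], edges[1:-1], [1e9]]), mu))
        stat, pval = sps.chisquare(obs, probs * counts.size, ddof=0)
        assert pval > 0.01

    def test_thinning_matches_binned_sampler_in_distribution(self, model):
        # same rate profile sampled two ways; spike counts per realization
        p = StimulusProtocol.single(tail=2000.0)
        thin = [sum(len(t) for t in sample_population(model, p, seed=s))
                for s in range(120)]
        binned = [int(sample_population_counts(model, p, seed=10_000 + s).sum())
                  for s in range(120)]
        assert sps.ks_2samp(thin, binned).pvalue > 0.01

    def test_population_psth_converges_to_rate(self, model):
        p = StimulusProtocol.single(tail=3000.0)
        n_rep = 300
        acc = np.zeros(int(p.total_duration))
        for s in range(n_rep):
            acc += sample_population_counts(model, p, seed=s)
        t = np.arange(0.0, p.total_duration, 1.0) + 0.5
        lam = rate(model, p, t) * model.n_orns * 1e-3
        # compare on 100-ms averages
        k = 100
        est = acc.reshape(-1, k).mean(axis=1) / n_rep
        ref = lam.reshape(-1, k).mean(axis=1)
        rel_l2 = np.linalg.norm(est - ref) / np.linalg.norm(ref)
        assert rel_l2 < 0.10


class TestDrive:
    kernel = DriveKernel(amplitude_na=0.05, tau_ms=10.0)

    def test_no_spikes_zero_drive(self):
        d = drive_from_spikes([SpikeTrain(np.empty(0))], self.kernel, 100.0)
        assert np.all(d == 0.0)

    def test_single_spike_kernel_shape(self):
        d = drive_from_spikes([SpikeTrain(np.array([10.0]))], self.kernel, 100.0)
        assert d[9] == 0.0
        assert d[10] == pytest.approx(self.kernel.amplitude_na, rel=1e-9)
        assert d[30] == pytest.approx(self.kernel.amplitude_na * np.exp(-20.0 / 10.0), rel=1e-6)

    def test_linearity(self, rng):
        a = SpikeTrain(np.sort(rng.uniform(0, 500, 40)))
        b = SpikeTrain(np.sort(rng.uniform(0, 500, 25)))
        d_ab = drive_from_spikes([a, b], self.kernel, 600.0)
        d_a = drive_from_spikes([a], self.kernel, 600.0)
        d_b = drive_from_spikes([b], self.kernel, 600.0)
        assert np.allclose(d_ab, d_a + d_b, atol=1e-12)


def test_calibrate_dose_law_fixes_slope_and_intercept():
    # synthetic pipeline: measured latency = model latency + dose-dependent
    # distortion; calibration must absorb the distortion
    def measure(model, dose, seed):
        return model.onset_latency(dose) + 30.0 - 4.0 * np.log10(dose)

    fitted, diag = calibrate_dose_law(ORNRateModel(), measure, n_runs=1, n_iter=4)
    assert diag["converged"]
    assert abs(diag["measured_slope"] + 16.0) <= 3.0
    assert abs(diag["measured_lat_1ng"] - 230.0) <= 10.0
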