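"""Electrophysiology: referencing, both artifact removers, beta-band power,
spike detection, PSTH and ISI summaries."""

import numpy as np
import pytest
from scipy.signal import periodogram

from duoprobe import ephys, synth
from duoprobe.synth import EPhysTrace


def _tone(freq, fs=20_000.0, dur=20.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return EPhysTrace(samples=amp * np.cos(2 * np.pi * freq * t), fs=fs)


class TestBipolar:
    def test_identical_traces_cancel(self):
        a = _tone(20.0)
        out = ephys.bipolar_reference(a, a)
        assert np.allclose(out.samples, 0.0)
        assert out.reference[0] == "bipolar"

    def test_shared_artifact_cancels_exactly(self):
        rng = np.random.default_rng(0)
        shared = rng.standard_normal(10_000)
        a = EPhysTrace(shared + rng.standard_normal(10_000), fs=1000.0,
                       channel="a")
        b = EPhysTrace(shared + rng.standard_normal(10_000), fs=1000.0,
                       channel="b")
        out = ephys.bipolar_reference(a, b)
        # the difference contains no trace of the shared component
        assert np.allclose(out.samples,
                           a.samples - shared - (b.samples - shared))

    def test_mismatched_rates_rejected(self):
        with pytest.raises(ValueError):
            ephys.bipolar_reference(_tone(20, fs=1000), _tone(20, fs=2000))


class TestSpectralRemoval:
    def test_only_interpolated_bins_change(self):
        rng = np.random.default_rng(1)
        tr = EPhysTrace(rng.standard_normal(60_000), fs=1000.0)
        out = ephys.remove_artifacts_spectral(tr, scan_rate_hz=10.0,
                                              n_harmonics=5)
        fa = np.fft.rfft(tr.samples)
        fb = np.fft.rfft(out.samples)
        changed = np.flatnonzero(~np.isclose(fa, fb, atol=1e-8))
        df = tr.fs / tr.samples.size
        freqs = changed * df
        # every altered bin sits within the notch of a 10 Hz harmonic
        assert freqs.size > 0
        near = np.abs(freqs / 10.0 - np.round(freqs / 10.0)) * 10.0
        assert np.all(near <= 2 * df + 1e-9)

    def test_harmonic_power_suppressed_to_flank_level(self):
        from scipy.signal import welch

        fs, dur = 2000.0, 60.0
        t = np.arange(int(dur * fs)) / fs
        rng = np.random.default_rng(7)
        art = np.zeros(t.size)
        tmpl = synth.artifact_template(fs, 8.5e-3, 200.0)
        for ta in np.arange(0.0, dur, 0.1):
            i0 = int(round(ta * fs))
            art[i0:i0 + tmpl.size] += tmpl[: t.size - i0]
        x = 5.0 * np.sin(2 * np.pi * 21.5 * t) + art + 0.5 * rng.standard_normal(t.size)
        tr = EPhysTrace(x, fs=fs)
        out = ephys.remove_artifacts_spectral(tr)
        # averaged spectrum over period-aligned segments keeps harmonics on-bin
        f, p0 = welch(tr.samples, fs=fs, nperseg=4000, noverlap=0,
                      window="boxcar")
        _, p1 = welch(out.samples, fs=fs, nperseg=4000, noverlap=0,
                      window="boxcar")
        for h in (10.0, 20.0, 30.0):
            i = int(round(h / f[1]))
            flank = np.median(np.r_[p1[i - 8:i - 2], p1[i + 3:i + 9]])
            assert p0[i] > 20.0 * flank          # artifact line present before
            assert p1[i] <= 2.0 * flank          # and gone after

    def test_beta_envelope_recovered_from_artifacted_trace(
            self, ephys_session, ephys_session_clean):
        dirty, _ = ephys_session
        clean, _ = ephys_session_clean
        env_fixed = ephys.beta_power(ephys.remove_artifacts_spectral(dirty))
        env_clean = ephys.beta_power(clean)
        rms_err = np.sqrt(np.mean((env_fixed.power - env_clean.power) ** 2))
        rms_ref = np.sqrt(np.mean(env_clean.power ** 2))
        assert rms_err <= 0.10 * rms_ref

    def test_excess_harmonics_clipped_with_warning(self):
        tr = _tone(20.0, fs=1000.0, dur=5.0)
        with pytest.warns(UserWarning, match="clipped"):
            ephys.remove_artifacts_spectral(tr, n_harmonics=500)


class TestTimeRemoval:
    def test_no_artifacts_is_identity(self):
        tr = _tone(20.0, dur=2.0)
        out = ephys.remove_artifacts_time(tr, [])
        assert np.array_equal(out.samples, tr.samples)

    def test_untouched_samples_are_bit_exact(self):
        rng = np.random.default_rng(2)
        tr = EPhysTrace(rng.standard_normal(40_000), fs=20_000.0)
        out = ephys.remove_artifacts_time(tr, [0.5, 1.0])
        touched = np.zeros(tr.samples.size, dtype=bool)
        for t in (0.5, 1.0):
            lo = int((t - 1e-3) * tr.fs) - 1
            hi = int(np.ceil((t + 8.5e-3 + 2e-3) * tr.fs)) + 1
            touched[lo:hi + 1] = True
        assert np.array_equal(out.samples[~touched], tr.samples[~touched])
        assert not np.array_equal(out.samples[touched], tr.samples[touched])

    def test_overlapping_windows_rejected(self):
        tr = _tone(20.0, dur=1.0)
        with pytest.raises(ValueError, match="overlap"):
            ephys.remove_artifacts_time(tr, [0.5, 0.505])

    def test_spike_between_artifacts_preserved(self):
        fs = 20_000.0
        x = np.zeros(int(fs))
        w = synth.spike_template(fs, trough_uV=-80.0)
        i0 = int(0.55 * fs)
        x[i0:i0 + w.size] = w
        tr = EPhysTrace(x, fs=fs)
        out = ephys.remove_artifacts_time(tr, [0.5, 0.6])
        assert np.array_equal(out.samples[i0:i0 + w.size], w)


class TestBetaPower:
    def test_zero_input_zero_envelope(self):
        env = ephys.beta_power(EPhysTrace(np.zeros(40_000), fs=2000.0))
        assert np.allclose(env.power, 0.0)

    def test_unit_in_band_tone_reads_unit_power(self):
        env = ephys.beta_power(_tone(20.0))
        mid = env.power[int(5 * env.fs): int(15 * env.fs)]
        assert np.all(np.abs(mid - 1.0) < 0.05)

    def test_out_of_band_tone_rejected_20db(self):
        env = ephys.beta_power(_tone(50.0))
        mid = env.power[int(5 * env.fs): int(15 * env.fs)]
        assert np.max(mid) <= 0.01

    def test_envelope_nonnegative_on_noise(self):
        rng = np.random.default_rng(3)
        env = ephys.beta_power(EPhysTrace(rng.standard_normal(60_000),
                                          fs=2000.0))
        assert np.all(env.power >= 0.0)

    def test_padding_invariance_mid_trace(self):
        tr = _tone(20.0, dur=10.0)
        padded = EPhysTrace(np.r_[np.zeros(4096), tr.samples, np.zeros(4096)],
                            fs=tr.fs)
        e1 = ephys.beta_power(tr).power
        e2 = ephys.beta_power(padded).power
        off = int(4096 / tr.fs * 1000)
        mid = slice(int(3 * 1000), int(7 * 1000))
        ratio = e2[off + mid.start: off + mid.stop] / e1[mid]
        assert np.all(np.abs(ratio - 1.0) < 0.01)

    def test_rectify_method_agrees_for_narrowband(self):
        env_h = ephys.beta_power(_tone(20.0), method="hilbert")
        env_r = ephys.beta_power(_tone(20.0), method="rectify")
        mid = slice(int(5e3), int(15e3))
        assert np.allclose(env_h.power[mid], env_r.power[mid], rtol=0.05)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            ephys.beta_power(_tone(20.0), band=(28.0, 13.0))


class TestDetectSpikes:
    def test_zero_trace_zero_spikes(self):
        out = ephys.detect_spikes(EPhysTrace(np.zeros(40_000), fs=20_000.0))
        assert out.times.size == 0

    def test_false_positive_rate_matches_rice_crossing_theory(self):
        """On pure Gaussian noise a -4 sigma threshold fires at roughly
        nu0 * exp(-8) where nu0 is the band's RMS frequency (~3.5 kHz for
        300-6000 Hz): about 1/s, far below simulated firing rates."""
        rng = np.random.default_rng(4)
        fs = 30_000.0
        tr = EPhysTrace(rng.standard_normal(int(60 * fs)), fs=fs)
        out = ephys.detect_spikes(tr)
        rate = out.times.size / tr.duration
        f1, f2 = 300.0, 6000.0
        nu0 = np.sqrt((f2 ** 3 - f1 ** 3) / (3 * (f2 - f1)))
        rice = nu0 * np.exp(-8.0)
        assert rate < 3.0
        assert 0.2 * rice < rate < 3.0 * rice

    def test_recall_and_precision_on_clean_poisson_train(self):
        trials = synth.simulate_trials("shape", 8, seed=31)
        tr, truth = synth.simulate_ephys_session(
            trials, fs=20_000.0, artifact_amp_uV=0.0, spike_rate_hz=20.0,
            spike_snr=10.0, seed=31)
        out = ephys.detect_spikes(tr)
        from duoprobe.pipeline import _match_spikes
        m = _match_spikes(out.times, truth.spike_times)
        assert m["recall"] >= 0.95
        assert m["precision"] >= 0.90

    def test_lockout_enforced(self, ephys_session):
        tr, truth = ephys_session
        cleaned = ephys.remove_artifacts_time(tr, truth.artifact_times)
        out = ephys.detect_spikes(cleaned)
        if out.times.size > 1:
            assert np.min(np.diff(out.times)) >= 1e-3 - 1e-9

    def test_snippets_trough_aligned(self):
        trials = synth.simulate_trials("shape", 4, seed=32)
        tr, _ = synth.simulate_ephys_session(
            trials, fs=20_000.0, artifact_amp_uV=0.0, spike_snr=12.0, seed=32)
        out = ephys.detect_spikes(tr)
        centers = np.argmin(out.snippets, axis=1)
        zero = np.flatnonzero(out.snippet_offsets == 0)[0]
        assert np.median(np.abs(centers - zero)) == 0


class TestSummaries:
    def test_homogeneous_poisson_psth_is_flat(self):
        rng = np.random.default_rng(5)
        lam, n_trials = 20.0, 300
        spikes = np.sort(rng.uniform(0, 700.0, rng.poisson(lam * 700)))
        events = np.arange(2.0, 690.0, 2.25)[:n_trials]
        centers, rates, n = ephys.psth(spikes, events, window=(-1, 1),
                                       bin_width=0.05)
        se = np.sqrt(lam / (n_trials * 0.05))
        z = (rates["all"] - lam) / se
        assert abs(z.mean()) < 3.0 / np.sqrt(z.size)   # unbiased overall
        assert np.max(np.abs(z)) < 4.5                 # no bin far off

    def test_no_spikes_zero_psth(self):
        centers, rates, _ = ephys.psth(np.empty(0), np.array([1.0, 2.0]))
        assert np.allclose(rates["all"], 0.0)

    def test_rate_step_recovered_from_simulator(self):
        trials = synth.simulate_trials("shape", 200, seed=33)
        trials["reward"] = "large"     # uniform doubling after reward
        _, truth = synth.simulate_ephys_session(
            trials, fs=2000.0, beta_tonic_uV=0.0, beta_burst_uV=0.0,
            artifact_amp_uV=0.0, spike_rate_hz=10.0,
            spike_reward_gain_large=2.0, spike_mod_duration_s=0.6, seed=33)
        centers, rates, _ = ephys.psth(truth.spike_times,
                                       trials["t_reward"].to_numpy(),
                                       window=(-1.0, 0.6), bin_width=0.1)
        pre = rates["all"][centers < 0].mean()
        post = rates["all"][centers > 0].mean()
        assert post / pre == pytest.approx(2.0, rel=0.10)

    def test_regular_train_single_isi_bin(self):
        # 100.5 ms period sits mid-bin, away from floating-point edge ties
        edges, counts = ephys.isi_histogram(np.arange(100) * 0.1005)
        occupied = np.flatnonzero(counts)
        assert occupied.size == 1
        assert edges[occupied[0]] == pytest.approx(0.100, abs=1e-9)
        assert counts[occupied[0]] == 99

    def test_isi_counts_conserved(self):
        rng = np.random.default_rng(6)
        times = np.sort(rng.uniform(0, 10, 250))
        _, counts = ephys.isi_histogram(times, max_isi_s=20.0)
        assert counts.sum() == times.size - 1

    def test_refractory_period_empty_bins(self):
        trials = synth.simulate_trials("shape", 50, seed=34)
        _, truth = synth.simulate_ephys_session(
            trials, fs=2000.0, beta_tonic_uV=0.0, beta_burst_uV=0.0,
            artifact_amp_uV=0.0, spike_rate_hz=40.0,
            spike_refractory_s=2e-3, seed=34)
        edges, counts = ephys.isi_histogram(truth.spike_times)
        assert counts[edges[:-1] < 2e-3 - 1e-9].sum() == 0

    def test_fewer_than_two_spikes_empty(self):
        edges, counts = ephys.isi_histogram(np.array([1.0]))
        assert edges.size == 0 and counts.size == 0
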