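"""Shared fixtures: one synthetic session pair (FSCV + ephys) and one fitted
chemometric model, generated once per test run."""

import numpy as np
import pytest

from duoprobe import fscv, synth


@pytest.fixture(scope="session")
def waveform():
    return synth.generate_waveform()


@pytest.fixture(scope="session")
def templates(waveform):
    return synth.make_templates(waveform)


@pytest.fixture(scope="session")
def trials16():
    return synth.simulate_trials("shape", 16, seed=11)


@pytest.fixture(scope="session")
def fscv_session(trials16, templates):
    """Default-noise 16-trial color plot plus ground truth."""
    return synth.simulate_fscv_session(trials16, templates, seed=11)


@pytest.fixture(scope="session")
def ephys_session(trials16):
    """Wide-band 16-trial trace (20 kHz keeps the suite fast; the spike band
    300-6000 Hz is fully below Nyquist) plus ground truth."""
    return synth.simulate_ephys_session(trials16, fs=20_000.0, seed=11)


@pytest.fixture(scope="session")
def ephys_session_clean(trials16):
    """Same seed with the scan artifact disabled (clean-render oracle)."""
    return synth.simulate_ephys_session(trials16, fs=20_000.0, seed=11,
                                        artifact_amp_uV=0.0)


@pytest.fixture(scope="session")
def pcr_model(templates):
    standards, conc, movement = fscv.make_training_bank(templates)
    return fscv.fit_pcr(standards, conc, analytes=fscv.BANK_ANALYTES,
                        movement_standards=movement)


def postcue_effect(rel, matrix, labels, window=(0.2, 2.0)):
    """Mean(large) - mean(small) over a post-cue window, NaN-excluding."""
    import warnings

    sel = (rel >= window[0]) & (rel <= window[1])
    labels = np.asarray(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        large = np.nanmean(matrix[labels == "large"][:, sel])
        small = np.nanmean(matrix[labels == "small"][:, sel])
    return large - small


def epoch_matrix(times, values, event_times, window, reference_event=False):
    """Truth-side epoch extraction on a uniform grid (floor frame indexing)."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    dt = float(np.median(np.diff(times)))
    lo, hi = int(round(window[0] / dt)), int(round(window[1] / dt))
    rel = np.arange(lo, hi + 1) * dt
    rows = []
    for t_ev in event_times:
        i0 = int(np.floor((t_ev - times[0]) / dt + 1e-9))
        if i0 + lo < 0 or i0 + hi >= times.size:
            rows.append(np.full(rel.size, np.nan))
            continue
        seg = values[i0 + lo: i0 + hi + 1].astype(float).copy()
        if reference_event:
            seg -= values[i0]
        rows.append(seg)
    return rel, np.asarray(rows)
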