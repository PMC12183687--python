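"""Artifact-tolerant electrophysiology: scan-artifact removal (spectral and
time-domain), beta-band power envelopes, threshold spike detection, PSTH and
ISI summaries.

The FSCV scan couples a stereotyped transient into concurrently recorded
voltage every repetition interval (10 Hz).  For low-frequency (LFP) analysis
the artifact train is removed in the frequency domain by interpolating the
discrete-spectrum bins at the scan frequency and its harmonics; for spike
analysis the artifact epochs are excised and bridged by polynomial
interpolation in the time domain, which preserves high-frequency content
everywhere else sample-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from math import gcd
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt, hilbert, resample_poly

from .synth import EPhysTrace

__all__ = [
    "SpikeSet",
    "BetaEnvelope",
    "bipolar_reference",
    "remove_artifacts_spectral",
    "remove_artifacts_time",
    "beta_power",
    "detect_spikes",
    "psth",
    "isi_histogram",
]


@dataclass
class SpikeSet:
    """Detected spikes: times, trough-aligned snippets, summary waveform."""

    times: np.ndarray             # s, sorted
    snippets: np.ndarray          # (n_spikes, window) uV
    snippet_offsets: np.ndarray   # sample offsets relative to trough
    fs: float
    threshold_uV: float
    n_dropped: int = 0

    @property
    def mean_waveform(self) -> np.ndarray:
        return self.snippets.mean(axis=0) if self.snippets.size else np.empty(0)

    @property
    def sd_waveform(self) -> np.ndarray:
        return self.snippets.std(axis=0) if self.snippets.size else np.empty(0)


@dataclass
class BetaEnvelope:
    """Smoothed band power series (uV^2) on a downsampled grid."""

    power: np.ndarray
    fs: float
    band: tuple
    smooth_window_s: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.power.size) / self.fs


# --------------------------------------------------------------------------
# referencing
# --------------------------------------------------------------------------

def bipolar_reference(trace_a: EPhysTrace, trace_b: EPhysTrace) -> EPhysTrace:
    """Sample-wise difference a - b; cancels shared (common-mode) components."""
    if trace_a.fs != trace_b.fs:
        raise ValueError("sampling rates differ")
    if trace_a.samples.size != trace_b.samples.size:
        raise ValueError("trace lengths differ")
    return EPhysTrace(samples=trace_a.samples - trace_b.samples, fs=trace_a.fs,
                      channel=f"{trace_a.channel}-{trace_b.channel}",
                      reference=("bipolar", trace_a.channel, trace_b.channel),
                      events=trace_a.events)


# --------------------------------------------------------------------------
# artifact removal
# --------------------------------------------------------------------------

def remove_artifacts_spectral(
    trace: EPhysTrace,
    scan_rate_hz: float = 10.0,
    n_harmonics: Optional[int] = None,
    neighbor_bins: int = 2,
    notch_halfwidth_bins: int = 1,
) -> EPhysTrace:
    """Interpolate the spectrum across the scan frequency and its harmonics.

    The whole-trace discrete spectrum is modified only at bins within
    ``notch_halfwidth_bins`` of each harmonic of ``scan_rate_hz``; replacement
    magnitude is linearly interpolated from ``neighbor_bins`` flanking bins on
    each side and the phase follows a circular-linear interpolation of the
    flanking phasors.  The inverse transform returns a real trace of the
    original length; total power changes only at the interpolated bins.
    """
    x = trace.samples
    n = x.size
    fs = trace.fs
    nyq = fs / 2.0
    max_h = int(np.floor((nyq - 1e-9) / scan_rate_hz))
    if n_harmonics is None:
        n_harmonics = max_h
    elif n_harmonics > max_h:
        warnings.warn(f"n_harmonics clipped from {n_harmonics} to {max_h} "
                      "(harmonics above Nyquist)")
        n_harmonics = max_h

    spec = np.fft.rfft(x)
    df = fs / n
    n_bins = spec.size
    for m in range(1, n_harmonics + 1):
        k0 = int(round(m * scan_rate_hz / df))
        lo = k0 - notch_halfwidth_bins
        hi = k0 + notch_halfwidth_bins
        if lo <= 1 or hi >= n_bins - 1:
            continue
        left = np.arange(max(1, lo - neighbor_bins), lo)
        right = np.arange(hi + 1, min(n_bins, hi + 1 + neighbor_bins))
        anchors = np.concatenate([left, right])
        target = np.arange(lo, hi + 1)
        mags = np.interp(target, anchors, np.abs(spec[anchors]))
        phasors = spec[anchors] / np.maximum(np.abs(spec[anchors]), 1e-300)
        re = np.interp(target, anchors, phasors.real)
        im = np.interp(target, anchors, phasors.imag)
        unit = re + 1j * im
        unit /= np.maximum(np.abs(unit), 1e-12)
        spec[target] = mags * unit
    cleaned = np.fft.irfft(spec, n)
    return replace(trace, samples=cleaned)


def remove_artifacts_time(
    trace: EPhysTrace,
    artifact_times: Sequence[float],
    window_pre: float = 1e-3,
    window_post: float = 2e-3,
    scan_duration: float = 8.5e-3,
    anchor_s: float = 0.5e-3,
    degree: int = 3,
) -> EPhysTrace:
    """Excise each artifact epoch and bridge it by polynomial interpolation.

    Samples in [t - window_pre, t + scan_duration + window_post] around each
    artifact onset are replaced by a degree-``degree`` polynomial fitted to
    ``anchor_s`` of clean samples flanking the gap; every sample outside the
    excision windows is untouched (bit-exact), preserving high-frequency
    content for spike detection.
    """
    times = np.sort(np.asarray(artifact_times, dtype=float))
    x = trace.samples.copy()
    fs = trace.fs
    n = x.size
    n_anchor = max(2, int(round(anchor_s * fs)))
    prev_hi = -1
    for t in times:
        lo = max(0, int(np.floor((t - window_pre) * fs)))
        hi = int(np.ceil((t + scan_duration + window_post) * fs))
        if lo <= prev_hi:
            raise ValueError("overlapping excision windows; shorten the windows "
                             "or thin the artifact times")
        a_lo = np.arange(max(0, lo - n_anchor), lo)
        a_hi = np.arange(min(n, hi + 1), min(n, hi + 1 + n_anchor))
        anchors = np.concatenate([a_lo, a_hi])
        gap = np.arange(lo, min(n, hi + 1))
        if gap.size == 0:
            continue
        if anchors.size <= degree:
            x[gap] = x[anchors].mean() if anchors.size else 0.0
        else:
            poly = np.polynomial.Polynomial.fit(anchors, x[anchors], deg=degree)
            x[gap] = poly(gap)
        prev_hi = hi
    return replace(trace, samples=x)


# --------------------------------------------------------------------------
# beta-band power
# --------------------------------------------------------------------------

def _downsample(x: np.ndarray, fs: float, fs_out: float) -> np.ndarray:
    if fs == fs_out:
        return x.copy()
    # polyphase anti-aliased resampling at a rational rate
    frac_num = int(round(fs_out * 1000))
    frac_den = int(round(fs * 1000))
    g = gcd(frac_num, frac_den)
    return resample_poly(x, frac_num // g, frac_den // g)


def beta_power(
    trace: EPhysTrace,
    band: tuple = (13.0, 28.0),
    smooth_window_s: float = 0.25,
    fs_out: float = 1000.0,
    filter_order: int = 4,
    method: str = "hilbert",
) -> BetaEnvelope:
    """Band-limited power envelope: downsample to ``fs_out``, zero-phase
    bandpass, square, envelope, and smooth with a unit-area Hanning window.

    The default envelope operator is the peak envelope of the squared
    narrowband trace, computed as the squared magnitude of the analytic
    signal (for a pure tone of amplitude A it reads A^2, the peak of the
    squared signal).  ``method='rectify'`` uses mean-square tracking
    (2 x smoothed square), which agrees for narrowband signals.
    """
    if band[0] >= band[1]:
        raise ValueError("band edges inverted")
    if band[1] >= fs_out / 2.0:
        raise ValueError("band must lie below the output Nyquist frequency")
    x = _downsample(trace.samples, trace.fs, fs_out)
    sos = butter(filter_order, list(band), btype="bandpass", fs=fs_out,
                 output="sos")
    xf = sosfiltfilt(sos, x)
    if method == "hilbert":
        env = np.abs(hilbert(xf)) ** 2
    elif method == "rectify":
        env = 2.0 * xf ** 2
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    nwin = max(1, int(round(smooth_window_s * fs_out)))
    w = np.hanning(nwin + 2)[1:-1]
    w /= w.sum()
    power = np.convolve(env, w, mode="same")
    return BetaEnvelope(power=np.clip(power, 0.0, None), fs=fs_out,
                        band=tuple(band), smooth_window_s=smooth_window_s)


# --------------------------------------------------------------------------
# spikes
# --------------------------------------------------------------------------

def detect_spikes(
    trace: EPhysTrace,
    band: tuple = (300.0, 6000.0),
    threshold_scale: float = 4.0,
    lockout_s: float = 1e-3,
    snippet_window: tuple = (-0.5e-3, 1.0e-3),
    exclude_intervals=None,
) -> SpikeSet:
    """Negative-threshold spike detection with a refractory lockout.

    The trace (assumed artifact-cleaned) is zero-phase bandpassed, the noise
    level is estimated robustly as sigma = median(|x|)/0.6745, and troughs
    crossing -``threshold_scale``·sigma are detected with ``lockout_s``
    enforced between accepted events.  Snippets are trough-aligned; events
    whose snippet window falls outside the trace are dropped and counted.
    This is a single-threshold detector, not a spike sorter: overlapping
    units are not separated.

    ``exclude_intervals`` — (start_s, end_s) pairs, typically the excised
    artifact windows — are omitted from the noise estimate (interpolated
    samples carry no high-frequency noise and would bias sigma low) and
    detections inside them are discarded (interpolated samples cannot
    contain spikes).
    """
    fs = trace.fs
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    if band[0] >= hi:
        raise ValueError("detection band lies above Nyquist")
    sos = butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    xf = sosfiltfilt(sos, trace.samples)

    keep = np.ones(xf.size, dtype=bool)
    if exclude_intervals is not None:
        for t0, t1 in exclude_intervals:
            keep[max(0, int(t0 * fs)): max(0, int(np.ceil(t1 * fs)) + 1)] = False
    sigma = np.median(np.abs(xf[keep])) / 0.6745 if keep.any() else 0.0
    thr = -threshold_scale * sigma

    below = xf < thr
    if not below.any() or sigma == 0:
        return SpikeSet(times=np.empty(0), snippets=np.empty((0, 0)),
                        snippet_offsets=np.empty(0, int), fs=fs,
                        threshold_uV=thr)

    crossings = np.flatnonzero(below & ~np.roll(below, 1))
    if below[0]:
        crossings = np.insert(crossings, 0, 0) if crossings.size == 0 or crossings[0] != 0 else crossings
    lock_n = max(1, int(round(lockout_s * fs)))
    troughs = []
    last = -lock_n
    for c in crossings:
        seg_end = min(xf.size, c + lock_n)
        tr_idx = c + int(np.argmin(xf[c:seg_end]))
        if tr_idx - last >= lock_n and keep[tr_idx]:
            troughs.append(tr_idx)
            last = tr_idx

    off_lo = int(round(snippet_window[0] * fs))
    off_hi = int(round(snippet_window[1] * fs))
    offsets = np.arange(off_lo, off_hi + 1)
    snippets, kept, dropped = [], [], 0
    for tr_idx in troughs:
        if tr_idx + off_lo < 0 or tr_idx + off_hi >= xf.size:
            dropped += 1
            continue
        snippets.append(xf[tr_idx + off_lo: tr_idx + off_hi + 1])
        kept.append(tr_idx)
    if dropped:
        warnings.warn(f"dropped {dropped} spike(s) with out-of-bounds snippets")
    return SpikeSet(times=np.asarray(kept) / fs,
                    snippets=np.asarray(snippets) if snippets else np.empty((0, offsets.size)),
                    snippet_offsets=offsets, fs=fs, threshold_uV=thr,
                    n_dropped=dropped)


# --------------------------------------------------------------------------
# spike summaries
# --------------------------------------------------------------------------

def psth(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    window: tuple = (-1.0, 2.0),
    bin_width: float = 0.05,
    condition_labels: Optional[Sequence[str]] = None,
):
    """Trial-averaged firing rate (spikes/s) aligned to events, per condition.

    Returns ``(bin_centers, rates, n_trials)`` with ``rates`` a dict mapping
    condition to the rate array (empty conditions yield an all-NaN row with a
    warning).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    if condition_labels is None:
        condition_labels = ["all"] * event_times.size
    labels = np.asarray(condition_labels)
    rates, n_trials = {}, {}
    for cond in pd.unique(labels):
        ev = event_times[labels == cond]
        n_trials[cond] = ev.size
        if ev.size == 0:
            warnings.warn(f"no trials in condition {cond!r}")
            rates[cond] = np.full(centers.size, np.nan)
            continue
        counts = np.zeros(centers.size)
        for t0 in ev:
            rel = spike_times - t0
            sel = rel[(rel >= window[0]) & (rel < window[1])]
            counts += np.histogram(sel, bins=edges)[0]
        rates[cond] = counts / (ev.size * bin_width)
    return centers, rates, n_trials


def isi_histogram(spike_times: np.ndarray, bin_width_s: float = 1e-3,
                  max_isi_s: float = 0.5):
    """Histogram of interspike intervals (default 1 ms bins).

    Returns ``(bin_edges, counts)``; fewer than 2 spikes yields empty arrays.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size < 2:
        return np.empty(0), np.empty(0, dtype=int)
    isi = np.diff(spike_times)
    edges = np.arange(0.0, max(max_isi_s, isi.max()) + bin_width_s, bin_width_s)
    counts, edges = np.histogram(isi, bins=edges)
    return edges, counts
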