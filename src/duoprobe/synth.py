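"""Synthetic dual-mode (FSCV + electrophysiology) session generator.

Everything downstream of the recording hardware is exercised against sessions
produced here: FSCV color plots with a large capacitive background, slow drift,
dopamine/pH redox signatures and sporadic movement artifacts; wide-band
electrophysiology with 1/f noise, reward-modulated beta bursts, spikes and a
stereotyped scan artifact every repetition interval; and the reward-biased
oculomotor task trial structure (central cue -> 2 s fixation -> value cue ->
4 s hold -> reward).

Every generator takes a single integer seed; independent components draw from
keyed substreams (``default_rng([seed, key])``) so that, e.g., setting the
artifact amplitude to zero leaves the noise and beta components bit-identical.
Ground truth (concentration traces, envelope profiles, spike and artifact
times) is returned alongside every session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ScanWaveform",
    "AnalyteTemplates",
    "GroundTruth",
    "EPhysTrace",
    "EVENT_CODES",
    "generate_waveform",
    "make_templates",
    "simulate_trials",
    "simulate_fscv_session",
    "simulate_ephys_session",
]

# 8-bit task event codes shared by both recording streams.  The trial-start
# code is uniform across trials, mirroring hardware synchronization pulses.
EVENT_CODES = {
    "trial_start": 1,
    "central_cue": 2,
    "value_cue": 3,
    "reward": 4,
}

_RNG_KEYS = {
    "trials": 0,
    "fscv_noise": 1,
    "fscv_drift": 2,
    "fscv_kinetics": 3,
    "fscv_movement": 4,
    "ephys_noise": 5,
    "ephys_beta": 6,
    "ephys_spikes": 7,
    "ephys_artifact": 8,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    """Keyed substream: independent of every other component at the same seed."""
    return np.random.default_rng([int(seed), _RNG_KEYS[component]])


# --------------------------------------------------------------------------
# scan waveform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanWaveform:
    """Triangular FSCV potential ramp with timing metadata.

    The ramp runs v_start -> v_peak -> v_start at ``scan_rate`` and is applied
    once per ``repetition_interval``.  ``potentials`` samples one period on the
    half-open interval [0, scan_duration): the sample that would land exactly
    back on ``v_start`` is the first sample of the next scan.
    """

    v_start: float
    v_peak: float
    scan_rate: float
    repetition_interval: float
    adc_rate: float
    potentials: np.ndarray

    @property
    def scan_duration(self) -> float:
        return 2.0 * (self.v_peak - self.v_start) / self.scan_rate

    @property
    def n_samples(self) -> int:
        return self.potentials.size

    @property
    def frame_rate(self) -> float:
        """Effective color-plot frame rate (scans per second)."""
        return 1.0 / self.repetition_interval

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.potentials))

    def anodic_slice(self) -> slice:
        """Ascending (oxidation) limb, including the apex sample."""
        return slice(0, self.peak_index + 1)

    def cathodic_slice(self) -> slice:
        """Descending (reduction) limb, from the apex sample on."""
        return slice(self.peak_index, self.n_samples)


def generate_waveform(
    v_start: float = -0.4,
    v_peak: float = 1.3,
    scan_rate: float = 400.0,
    repetition_interval: float = 0.1,
    adc_rate: float = 100_000.0,
) -> ScanWaveform:
    """Build the standard triangular FSCV waveform (defaults: -0.4 to 1.3 V at
    400 V/s, applied every 100 ms, digitized at 100 kHz -> 850 samples/scan).
    """
    if v_peak <= v_start:
        raise ValueError("v_peak must exceed v_start")
    if scan_rate <= 0 or adc_rate <= 0:
        raise ValueError("scan_rate and adc_rate must be positive")
    duration = 2.0 * (v_peak - v_start) / scan_rate
    if duration >= repetition_interval:
        raise ValueError(
            f"scan duration {duration * 1e3:.2f} ms does not fit inside the "
            f"repetition interval {repetition_interval * 1e3:.2f} ms"
        )
    n = int(round(duration * adc_rate))
    if n < 4:
        raise ValueError("adc_rate too low to resolve the scan")
    t = np.arange(n) / adc_rate
    t_half = duration / 2.0
    up = v_start + scan_rate * t
    down = v_peak - scan_rate * (t - t_half)
    potentials = np.where(t <= t_half, up, down)
    return ScanWaveform(v_start, v_peak, scan_rate, repetition_interval,
                        adc_rate, potentials)


# --------------------------------------------------------------------------
# analyte templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyteTemplates:
    """Unit-response voltammograms for dopamine, pH and movement artifacts.

    ``templates`` is (n_analytes, samples-per-scan) with unit peak magnitude;
    ``gains`` converts concentration units to current (nA): nA/nM for
    dopamine, nA per pH unit, nA per (dimensionless) movement unit.
    """

    waveform: ScanWaveform
    names: tuple
    templates: np.ndarray
    gains: dict
    peak_potentials: dict

    def response(self, name: str) -> np.ndarray:
        """Current response (nA) per unit concentration of one analyte."""
        i = self.names.index(name)
        return self.gains[name] * self.templates[i]


def _bump(potentials: np.ndarray, limb: slice, center: float, width: float) -> np.ndarray:
    """Gaussian bump in the potential domain restricted to one sweep limb."""
    out = np.zeros_like(potentials)
    v = potentials[limb]
    out[limb] = np.exp(-0.5 * ((v - center) / width) ** 2)
    return out


def make_templates(
    waveform: ScanWaveform,
    da_oxidation_v: float = 0.6,
    da_reduction_v: float = -0.2,
    da_ox_width_v: float = 0.15,
    da_red_width_v: float = 0.18,
    da_red_rel_amp: float = 0.8,
    gains: Optional[dict] = None,
) -> AnalyteTemplates:
    """Construct dopamine, pH and movement unit voltammograms.

    The dopamine template is a positive (anodic) bump at the oxidation
    potential on the ascending limb and a negative (cathodic) bump at the
    reduction potential on the descending limb — the classic two-lobed
    background-subtracted dopamine CV.  The movement template is a broadband
    shape explicitly decorrelated (Pearson r = 0) from the dopamine template.
    """
    for v, what in ((da_oxidation_v, "oxidation"), (da_reduction_v, "reduction")):
        if not (waveform.v_start <= v <= waveform.v_peak):
            raise ValueError(f"dopamine {what} potential {v} V outside scan range "
                             f"[{waveform.v_start}, {waveform.v_peak}] V")
    if gains is None:
        gains = {"da": 0.01, "ph": 50.0, "movement": 10.0}

    pot = waveform.potentials
    da = (_bump(pot, waveform.anodic_slice(), da_oxidation_v, da_ox_width_v)
          - da_red_rel_amp * _bump(pot, waveform.cathodic_slice(),
                                   da_reduction_v, da_red_width_v))
    if np.max(np.abs(da)) > 0:
        da = da / np.max(np.abs(da))

    # pH: broad, shallow features on both limbs, distinct from dopamine.
    ph = (_bump(pot, waveform.anodic_slice(), 0.2, 0.45)
          - 0.6 * _bump(pot, waveform.cathodic_slice(), 0.9, 0.40))
    ph = ph / np.max(np.abs(ph))

    # Movement/charging artifact: slow broadband deflection across the whole
    # scan, Gram-Schmidt decorrelated from both the dopamine template (so the
    # correlation veto has a well-defined target, |r| < 0.3 guaranteed) and
    # the capacitive background shape (so ordinary drift is not mistaken for
    # a movement artifact).
    n = waveform.n_samples
    base = np.cos(np.pi * np.arange(n) / n) + 0.4 * np.sin(3 * np.pi * np.arange(n) / n)
    base_c = base - base.mean()
    bg = background_voltammogram(waveform)
    span = np.column_stack([da - da.mean(), bg - bg.mean()])
    coeffs, *_ = np.linalg.lstsq(span, base_c, rcond=None)
    base_c = base_c - span @ coeffs
    movement = base_c / np.max(np.abs(base_c))

    templates = np.vstack([da, ph, movement])
    return AnalyteTemplates(
        waveform=waveform,
        names=("da", "ph", "movement"),
        templates=templates,
        gains=dict(gains),
        peak_potentials={"da_ox": da_oxidation_v, "da_red": da_reduction_v},
    )


# --------------------------------------------------------------------------
# trial structure
# --------------------------------------------------------------------------

def simulate_trials(
    task: str = "shape",
    n_trials: int = 100,
    *,
    fixation_s: float = 2.0,
    hold_s: float = 4.0,
    start_lead_s: float = 0.5,
    iti_s: float = 3.0,
    iti_jitter_s: float = 1.0,
    forced_fraction: float = 0.25,
    p_success: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the trial table of the reward-biased saccade tasks.

    ``direction``: a single value cue per trial (all trials effectively
    forced/instructed).  ``shape``: two-alternative choice with an exact
    ``forced_fraction`` of interleaved forced-choice trials (default 25%).
    Timing per trial: trial start, central cue, 2 s fixation, value cue,
    4 s hold, reward.
    """
    if task not in ("direction", "shape"):
        raise ValueError(f"unknown task {task!r}; expected 'direction' or 'shape'")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed, "trials")

    if task == "direction":
        trial_type = np.array(["forced"] * n_trials)
    else:
        n_forced = int(round(forced_fraction * n_trials))
        trial_type = np.array(["choice"] * n_trials)
        forced_idx = rng.choice(n_trials, size=n_forced, replace=False)
        trial_type[forced_idx] = "forced"

    reward = rng.choice(["large", "small"], size=n_trials)
    laterality = rng.choice(["contra", "ipsi"], size=n_trials)
    success = rng.random(n_trials) < p_success

    itis = iti_s + iti_jitter_s * rng.random(n_trials)
    trial_len = start_lead_s + fixation_s + hold_s
    t_start = np.empty(n_trials)
    t0 = 1.0
    for i in range(n_trials):
        t_start[i] = t0
        t0 += trial_len + itis[i]
    t_central = t_start + start_lead_s
    t_value = t_central + fixation_s
    t_reward = t_value + hold_s

    return pd.DataFrame({
        "trial": np.arange(n_trials),
        "t_start": t_start,
        "t_central_cue": t_central,
        "t_value_cue": t_value,
        "t_reward": t_reward,
        "reward": reward,
        "laterality": laterality,
        "trial_type": trial_type,
        "success": success,
    })


def events_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Expand a trial table into a timestamped 8-bit event-code stream."""
    rows = []
    for _, tr in trials.iterrows():
        for label, col in (("trial_start", "t_start"),
                           ("central_cue", "t_central_cue"),
                           ("value_cue", "t_value_cue"),
                           ("reward", "t_reward")):
            rows.append((tr[col], EVENT_CODES[label], label, int(tr["trial"])))
    ev = pd.DataFrame(rows, columns=["timestamp_s", "code", "label", "trial"])
    return ev.sort_values("timestamp_s", ignore_index=True)


# --------------------------------------------------------------------------
# ground truth container
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Known truth stored alongside every simulated session."""

    seed: int
    params: dict = field(default_factory=dict)
    # FSCV side (10 Hz frame grid)
    frame_times: Optional[np.ndarray] = None
    da_nM: Optional[np.ndarray] = None
    ph: Optional[np.ndarray] = None
    movement_frames: Optional[np.ndarray] = None
    # EPhys side
    beta_env_times: Optional[np.ndarray] = None
    beta_env: Optional[np.ndarray] = None          # true power envelope (uV^2)
    erd_profile: Optional[np.ndarray] = None       # multiplicative amplitude factor
    spike_times: Optional[np.ndarray] = None
    artifact_times: Optional[np.ndarray] = None


# --------------------------------------------------------------------------
# FSCV session
# --------------------------------------------------------------------------

def _gamma_kernel(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma-shaped transient, normalized to unit peak, zero for t < 0."""
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = tp ** (shape - 1.0) * np.exp(-tp)
    peak = (shape - 1.0) ** (shape - 1.0) * np.exp(-(shape - 1.0)) if shape > 1 else 1.0
    return out / peak


def background_voltammogram(waveform: ScanWaveform) -> np.ndarray:
    """Capacitive-like stable background CV, unit peak magnitude.

    Dominated by the charging current ~ C dV/dt (sign of the sweep slope),
    smoothed at the apex, with a mild potential-dependent tilt.
    """
    pot = waveform.potentials
    slope_sign = np.gradient(pot) * waveform.adc_rate / waveform.scan_rate
    sm = int(max(3, waveform.n_samples // 40))
    kern = np.hanning(sm)
    kern /= kern.sum()
    cap = np.convolve(slope_sign, kern, mode="same")
    shape = cap * (1.0 + 0.15 * (pot - pot.mean()))
    return shape / np.max(np.abs(shape))


def simulate_fscv_session(
    trials: pd.DataFrame,
    templates: AnalyteTemplates,
    *,
    amp_large_nM: float = 100.0,
    amp_small_nM: float = 50.0,
    amp_jitter: float = 0.2,
    kernel_shape: float = 2.0,
    kernel_scale_s: float = 0.7,
    ph_per_reward: float = -0.02,
    ph_kernel_shape: float = 3.0,
    ph_kernel_scale_s: float = 1.5,
    background_nA: float = 400.0,
    drift_linear_nA_s: float = 0.02,
    drift_step_nA: float = 0.05,
    noise_nA: float = 0.5,
    movement_prob: float = 0.01,
    movement_amp: float = 2.0,
    movement_amp_sd: float = 0.5,
    tail_s: float = 5.0,
    sensitivity_scale: float = 1.0,
    seed: int = 0,
):
    """Render a color plot for one session plus its ground truth.

    Each frame is  background + drift(t) + sum_a gain_a * c_a(t) * template_a
    + white noise.  Dopamine transients are gamma-shaped, locked to the value
    cue, with amplitude set by reward size (large > small) and multiplicative
    jitter; pH drifts slowly after reward; movement-artifact frames occur as a
    Bernoulli process.  ``sensitivity_scale`` scales the electrode's dopamine
    gain relative to the calibration bank (for sensitivity-transfer tests).

    Returns ``(ColorPlot, GroundTruth)``.
    """
    from .fscv import ColorPlot  # deferred: fscv imports ScanWaveform from here

    wf = templates.waveform
    duration = float(trials["t_reward"].max()) + tail_s
    n_frames = int(np.ceil(duration * wf.frame_rate))
    frame_times = np.arange(n_frames) / wf.frame_rate
    n_samp = wf.n_samples

    rng_kin = _rng(seed, "fscv_kinetics")
    rng_drift = _rng(seed, "fscv_drift")
    rng_noise = _rng(seed, "fscv_noise")
    rng_move = _rng(seed, "fscv_movement")

    # true concentration traces on the frame grid
    da = np.zeros(n_frames)
    ph = np.zeros(n_frames)
    for _, tr in trials.iterrows():
        amp = amp_large_nM if tr["reward"] == "large" else amp_small_nM
        amp = amp * max(0.0, 1.0 + amp_jitter * rng_kin.standard_normal())
        da += amp * _gamma_kernel(frame_times - tr["t_value_cue"],
                                  kernel_shape, kernel_scale_s)
        ph += ph_per_reward * _gamma_kernel(frame_times - tr["t_reward"],
                                            ph_kernel_shape, ph_kernel_scale_s)

    move_mask = rng_move.random(n_frames) < movement_prob
    move_amp = np.zeros(n_frames)
    move_amp[move_mask] = np.abs(
        movement_amp + movement_amp_sd * rng_move.standard_normal(move_mask.sum()))

    # drift: linear trend + random walk, multiplying a background-like shape
    drift = (drift_linear_nA_s * frame_times
             + np.cumsum(drift_step_nA * rng_drift.standard_normal(n_frames)))

    bg_shape = background_voltammogram(wf)
    currents = np.outer(np.ones(n_frames), background_nA * bg_shape)
    currents += np.outer(drift, bg_shape)
    currents += np.outer(da, sensitivity_scale * templates.response("da"))
    currents += np.outer(ph, templates.response("ph"))
    currents += np.outer(move_amp, templates.response("movement"))
    if noise_nA > 0:
        currents += noise_nA * rng_noise.standard_normal((n_frames, n_samp))

    events = events_from_trials(trials)
    cp = ColorPlot(currents=currents, frame_times=frame_times,
                   waveform=wf, events=events)
    truth = GroundTruth(
        seed=seed,
        params={"amp_large_nM": amp_large_nM, "amp_small_nM": amp_small_nM,
                "noise_nA": noise_nA, "background_nA": background_nA,
                "movement_prob": movement_prob,
                "sensitivity_scale": sensitivity_scale},
        frame_times=frame_times, da_nM=da, ph=ph,
        movement_frames=np.flatnonzero(move_mask),
    )
    return cp, truth


# --------------------------------------------------------------------------
# EPhys session
# --------------------------------------------------------------------------

@dataclass
class EPhysTrace:
    """Wide-band extracellular voltage trace with event codes."""

    samples: np.ndarray          # uV
    fs: float                    # samples/s
    channel: str = "ch0"
    reference: tuple = ("ground",)
    events: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def _pink_noise(n: int, fs: float, sigma: float, knee_hz: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with 1/f power spectrum above ``knee_hz``, total SD sigma."""
    white = rng.standard_normal(n)
    if sigma == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, knee_hz))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return sigma * x / x.std()


def _erd_bump(t: np.ndarray, onset: float, dur: float) -> np.ndarray:
    """Raised-cosine suppression profile on [onset, onset+dur] after an event."""
    out = np.zeros_like(t)
    inside = (t >= onset) & (t <= onset + dur)
    out[inside] = 0.5 * (1.0 - np.cos(2 * np.pi * (t[inside] - onset) / dur))
    return out


def spike_template(fs: float, trough_uV: float = -1.0) -> np.ndarray:
    """Biphasic extracellular spike waveform (~1.2 ms), unit trough by default."""
    t = np.arange(int(round(1.2e-3 * fs))) / fs
    w = (-np.exp(-0.5 * ((t - 0.25e-3) / 0.12e-3) ** 2)
         + 0.35 * np.exp(-0.5 * ((t - 0.65e-3) / 0.22e-3) ** 2))
    return trough_uV * w / np.abs(w.min())


def artifact_template(fs: float, duration_s: float, amp_uV: float,
                      freq_hz: float = 900.0, tau_s: float = 1.5e-3) -> np.ndarray:
    """Stereotyped damped-oscillation scan artifact of the given duration."""
    t = np.arange(int(round(duration_s * fs))) / fs
    return amp_uV * np.exp(-t / tau_s) * np.sin(2 * np.pi * freq_hz * t)


def simulate_ephys_session(
    trials: pd.DataFrame,
    *,
    fs: float = 30_000.0,
    noise_pink_uV: float = 25.0,
    noise_knee_hz: float = 1.0,
    noise_white_uV: float = 4.0,
    beta_tonic_uV: float = 8.0,
    beta_burst_rate_hz: float = 2.0,
    beta_burst_uV: float = 12.0,
    beta_burst_cycles: float = 3.0,
    beta_center_hz: float = 20.0,
    beta_center_jitter_hz: float = 4.0,
    erd_depth_large: float = 0.5,
    erd_depth_small: float = 0.25,
    erd_ipsi_factor: float = 0.5,
    erd_onset_s: float = 0.2,
    erd_duration_s: float = 1.4,
    spike_rate_hz: float = 10.0,
    spike_reward_gain_large: float = 2.0,
    spike_reward_gain_small: float = 1.4,
    spike_mod_duration_s: float = 0.6,
    spike_refractory_s: float = 2e-3,
    spike_snr: float = 10.0,
    artifact_amp_uV: float = 250.0,
    artifact_duration_s: float = 8.5e-3,
    scan_interval_s: float = 0.1,
    tail_s: float = 2.0,
    channel: str = "ch0",
    seed: int = 0,
):
    """Render one wide-band electrophysiology channel plus ground truth.

    trace = 1/f noise + beta oscillation (tonic + Poisson bursts, 13-28 Hz)
    with cue-locked event-related desynchronization scaled by reward size and
    laterality + refractory inhomogeneous-Poisson spike train (fixed biphasic
    waveform, amplitude = ``spike_snr`` x the 300-6000 Hz noise SD) + a
    stereotyped damped-oscillation artifact at every FSCV scan onset.

    Returns ``(EPhysTrace, GroundTruth)``.
    """
    if artifact_duration_s >= scan_interval_s:
        raise ValueError("artifact duration must be shorter than the scan interval")
    nyq = fs / 2.0
    if beta_center_hz + beta_center_jitter_hz >= nyq:
        raise ValueError("beta band exceeds Nyquist at this sampling rate")

    duration = float(trials["t_reward"].max()) + tail_s
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs

    rng_noise = _rng(seed, "ephys_noise")
    rng_beta = _rng(seed, "ephys_beta")
    rng_spk = _rng(seed, "ephys_spikes")

    noise = _pink_noise(n, fs, noise_pink_uV, noise_knee_hz, rng_noise)
    if noise_white_uV > 0:
        noise += noise_white_uV * rng_noise.standard_normal(n)

    # --- beta component: tonic oscillation + Gaussian-windowed bursts -------
    amp_env = np.full(n, float(beta_tonic_uV))
    f0 = beta_center_hz + beta_center_jitter_hz * (2 * rng_beta.random() - 1)
    f0 = float(np.clip(f0, 13.0, 28.0))
    phase0 = 2 * np.pi * rng_beta.random()
    n_bursts = rng_beta.poisson(beta_burst_rate_hz * duration)
    burst_t = np.sort(rng_beta.uniform(0, duration, n_bursts))
    sigma_b = beta_burst_cycles / f0 / 2.355      # FWHM = beta_burst_cycles periods
    for tb in burst_t:
        lo = max(0, int((tb - 4 * sigma_b) * fs))
        hi = min(n, int((tb + 4 * sigma_b) * fs))
        amp_env[lo:hi] += beta_burst_uV * np.exp(
            -0.5 * ((t[lo:hi] - tb) / sigma_b) ** 2)

    # reward/laterality-scaled desynchronization after the value cue
    erd = np.zeros(n)
    for _, tr in trials.iterrows():
        depth = erd_depth_large if tr["reward"] == "large" else erd_depth_small
        if tr["laterality"] == "ipsi":
            depth *= erd_ipsi_factor
        lo = max(0, int((tr["t_value_cue"] + erd_onset_s) * fs))
        hi = min(n, int((tr["t_value_cue"] + erd_onset_s + erd_duration_s) * fs) + 1)
        if lo < hi:
            erd[lo:hi] += depth * _erd_bump(t[lo:hi] - tr["t_value_cue"],
                                            erd_onset_s, erd_duration_s)
    modulation = np.clip(1.0 - erd, 0.0, 1.0)
    amp_env *= modulation
    beta = amp_env * np.cos(2 * np.pi * f0 * t + phase0)

    # --- spikes: inhomogeneous Poisson with refractory lockout --------------
    rate = np.full(n, float(spike_rate_hz))
    if spike_rate_hz > 0:
        for _, tr in trials.iterrows():
            gain = (spike_reward_gain_large if tr["reward"] == "large"
                    else spike_reward_gain_small)
            lo = int(tr["t_reward"] * fs)
            hi = min(n, int((tr["t_reward"] + spike_mod_duration_s) * fs))
            if lo < n:
                rate[lo:hi] *= gain
        rate_max = rate.max()
        n_cand = rng_spk.poisson(rate_max * duration)
        cand = np.sort(rng_spk.uniform(0, duration, n_cand))
        accept = rng_spk.random(cand.size) < rate[
            np.minimum((cand * fs).astype(int), n - 1)] / rate_max
        cand = cand[accept]
        spike_times = []
        last = -np.inf
        for ts in cand:
            if ts - last >= spike_refractory_s:
                spike_times.append(ts)
                last = ts
        spike_times = np.asarray(spike_times)
    else:
        spike_times = np.empty(0)

    spikes = np.zeros(n)
    if spike_times.size:
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, [300.0, min(6000.0, 0.95 * nyq)], btype="bandpass",
                     fs=fs, output="sos")
        sigma_band = np.median(np.abs(sosfiltfilt(sos, noise))) / 0.6745
        # SNR is defined in the detection band: the bandpassed waveform's
        # trough is spike_snr x the bandpassed noise SD, so compensate for
        # the filter's attenuation of the narrow trough.
        unit = spike_template(fs, trough_uV=-1.0)
        padded = np.zeros(unit.size + 2 * int(0.05 * fs))
        padded[padded.size // 2: padded.size // 2 + unit.size] = unit
        attenuation = np.abs(sosfiltfilt(sos, padded).min())
        tmpl = spike_template(fs, trough_uV=-spike_snr * sigma_band / attenuation)
        trough_off = int(np.argmin(tmpl))    # truth times mark the trough
        for ts in spike_times:
            i0 = int(round(ts * fs)) - trough_off
            s0 = max(0, -i0)
            s1 = min(tmpl.size, n - i0)
            if s1 > s0:
                spikes[i0 + s0: i0 + s1] += tmpl[s0:s1]

    # --- stereotyped FSCV scan artifact every scan interval -----------------
    artifact_times = np.arange(0.0, duration, scan_interval_s)
    art = np.zeros(n)
    if artifact_amp_uV != 0:
        tmpl = artifact_template(fs, artifact_duration_s, artifact_amp_uV)
        for ta in artifact_times:
            i0 = int(round(ta * fs))
            seg = tmpl[: n - i0]
            art[i0:i0 + seg.size] += seg

    trace = EPhysTrace(samples=noise + beta + spikes + art, fs=fs,
                       channel=channel, reference=("ground",),
                       events=events_from_trials(trials))

    # ground truth: true power envelope of the beta component on a 1 kHz grid
    fs_env = 1000.0
    idx = np.minimum((np.arange(int(duration * fs_env)) / fs_env * fs).astype(int),
                     n - 1)
    truth = GroundTruth(
        seed=seed,
        params={"fs": fs, "f0": f0, "erd_depth_large": erd_depth_large,
                "erd_depth_small": erd_depth_small,
                "spike_rate_hz": spike_rate_hz, "spike_snr": spike_snr,
                "artifact_amp_uV": artifact_amp_uV},
        beta_env_times=np.arange(idx.size) / fs_env,
        beta_env=amp_env[idx] ** 2,
        erd_profile=modulation[idx],
        spike_times=spike_times,
        artifact_times=artifact_times,
    )
    return trace, truth
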