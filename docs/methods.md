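# Methods

This note documents the models implemented in `duoprobe`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## 1. Scan waveform and color plots

FSCV applies a triangular potential ramp from −0.4 V to +1.3 V and back at
400 V/s (scan duration 2·1.7/400 = 8.5 ms), repeated every 100 ms, giving an
effective 10 Hz frame rate. At the default 100 kHz digitization a scan is
850 samples. The ramp is sampled on the half-open interval [0, T): the
sample that would land exactly back on −0.4 V is the first sample of the
next scan, so the last stored sample sits one ADC voltage step (4 mV) above
the start potential. Consequence for tests and consumers: assert endpoint
equality only to within one ADC step.

A session is a color plot — a frames × samples current matrix (nA) on the
10 Hz grid — with the timestamped 8-bit task event stream attached.

## 2. Synthetic sessions: what is emulated

Each FSCV frame is

    background · shape_cap  +  drift(t) · shape_cap
      + Δ[DA](t)·g_DA·T_DA + ΔpH(t)·g_pH·T_pH + a_move(t)·g_mv·T_mv
      + white noise (σ = 0.5 nA/sample)

- `shape_cap` is a capacitive-like background CV (sign of dV/dt, smoothed,
  mildly potential-tilted), scaled to 400 nA. Real background currents are
  hundreds of nA and dwarf faradaic signals, which is why everything
  downstream is differential.
- Drift is a linear trend (0.02 nA/s) plus a frame-wise random walk
  (0.05 nA/√frame) multiplying the background shape — the slow instability
  that makes background subtraction mandatory beyond ~30–60 s.
- The dopamine template is a positive Gaussian bump (σ = 0.15 V) at +0.6 V
  on the anodic sweep and a −0.8-relative-amplitude bump (σ = 0.18 V) at
  −0.2 V on the cathodic sweep; gain 0.01 nA/nM. The pH template is a
  broader two-lobed shape; gain 50 nA per pH unit. The movement template is
  a slow broadband deflection explicitly decorrelated (least-squares
  projection, r = 0) from both the dopamine template and the background
  shape — without the latter, ordinary drift would masquerade as movement
  and trip the correlation veto.
- Value-cue-locked dopamine transients use a gamma kernel (shape 2, scale
  0.7 s, unit peak) with amplitudes 100 nM (large reward) vs 50 nM (small),
  ±20% multiplicative jitter — tens-of-nM cue-evoked transients at striatal
  scale. pH shifts −0.02/reward with a slower kernel. Movement frames are
  Bernoulli (p = 0.01/frame) with amplitude ~2 gain units.

Each EPhys trace (µV) is 1/f noise (25 µV SD, knee 1 Hz) + white noise
(4 µV) + a β oscillation (tonic 8 µV plus Poisson bursts at 2/s, 12 µV,
~3 cycles, carrier 20 ± 4 Hz) + a refractory (2 ms) inhomogeneous-Poisson
spike train with a fixed biphasic ~1.2 ms waveform + a stereotyped damped
oscillation (900 Hz, τ = 1.5 ms, 8.5 ms long, 250 µV) at every scan onset.
Event-related desynchronization multiplies the β amplitude by
1 − depth·bump(t) over 0.2–1.6 s after the value cue, depth 0.5 (large) vs
0.25 (small), halved for ipsilateral cues. Reward responses multiply the
spike rate (baseline 10 Hz) by 2.0 / 1.4 for 0.6 s after reward.

Spike SNR is defined where detection happens: the inserted waveform is
scaled so that its trough *after* the 300–6000 Hz detection bandpass equals
`spike_snr` × the bandpassed noise SD (the narrow trough is otherwise
attenuated roughly twofold by the filter, which would make nominal SNRs
uninterpretable).

All randomness derives from one session seed via keyed substreams
(`default_rng([seed, component])`), so changing one component's amplitude
(e.g. disabling the artifact) leaves every other component bit-identical —
this is what makes clean-render oracles possible. Ground truth (Δ[DA] and
pH series, movement frames, true β power envelope and ERD profile at 1 kHz,
spike and artifact times) is returned with every session.

**What is not emulated:** adsorption electrochemistry and electron-transfer
kinetics; electrode fouling and tissue encapsulation; pH-buffer chemistry;
saccade kinematics; spike-waveform drift and multi-unit overlap;
cross-sensor transfer error of calibration standards (flagged, not
modeled). Passing tests therefore demonstrate correctness of the analysis
chain under the stated statistical model of the data, not robustness to
every failure mode of real recordings.

## 3. Chemometrics

**Background subtraction** subtracts the frame nearest at-or-before the
reference event (ties toward earlier); all Δ quantities are relative to that
frame, and each trial's epoch is referenced at its own value-cue frame.

**PCR.** Standards (differential CVs) are decomposed by SVD; retained scores
are mapped to known concentrations by least squares. The map is linear
through the origin by default — inputs and concentrations are both
differential, and this preserves exact prediction linearity; mean-centering
of both blocks is available (`center=True`) and recorded in the model.
Rank selection: the default `noise-floor` rule keeps eigenvalues above 5×
the median eigenvalue (the scree's noise plateau). The conventional
cumulative-variance rule is available but retains noise components when
standards are realistically noisy (with 90 noisy standards it kept 27
components and nulled essentially every frame); the fixed-k rule serves
exact-recovery tests.

**Q gating.** Q is the squared residual outside the retained subspace.
Q_α is the Jackson–Mudholkar closed form over the discarded eigenvalues:
θᵢ = Σλʲⁱ, h₀ = 1 − 2θ₁θ₃/(3θ₂²),
Q_α = θ₁[c_α h₀ √(2θ₂)/θ₁ + 1 + θ₂h₀(h₀−1)/θ₁²]^{1/h₀}; α defaults to 0.05.
Calibration holds when test-frame noise matches the training residual model
(verified by simulation in the residual eigenspace); for full-space white
noise with few standards the threshold is conservative (over-nulling never
occurs, under-nulling of structured outliers is still caught because their
residuals are large). Degenerate case: no (or all-zero) discarded
eigenvalues → Q_α = 0 (with a warning in the all-zero case).

**Movement veto.** Pearson correlation of each frame against each movement
standard (computed on the raw background-subtracted CV); max r > 0.8 nulls
the frame. When both vetoes fire, the recorded reason is `movement`.
Nulled frames become NaN and are excluded — never zeroed — by all averaging.

**Calibration bank.** The synthetic in-vitro bank spans 0–1000 nM dopamine ×
±0.2 pH × ±5 nA drift (a nuisance column so residual drift is absorbed by
the regression instead of inflating Q), with per-standard noise 0.71 nA =
√2 × the 0.5 nA scan noise, because background subtraction doubles noise
variance and Q_α must reflect the frames it gates. Standard levels are
assumptions (bench banks are measured on separate sensors); they are chosen
large against scan noise so the regression map is estimated without
attenuation — at 0–150 nM levels the noise-limited loadings attenuated
recovered concentrations by ~10%.

**Sensitivity transfer.** s = dopamine oxidation current / background
current; the recorded factor is s_vivo/s_cal and concentrations are divided
by it, so an electrode at 0.8× bench sensitivity recovers truth after
normalization.

## 4. Electrophysiology

**Spectral interpolation** (LFP route): whole-trace rFFT; at each harmonic
of 10 Hz up to Nyquist, the bins within ±1 bin of the harmonic are replaced
by linear interpolation of magnitude from 2 flanking bins per side, with
circular-linear phase interpolation (unit phasors interpolated and
renormalized); total power changes only at the replaced bins. All widths
are configurable. The artifact line is on-bin only when the analyzed length
is a whole number of scan periods; assessments of residual harmonic power
should use period-aligned segments (Welch with boxcar segments of whole
periods), since single-bin periodogram values of stochastic signals
fluctuate severalfold around their mean.

**Time-domain interpolation** (spike route): samples in
[t − 1 ms, t + 8.5 ms + 2 ms] around each artifact onset are replaced by a
cubic polynomial least-squares fitted to 0.5 ms of clean samples on each
side; everything outside is untouched bit-exactly. Spikes inside excised
windows (~11.5% of time at defaults) are unrecoverable by construction, so
detection is scored against spikes whose trough lies outside them, and the
excised intervals are excluded from the detector's noise estimate —
interpolated samples carry no high-frequency noise and would bias the
median-based σ low by ~15%, silently lowering the effective threshold.

**β power**: polyphase resampling to 1 kHz, zero-phase 4th-order Butterworth
13–28 Hz (forward–backward), squaring, envelope, unit-area Hanning smoothing
over 0.25 s. The envelope operator is the peak envelope of the squared
narrowband trace, computed as the squared magnitude of the analytic signal
of the bandpassed trace — for a unit tone it reads 1.0 µV² (the peak of the
squared signal), which makes the output directly interpretable as amplitude²
in µV². A mean-square-tracking alternative (`method='rectify'`, 2× the
smoothed square) agrees for narrowband signals. Output is raw power; no
dB/z-score normalization is applied (a baseline normalization is a
one-liner on the epoch matrices).

**Spike detection** is a single negative threshold at −4σ
(σ = median(|x|)/0.6745 on the 300–6000 Hz bandpassed trace) with trough
alignment and a 1 ms lockout — a documented stand-in for full spike
sorting; it does not separate overlapping units. On pure Gaussian noise the
false-positive rate follows Rice's crossing formula ν ≈ ν₀e^(−u²/2) ≈ 1/s at
u = 4 for this band — negligible against tens-of-Hz unit rates but not
against sparse units; raise `threshold_scale` for those.

PSTHs are per-condition trial-averaged rates (spikes/s); ISI histograms use
1 ms bins; fewer than two spikes yield an empty histogram.

## 5. Alignment and averaging

Streams are synchronized by least squares on matched occurrences of the
uniform trial-start code (k-th in A ↔ k-th in B); the map records slope,
offset, residual RMS (warning above 1 ms) and is exactly invertible.
Trial averages are computed on each modality's native grid (10 Hz frames for
chemistry, 1 kHz for β power; no cross-interpolation). SE = SD/√n with
ddof = 1, pointwise, where n counts non-null trials at that time point;
a single usable trial reports SE = 0 and is flagged. Partial epochs are
dropped and counted. The default trial filter for shape-task figures is
successful forced-choice trials only (configurable).

## 6. Mechanics

K = Σᵢ Eᵢπ(D⁴out,i − D⁴in,i)/64 over validated concentric layers;
P_cr = π²K/(KₑL)² with Kₑ ∈ {fixed-free: 2, pinned-pinned: 1,
fixed-pinned: 0.699, fixed-fixed: 0.5} (fixed-free default, the insertion
configuration); δ = FL³/3K. Moduli table (overridable): fused silica
72 GPa, carbon fiber 234 GPa (high-modulus PAN, 34-700 class), parylene-C
2.8 GPa, tungsten 3.5 × 10¹¹ N/m². The design comparison is made against
printed inequality bounds, not equalities, because the source bounds do not
pin down which modulus/diameter pair produced them.

## 7. Problem sizes used by the test suite

Chosen as the package's study conditions: chemometric recovery and reward
effects use 16-trial sessions (the Δ[DA] effect at 100 vs 50 nM is resolved
with |t| > 2 per session); the β-ERD sign-recovery property uses 100
sessions of 96 trials rendered at 1 kHz without spikes — β power is bursty,
and short sessions under-power the comparison (statistics, not method:
at 16 trials the sign is recovered in ~80/100 sessions, at 96 trials in
≥95/100), while 96 trials matches the task's block structure of tens to
hundreds of trials. Spike-detection scoring uses 16-trial sessions at
20 kHz, SNR 8–10, rate 20 Hz. Q-calibration uses 5000 matched-noise frames.

## 8. Known limitations

- Q gating assumes the training bank's noise level matches the session's
  differential noise; a mismatched bank shifts the null rate (conservative
  if the bank is noisier, aggressive if cleaner).
- The movement veto is only as good as the movement standards; artifacts
  orthogonal to the bank pass the correlation test and must be caught by Q.
- Whole-session background subtraction accumulates drift; frames far from
  the reference are legitimately nulled. Use per-trial referencing (the
  default epoch path) for event-locked questions.
- The spike detector is not a sorter; counts conflate units.
- Session files quantize EPhys to int16 at a recorded gain (µV/LSB); the
  stored representation is the session of record (round-trips are
  bit-stable; the quantization error bound is half an LSB).
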