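#!/usr/bin/env python
"""Generate the reference synthetic session used by the downstream analyses.

Simulates one 48-trial shape-task session — FSCV color plot at 10 Hz with
dopamine/pH/movement structure, and a concurrent 20 kHz electrophysiology
channel with beta bursts, reward-modulated spiking and the 10 Hz scan
artifact — and writes it with ground truth to results/session/.
"""

import numpy as np

from duoprobe import session_io, synth

SEED = 7
OUT = "results/session"


def main():
    trials = synth.simulate_trials("shape", 48, seed=SEED)
    wf = synth.generate_waveform()
    templates = synth.make_templates(wf)
    cp, truth_f = synth.simulate_fscv_session(trials, templates, seed=SEED)
    trace, truth_e = synth.simulate_ephys_session(trials, fs=20_000.0,
                                                  seed=SEED)
    truth = truth_f
    for field in ("beta_env_times", "beta_env", "erd_profile", "spike_times",
                  "artifact_times"):
        setattr(truth, field, getattr(truth_e, field))
    bundle = session_io.SessionBundle(
        colorplot=cp, ephys={trace.channel: trace}, events=cp.events,
        ground_truth=truth, config={"task": "shape", "n_trials": 48,
                                    "fs": 20_000.0}, seed=SEED, checksums={})
    session_io.write_session(bundle, OUT)
    trials.to_csv(f"{OUT}/trials.tsv", sep="\t", index=False)

    print(f"wrote session to {OUT}/")
    print(f"  {cp.n_frames} FSCV frames x {cp.currents.shape[1]} samples "
          f"({cp.n_frames / 10:.0f} s at 10 Hz)")
    print(f"  {trace.samples.size} EPhys samples at {trace.fs:.0f} Hz")
    print(f"  {truth.spike_times.size} true spikes, "
          f"{truth.artifact_times.size} scan artifacts")
    print(f"  {len(trials)} trials "
          f"({(trials.trial_type == 'forced').sum()} forced), "
          f"true dDA peak {truth.da_nM.max():.0f} nM")


if __name__ == "__main__":
    main()
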