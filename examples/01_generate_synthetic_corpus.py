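"""Generate a small synthetic force-plate corpus with known ground truth.

Each trial is a level-held trigger sequence fixation (128) -> stimulus
(1/2/4/8) -> response (32/64) -> inter-trial interval (0); channels are
slow sway plus white noise.  The printed schedule is the ground truth the
rest of the pipeline is checked against.
"""

from fpevent import SyntheticConfig, generate_corpus

config = SyntheticConfig(n_blocks=2, n_trials_per_block=10)
recordings, schedule = generate_corpus(config, seed=1)

print(f"{len(recordings)} blocks, {len(schedule)} trials total")
rec = recordings[0]
print(f"block 1: {rec.n_samples} samples at {rec.sampling_rate:g} Hz, "
      f"channels {list(rec.channels)}")
print("\nFirst three scheduled trials (onsets are sample indices):")
cols = ["trial", "fixation_onset", "fixation_duration_ms", "stimulus_code",
        "stimulus_onset", "rt_ms", "response_code", "response_onset"]
print(schedule[schedule["block"] == 1][cols].head(3).to_string(index=False))
# Every onset above reappears verbatim as a trigger-event onset in the
# recording's code stream; that is what makes end-to-end checks exact.
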